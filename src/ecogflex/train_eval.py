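"""Training loop, combined MSE + cosine loss, and Pearson evaluation.

The loss is

    L = MSE(pred, target) + lambda * (1 - mean cosine similarity),

where the cosine similarity is computed per (sample, finger) along the
window's time axis and averaged; lambda defaults to 1 (equal weighting).
Optimization is Adam with L2 weight decay.  Decoding quality is reported
as the Pearson correlation between predicted and true flexion, per finger
over the full stitched test series, averaged across the five fingers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import DecoderModel, ModelConfig, build_model
from .preprocess import Spectrogram
from .windowing import WindowConfig, WindowedDataset, make_windows, stitch_predictions

logger = logging.getLogger("ecogflex")

__all__ = [
    "TrainConfig",
    "EvalReport",
    "cosine_similarity",
    "combined_loss",
    "pearson_r",
    "AdamOptimizer",
    "split_chronological",
    "train",
    "evaluate",
    "run_ablation",
]

FINGERS = ("thumb", "index", "middle", "ring", "little")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (learning rate and weight decay follow
    the published recipe; the rest are desk-scale defaults)."""

    lr: float = 8.42e-5
    weight_decay: float = 1e-6
    cosine_weight: float = 1.0
    batch_size: int = 64
    max_epochs: int = 40
    seed: int = 0
    patience: int = 5
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.weight_decay < 0 or self.cosine_weight < 0:
            raise ValueError("need lr > 0, weight_decay >= 0, cosine_weight >= 0")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    """Per-finger and averaged Pearson correlations on a test series."""

    per_finger_r: np.ndarray  # 5 values, NaN where undefined
    mean_r: float
    n_test_samples: int
    finger_names: tuple = FINGERS

    def as_dict(self) -> dict:
        d = {name: float(r) for name, r in zip(self.finger_names, self.per_finger_r)}
        d["mean"] = float(self.mean_r)
        d["n_test_samples"] = self.n_test_samples
        return d


# ---------------------------------------------------------------------------
# Metrics and loss
# ---------------------------------------------------------------------------


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """x.y / (|x||y|); returns 0 (with a warning) if either norm is zero."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        logger.warning("cosine_similarity: zero-norm vector, returning 0")
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation: covariance normalized by both standard deviations."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xc**2)), np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.sum(xc * yc) / (sx * sy))


def combined_loss(pred: np.ndarray, target: np.ndarray, lam: float = 1.0, with_grad: bool = False):
    """MSE plus lambda * (1 - mean per-(sample,finger) cosine along time).

    Returns the scalar loss, or ``(loss, dL/dpred)`` when ``with_grad``.
    """
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target
    mse = float(np.mean(diff**2))

    p = pred.reshape(-1, pred.shape[-1]).astype(np.float64)
    t = target.reshape(-1, target.shape[-1]).astype(np.float64)
    dot = np.sum(p * t, axis=1)
    npn = np.linalg.norm(p, axis=1)
    ntn = np.linalg.norm(t, axis=1)
    mask = (npn > 0) & (ntn > 0)
    if not np.all(mask):
        logger.warning("combined_loss: %d zero-norm segment(s), cosine term set to 0",
                       int(np.sum(~mask)))
    cos = np.zeros_like(dot)
    cos[mask] = dot[mask] / (npn[mask] * ntn[mask])
    loss = mse + lam * (1.0 - float(cos.mean()))
    if not with_grad:
        return loss

    grad = (2.0 / pred.size) * diff
    if lam > 0:
        dcos = np.zeros_like(p)
        m = mask
        dcos[m] = t[m] / (npn[m] * ntn[m])[:, None] - (cos[m] / npn[m] ** 2)[:, None] * p[m]
        grad -= (lam / p.shape[0]) * dcos.reshape(pred.shape)
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class AdamOptimizer:
    """Adam with L2 weight decay added to the gradient (coupled form)."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(np.float32)
            if self.wd:
                g = g + np.float32(self.wd) * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= np.float32(self.lr) * mhat / (np.sqrt(vhat) + np.float32(self.eps))


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------


def split_chronological(ds: WindowedDataset, val_fraction: float) -> tuple[WindowedDataset, WindowedDataset]:
    """Chronological train/validation split over window start times.

    Avoids the temporal leakage a shuffled split would create with heavily
    overlapping windows.
    """
    n = len(ds)
    n_val = max(1, int(round(n * val_fraction)))
    if n_val >= n:
        raise ValueError("not enough windows to split")
    cut = n - n_val

    def _sub(a, b):
        return WindowedDataset(
            inputs=ds.inputs[a:b], targets=ds.targets[a:b],
            window_starts=ds.window_starts[a:b], n_channels=ds.n_channels,
            n_freqs=ds.n_freqs, source_T=ds.source_T, meta=dict(ds.meta),
        )

    return _sub(0, cut), _sub(cut, n)


def _epoch_metrics(model: DecoderModel, ds: WindowedDataset, lam: float, batch: int):
    """Loss and mean per-window-finger Pearson in evaluation mode."""
    losses, rs = [], []
    for i in range(0, len(ds), batch):
        xb, tb = ds.inputs[i : i + batch], ds.targets[i : i + batch]
        pred = model.forward(xb, train=False)
        losses.append(combined_loss(pred, tb, lam) * len(xb))
        for b in range(len(xb)):
            for f in range(tb.shape[1]):
                tv, pv = tb[b, f], pred[b, f]
                if tv.std() > 0 and pv.std() > 0:
                    rs.append(pearson_r(pv, tv))
    loss = float(np.sum(losses) / len(ds))
    return loss, (float(np.mean(rs)) if rs else float("nan"))


def train(
    model: DecoderModel,
    train_windows: WindowedDataset,
    val_windows: WindowedDataset | None,
    cfg: TrainConfig,
    max_steps: int | None = None,
) -> tuple[DecoderModel, dict]:
    """Seeded Adam training with optional early stopping on validation r.

    ``val_windows=None`` disables validation and early stopping (pure
    optimization runs, e.g. overfit checks).  ``max_steps`` caps the total
    number of optimizer steps regardless of epochs.

    Returns the model (best-validation weights restored when validating)
    and a history dict with per-epoch losses and validation mean r.
    """
    if len(train_windows) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(model.parameters(), cfg.lr, cfg.weight_decay)
    history = {"train_loss": [], "val_loss": [], "val_mean_r": [], "steps": 0}
    best_metric, best_params, since_best = -np.inf, None, 0
    n = len(train_windows)
    steps_done = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_count = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            if max_steps is not None and steps_done >= max_steps:
                break
            idx = order[i : i + cfg.batch_size]
            xb = train_windows.inputs[idx]
            tb = train_windows.targets[idx]
            pred = model.forward(xb, train=True)
            loss, grad = combined_loss(pred, tb, cfg.cosine_weight, with_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, step {steps_done}: loss={loss}"
                )
            model.backward(grad)
            opt.step(model.gradients())
            ep_loss += loss * len(idx)
            ep_count += len(idx)
            steps_done += 1
        if ep_count == 0:
            break
        history["train_loss"].append(ep_loss / ep_count)

        if val_windows is not None and len(val_windows):
            vloss, vr = _epoch_metrics(model, val_windows, cfg.cosine_weight, cfg.batch_size)
            history["val_loss"].append(vloss)
            history["val_mean_r"].append(vr)
            metric = vr if np.isfinite(vr) else -vloss
            if metric > best_metric:
                best_metric, since_best = metric, 0
                best_params = {k: v.copy() for k, v in model.parameters().items()}
            else:
                since_best += 1
                if since_best > cfg.patience:
                    logger.info("early stop at epoch %d (best val r=%.3f)", epoch, best_metric)
                    break
        if max_steps is not None and steps_done >= max_steps:
            break

    history["steps"] = steps_done
    if best_params is not None:
        for k, p in model.parameters().items():
            p[...] = best_params[k]
    return model, history


def predict_series(
    model: DecoderModel,
    spec: Spectrogram,
    l: int = 256,
    stitch_mode: str = "tile",
    stride: int | None = None,
    batch_size: int = 64,
) -> tuple[np.ndarray, int]:
    """Windowed forward pass + stitching over a full spectrogram.

    Returns ``(pred (5, T'), T')`` where T' is the covered (possibly
    truncated) span: a multiple of l for tiling, or the last window's end
    for overlap averaging.
    """
    T = spec.n_times
    if stitch_mode == "tile":
        s = l
        T_use = (T // l) * l
    else:
        s = stride or l // 4
        n = (T - l) // s + 1
        T_use = (n - 1) * s + l
    if T_use < l:
        raise ValueError(f"test series too short ({T} samples) for window length {l}")
    flat = spec.values.reshape(-1, T)[:, :T_use]
    starts = np.arange(0, T_use - l + 1, s)
    preds = []
    for i in range(0, len(starts), batch_size):
        batch_starts = starts[i : i + batch_size]
        xb = np.stack([flat[:, s0 : s0 + l] for s0 in batch_starts]).astype(np.float32)
        preds.append(model.forward(xb, train=False))
    window_preds = np.concatenate(preds, axis=0)
    return stitch_predictions(window_preds, starts, T_use, mode=stitch_mode), T_use


def evaluate(
    model: DecoderModel,
    spec: Spectrogram,
    fingers: np.ndarray,
    stitch_mode: str = "tile",
    l: int = 256,
    stride: int | None = None,
) -> EvalReport:
    """Decode a held-out series and report per-finger Pearson correlations.

    Fingers whose true trace has zero variance are reported as NaN and
    excluded from the mean with a warning.
    """
    fingers = np.asarray(fingers, dtype=float)
    pred, T_use = predict_series(model, spec, l=l, stitch_mode=stitch_mode, stride=stride)
    truth = fingers[:, :T_use]
    rs = np.full(truth.shape[0], np.nan)
    for f in range(truth.shape[0]):
        try:
            rs[f] = pearson_r(pred[f], truth[f])
        except ValueError:
            logger.warning("finger %d: correlation undefined (zero variance), excluded", f)
    mean_r = float(np.nanmean(rs)) if np.any(np.isfinite(rs)) else float("nan")
    return EvalReport(per_finger_r=rs, mean_r=mean_r, n_test_samples=T_use)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------


def run_ablation(
    grid: list[dict],
    train_rec,
    test_rec,
    model_cfg_base: ModelConfig,
    train_cfg: TrainConfig,
    pre_cfg=None,
    l: int = 256,
    max_steps: int | None = None,
) -> list[dict]:
    """Train and evaluate one model per grid cell with shared seeds.

    Each cell is a dict with any of the keys ``wavelet`` (morlet / haar /
    daubechies / symlet), ``dilation`` (bool), ``upsample``
    (transposed_conv / linear) and ``stride`` (training stride).  Failures
    are recorded per cell; the grid continues.
    """
    from dataclasses import replace

    from .preprocess import (PreprocessConfig, alt_wavelet_spectrogram, bandpass_filter,
                             downsample_time, interpolate_fingers, morlet_spectrogram,
                             normalize_channels, notch_filter)

    pre_cfg = pre_cfg or PreprocessConfig()
    spec_cache: dict[str, tuple] = {}

    def _preprocess(rec, family):
        x = normalize_channels(rec.ecog)
        x = bandpass_filter(x, rec.fs_ecog, pre_cfg.band_lo, pre_cfg.band_hi)
        x = notch_filter(x, rec.fs_ecog, pre_cfg.line_freq,
                         harmonics=[pre_cfg.line_freq * k for k in range(1, pre_cfg.n_harmonics + 1)],
                         q=pre_cfg.notch_q)
        if family == "morlet":
            spec = morlet_spectrogram(x, rec.fs_ecog, pre_cfg.morlet, list(rec.channel_ids))
        else:
            spec = alt_wavelet_spectrogram(x, rec.fs_ecog, family, pre_cfg.morlet,
                                           list(rec.channel_ids))
        spec = downsample_time(spec, pre_cfg.out_fs)
        fing = interpolate_fingers(rec.fingers, rec.fs_glove, pre_cfg.out_fs)
        t = min(spec.n_times, fing.shape[1])
        spec = Spectrogram(values=spec.values[:, :, :t], fs=spec.fs,
                           freqs=spec.freqs, channel_ids=list(spec.channel_ids))
        return spec, fing[:, :t]

    def _get(family):
        if family not in spec_cache:
            spec_cache[family] = (_preprocess(train_rec, family), _preprocess(test_rec, family))
        return spec_cache[family]

    results = []
    for cell in grid:
        row = {"wavelet": cell.get("wavelet", "morlet"),
               "dilation": bool(cell.get("dilation", True)),
               "upsample": cell.get("upsample", "transposed_conv"),
               "stride": int(cell.get("stride", 8))}
        try:
            (spec_tr, fing_tr), (spec_te, fing_te) = _get(row["wavelet"])
            wcfg = WindowConfig(l=l, s=row["stride"])
            ds = make_windows(spec_tr, fing_tr, wcfg)
            tr, va = split_chronological(ds, train_cfg.val_fraction)
            mcfg = replace(model_cfg_base, dilation_enabled=row["dilation"],
                           upsample_mode=row["upsample"])
            model = build_model(mcfg, seed=train_cfg.seed)
            model, hist = train(model, tr, va, train_cfg, max_steps=max_steps)
            rep = evaluate(model, spec_te, fing_te, l=l)
            row.update(mean_r=rep.mean_r,
                       per_finger_r=[float(r) for r in rep.per_finger_r],
                       steps=hist["steps"])
        except Exception as exc:  # noqa: BLE001 - per-cell failures must not kill the grid
            logger.exception("ablation cell %s failed", row)
            row.update(mean_r=float("nan"), error=str(exc))
        results.append(row)
    return results
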