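"""Dilated/transposed 1-D convolutional encoder-decoder.

Architecture (lengths for window length l, which must be divisible by 32):

* Feature Reduction — 1-D conv over the merged electrode x frequency axis
  (in_features -> 64, kernel 3, "same" padding).
* Encoder, 5 stages — dilated 1-D conv ("same" effective padding) ->
  layer normalization -> GELU -> dropout -> max-pool(2).  The pooled output
  of every stage is saved for the skip path; after five stages the
  bottleneck has length l/32.
* Decoder, 5 stages — concatenate the matching skip on the feature axis
  (doubling it) -> standard conv block -> x2 upsampling (learnable
  transposed conv, kernel 2 stride 2; or non-learnable linear interpolation
  when ablated).
* Head — 1x1 conv to 5 finger outputs; output time length equals l.

Because the skip saved at each stage is the *pooled* copy, the first
decoder stage's skip is the bottleneck itself; lengths then pair off so the
skip at every later stage matches its decoder input exactly.

Everything here — convolutions, normalization, activations, pooling,
upsampling and their gradients — is implemented directly on NumPy arrays;
the model exposes ``forward``/``backward`` and a flat parameter/gradient
view for the optimizer.  float32 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import erf

__all__ = [
    "ModelConfig",
    "DecoderModel",
    "build_model",
    "count_parameters",
    "receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


@dataclass
class ModelConfig:
    """Hyperparameters of the decoder network.

    ``layer_dims`` lists the Feature Reduction width followed by the five
    encoder stage widths; decoder widths mirror the encoder in reverse.
    ``upsample_mode`` and ``dilation_enabled`` are the ablation switches.
    """

    in_features: int
    layer_dims: tuple = (64, 64, 128, 256, 512, 512)
    kernel_sizes: tuple = (7, 7, 5, 5, 5)
    dilations: tuple = (1, 2, 3, 1, 2)
    reduction_kernel: int = 3
    dropout: float = 0.1
    pool_factor: int = 2
    n_outputs: int = 5
    upsample_mode: str = "transposed_conv"
    dilation_enabled: bool = True

    def __post_init__(self) -> None:
        if len(self.layer_dims) != 6:
            raise ValueError("layer_dims must list reduction width + 5 encoder widths")
        if len(self.kernel_sizes) != 5 or len(self.dilations) != 5:
            raise ValueError("need exactly 5 encoder kernel sizes and dilations")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.in_features < 1 or any(d < 1 for d in self.layer_dims):
            raise ValueError("dimensions must be positive")
        if any(k < 1 or k % 2 == 0 for k in self.kernel_sizes) or self.reduction_kernel % 2 == 0:
            raise ValueError("conv kernels must be odd for exact 'same' padding")
        if self.upsample_mode not in ("transposed_conv", "linear"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def effective_dilations(self) -> tuple:
        return self.dilations if self.dilation_enabled else (1,) * 5


# ---------------------------------------------------------------------------
# Layers.  Each stores its forward cache and accumulates parameter grads.
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(_Layer):
    """1-D convolution with dilation and exact "same" padding (odd kernels)."""

    def __init__(self, cin, cout, k, dilation=1, rng=None):
        super().__init__()
        self.k, self.d = k, dilation
        self.pad = dilation * (k - 1) // 2
        std = np.sqrt(2.0 / (cin * k))
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, std, size=(cout, cin, k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train):
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp, self._L = xp, L
        W, b = self.params["W"], self.params["b"]
        y = np.broadcast_to(b[None, :, None], (B, W.shape[0], L)).astype(np.float32).copy()
        for kk in range(self.k):
            seg = xp[:, :, kk * self.d : kk * self.d + L]
            y += np.matmul(W[:, :, kk], seg)
        return y

    def backward(self, dy):
        xp, L = self._xp, self._L
        W = self.params["W"]
        B = dy.shape[0]
        self.grads["b"] = dy.sum(axis=(0, 2))
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        dy2 = dy.transpose(1, 0, 2).reshape(W.shape[0], -1)  # (O, B*L)
        for kk in range(self.k):
            seg = xp[:, :, kk * self.d : kk * self.d + L]
            seg2 = seg.transpose(1, 0, 2).reshape(W.shape[1], -1)  # (C, B*L)
            dW[:, :, kk] = dy2 @ seg2.T
            dxp[:, :, kk * self.d : kk * self.d + L] += np.matmul(W[:, :, kk].T, dy)
        self.grads["W"] = dW
        self._xp = None
        return dxp[:, :, self.pad : self.pad + L] if self.pad else dxp


class ConvTranspose1d(_Layer):
    """Transposed conv, kernel 2 stride 2: exact x2 upsampling, no cropping."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        std = np.sqrt(2.0 / (cin * 2))
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, std, size=(cout, cin, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        W, b = self.params["W"], self.params["b"]
        B, C, L = x.shape
        y = np.empty((B, W.shape[0], 2 * L), dtype=np.float32)
        y[:, :, 0::2] = np.matmul(W[:, :, 0], x)
        y[:, :, 1::2] = np.matmul(W[:, :, 1], x)
        return y + b[None, :, None]

    def backward(self, dy):
        x, W = self._x, self.params["W"]
        self.grads["b"] = dy.sum(axis=(0, 2))
        dW = np.empty_like(W)
        x2 = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
        dx = np.zeros_like(x)
        for kk in range(2):
            dyk = dy[:, :, kk::2]
            dyk2 = dyk.transpose(1, 0, 2).reshape(W.shape[0], -1)
            dW[:, :, kk] = dyk2 @ x2.T
            dx += np.matmul(W[:, :, kk].T, dyk)
        self.grads["W"] = dW
        self._x = None
        return dx


class LayerNorm(_Layer):
    """Normalizes over the feature axis at every (sample, time) position."""

    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)

    def forward(self, x, train):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, dy):
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxh = dy * self.params["gamma"][None, :, None]
        dx = istd * (
            dxh
            - dxh.mean(axis=1, keepdims=True)
            - xhat * (dxh * xhat).mean(axis=1, keepdims=True)
        )
        self._xhat = self._istd = None
        return dx.astype(np.float32)


class GELU(_Layer):
    def forward(self, x, train):
        self._x = x
        return (0.5 * x * (1.0 + erf(x / _SQRT2))).astype(np.float32)

    def backward(self, dy):
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        self._x = None
        return (dy * (cdf + x * pdf)).astype(np.float32)


class Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool1d(_Layer):
    """Non-overlapping max pooling by factor 2 along time."""

    def forward(self, x, train):
        B, C, L = x.shape
        xr = x.reshape(B, C, L // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        dxr = np.zeros((B, C, L // 2, 2), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        self._arg = None
        return dxr.reshape(B, C, L)


class LinearUpsample2(_Layer):
    """Non-learnable x2 linear-interpolation upsampling (ablation arm).

    Half-sample-offset scheme: y[2i] = 0.25 x[i-1] + 0.75 x[i],
    y[2i+1] = 0.75 x[i] + 0.25 x[i+1], edges clamped.
    """

    def forward(self, x, train):
        B, C, L = x.shape
        self._L = L
        xp = np.concatenate([x[:, :, :1], x, x[:, :, -1:]], axis=2)
        y = np.empty((B, C, 2 * L), dtype=np.float32)
        y[:, :, 0::2] = 0.25 * xp[:, :, 0:L] + 0.75 * xp[:, :, 1 : L + 1]
        y[:, :, 1::2] = 0.75 * xp[:, :, 1 : L + 1] + 0.25 * xp[:, :, 2 : L + 2]
        return y

    def backward(self, dy):
        L = self._L
        de, do = dy[:, :, 0::2], dy[:, :, 1::2]
        dxp = np.zeros((dy.shape[0], dy.shape[1], L + 2), dtype=np.float32)
        dxp[:, :, 0:L] += 0.25 * de
        dxp[:, :, 1 : L + 1] += 0.75 * de + 0.75 * do
        dxp[:, :, 2 : L + 2] += 0.25 * do
        dx = dxp[:, :, 1 : L + 1].copy()
        dx[:, :, 0] += dxp[:, :, 0]
        dx[:, :, -1] += dxp[:, :, -1]
        return dx


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


@dataclass
class _DecStage:
    block: list
    up: _Layer


class DecoderModel:
    """Assembled network; see the module docstring for the layout."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))

        dims = cfg.layer_dims
        dil = cfg.effective_dilations
        self.reduction = Conv1d(cfg.in_features, dims[0], cfg.reduction_kernel, 1, rng)

        self.enc_stages: list[list[_Layer]] = []
        for i in range(5):
            cin, cout = dims[i], dims[i + 1]
            self.enc_stages.append([
                Conv1d(cin, cout, cfg.kernel_sizes[i], dil[i], rng),
                LayerNorm(cout),
                GELU(),
                Dropout(cfg.dropout, self._drop_rng),
                MaxPool1d(),
            ])

        # decoder widths mirror the encoder in reverse; skips pair by length
        rev = tuple(reversed(dims))            # (512, 512, 256, 128, 64, 64)
        rev_k = tuple(reversed(cfg.kernel_sizes))
        skip_ch = [dims[5], dims[4], dims[3], dims[2], dims[1]]
        self.dec_stages: list[_DecStage] = []
        cur = dims[5]
        for i in range(5):
            cout = rev[i + 1]
            block = [
                Conv1d(cur + skip_ch[i], cout, rev_k[i], 1, rng),
                LayerNorm(cout),
                GELU(),
                Dropout(cfg.dropout, self._drop_rng),
            ]
            up = (ConvTranspose1d(cout, cout, rng)
                  if cfg.upsample_mode == "transposed_conv" else LinearUpsample2())
            self.dec_stages.append(_DecStage(block, up))
            cur = cout

        self.head = Conv1d(cur, cfg.n_outputs, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        yield "reduction", self.reduction
        for i, st in enumerate(self.enc_stages):
            for j, layer in enumerate(st):
                yield f"enc{i}.{type(layer).__name__.lower()}{j}", layer
        for i, st in enumerate(self.dec_stages):
            for j, layer in enumerate(st.block):
                yield f"dec{i}.{type(layer).__name__.lower()}{j}", layer
            yield f"dec{i}.up", st.up
        yield "head", self.head

    def parameters(self):
        """Flat ``{qualified_name: array}`` view of all learnable tensors."""
        return {f"{ln}.{pn}": p for ln, layer in self._layers() for pn, p in layer.params.items()}

    def gradients(self):
        return {f"{ln}.{pn}": g for ln, layer in self._layers() for pn, g in layer.grads.items()}

    # -- forward / backward -------------------------------------------------

    def _check_length(self, L: int) -> None:
        if L % 32 != 0:
            raise ValueError(f"time length {L} not divisible by 32 (five x2 poolings)")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.cfg.in_features:
            raise ValueError(
                f"expected (batch, {self.cfg.in_features}, l) input, got {x.shape}"
            )
        self._check_length(x.shape[2])
        h = self.reduction.forward(x, train)
        skips = []
        for st in self.enc_stages:
            for layer in st:
                h = layer.forward(h, train)
            skips.append(h)
        cur = skips[-1]
        self._splits = []
        for i, st in enumerate(self.dec_stages):
            skip = skips[4 - i]
            self._splits.append(cur.shape[1])
            cur = np.concatenate([cur, skip], axis=1)
            for layer in st.block:
                cur = layer.forward(cur, train)
            cur = st.up.forward(cur, train)
        return self.head.forward(cur, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate loss gradient; fills layer grads, returns d(input)."""
        d = self.head.backward(np.asarray(dy, dtype=np.float32))
        dskips = [None] * 5
        for i in reversed(range(5)):
            st = self.dec_stages[i]
            d = st.up.backward(d)
            for layer in reversed(st.block):
                d = layer.backward(d)
            split = self._splits[i]
            d, ds = d[:, :split, :], d[:, split:, :]
            k = 4 - i
            dskips[k] = ds if dskips[k] is None else dskips[k] + ds
        dskips[4] = dskips[4] + d  # bottleneck also feeds the decoder input path
        g = None
        for k in reversed(range(5)):
            total = dskips[k] if g is None else dskips[k] + g
            for layer in reversed(self.enc_stages[k]):
                total = layer.backward(total)
            g = total
        return self.reduction.backward(g)

    def __call__(self, x, train=False):
        return self.forward(x, train)


def build_model(cfg: ModelConfig, seed: int = 0) -> DecoderModel:
    """Assemble the network from its configuration with seeded initialization."""
    return DecoderModel(cfg, seed=seed)


def count_parameters(model: DecoderModel) -> int:
    """Total learnable scalar count."""
    return sum(p.size for p in model.parameters().values())


def parameter_ledger(model: DecoderModel) -> list[tuple[str, int]]:
    """Per-tensor (name, size) listing, for the model-summary surface."""
    return [(name, p.size) for name, p in model.parameters().items()]


def receptive_field(cfg: ModelConfig) -> int:
    """Effective receptive field (input samples) of the encoder path.

    Standard recurrence: each conv adds (k-1)*dilation*jump, each pool adds
    (pool-1)*jump and multiplies the jump.
    """
    rf, jump = 1, 1
    rf += (cfg.reduction_kernel - 1) * jump
    for k, d in zip(cfg.kernel_sizes, cfg.effective_dilations):
        rf += (k - 1) * d * jump
        rf += (cfg.pool_factor - 1) * jump
        jump *= cfg.pool_factor
    return rf


def save_checkpoint(model: DecoderModel, path) -> None:
    """Config + weights + init seed in one .npz file."""
    meta = json.dumps({"config": asdict(model.cfg), "seed": model.seed})
    np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.parameters())


def load_checkpoint(path) -> DecoderModel:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        for key in ("layer_dims", "kernel_sizes", "dilations"):
            cfg_d[key] = tuple(cfg_d[key])
        model = DecoderModel(ModelConfig(**cfg_d), seed=meta["seed"])
        params = model.parameters()
        for name, p in params.items():
            p[...] = z[name]
    return model
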