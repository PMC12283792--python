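"""Sliding-window sample construction and prediction stitching.

A time-aligned spectrogram (c, f, T) and trajectory matrix (5, T) are cut
into N overlapping fixed-length samples,

    N = floor((T - l) / s) + 1,

with window length l (default 256) and stride s (default 1).  Each sample's
input is the spectrogram slice flattened over (channel, frequency) —
channel-major, feature index = channel * n_freqs + freq — giving the
(feature, l) layout the decoder consumes.  ``stitch_predictions`` inverts
the windowing for model output, either by tiling non-overlapping windows or
by averaging all windows covering each time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Spectrogram

__all__ = ["WindowConfig", "WindowedDataset", "count_windows", "make_windows", "stitch_predictions"]


@dataclass
class WindowConfig:
    """Sliding-window geometry.  l must be divisible by 32 (five poolings)."""

    l: int = 256
    s: int = 1

    def __post_init__(self) -> None:
        if self.l < 1 or self.s < 1:
            raise ValueError("window length and stride must be >= 1")
        if self.l % 32 != 0:
            raise ValueError(f"window length {self.l} must be divisible by 32 "
                             "(five encoder poolings halve the time axis)")


@dataclass
class WindowedDataset:
    """N windowed samples: inputs (N, c*f, l), targets (N, 5, l)."""

    inputs: np.ndarray
    targets: np.ndarray
    window_starts: np.ndarray
    n_channels: int
    n_freqs: int
    source_T: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def l(self) -> int:
        return self.inputs.shape[2]


def count_windows(T: int, l: int, s: int) -> int:
    """Number of length-l windows with stride s fitting in T samples."""
    if l < 1 or s < 1:
        raise ValueError("need l >= 1 and s >= 1")
    if T < l:
        raise ValueError(f"series length T={T} shorter than window length l={l}: zero windows")
    return (T - l) // s + 1


def make_windows(
    spec: Spectrogram, fingers: np.ndarray, cfg: WindowConfig | None = None
) -> WindowedDataset:
    """Cut aligned (spectrogram, fingers) into overlapping training samples.

    The feature axis flattens (channel, frequency) channel-major, matching
    the order recorded in the dataset metadata.
    """
    cfg = cfg or WindowConfig()
    fingers = np.asarray(fingers)
    c, f, T = spec.values.shape
    if fingers.ndim != 2 or fingers.shape[1] != T:
        raise ValueError(
            f"fingers time axis ({fingers.shape}) misaligned with spectrogram T={T}"
        )
    n = count_windows(T, cfg.l, cfg.s)
    starts = np.arange(n) * cfg.s
    flat = spec.values.reshape(c * f, T)

    # gather windows via stride tricks, then copy into contiguous arrays
    idx = starts[:, None] + np.arange(cfg.l)[None, :]
    inputs = np.ascontiguousarray(np.swapaxes(flat[:, idx], 0, 1), dtype=np.float32)
    targets = np.ascontiguousarray(np.swapaxes(fingers[:, idx], 0, 1), dtype=np.float32)
    return WindowedDataset(
        inputs=inputs,
        targets=targets,
        window_starts=starts,
        n_channels=c,
        n_freqs=f,
        source_T=T,
        meta={"flatten_order": "channel_major", "l": cfg.l, "s": cfg.s},
    )


def stitch_predictions(
    window_preds: np.ndarray,
    starts: np.ndarray,
    T: int,
    mode: str = "overlap_mean",
) -> np.ndarray:
    """Recombine per-window predictions (N, 5, l) into one (5, T) trajectory.

    ``tile``
        Windows are concatenated; they must exactly partition [0, T).
    ``overlap_mean``
        Each time point is the mean of every window prediction covering it;
        the windows must jointly cover [0, T).
    """
    preds = np.asarray(window_preds, dtype=float)
    starts = np.asarray(starts, dtype=int)
    if preds.ndim != 3 or preds.shape[0] != starts.shape[0]:
        raise ValueError("window_preds must be (N, n_out, l) matching starts")
    n, n_out, l = preds.shape

    if mode == "tile":
        order = np.argsort(starts)
        expected = np.arange(n) * l
        if not np.array_equal(starts[order], expected) or n * l != T:
            raise ValueError("tile mode requires non-overlapping windows exactly covering [0, T)")
        out = np.empty((n_out, T))
        for i in order:
            out[:, starts[i] : starts[i] + l] = preds[i]
        return out

    if mode == "overlap_mean":
        acc = np.zeros((n_out, T))
        cnt = np.zeros(T)
        for i in range(n):
            s0 = starts[i]
            acc[:, s0 : s0 + l] += preds[i]
            cnt[s0 : s0 + l] += 1
        if np.any(cnt == 0):
            raise ValueError("windows do not cover every time point in [0, T)")
        return acc / cnt

    raise ValueError(f"unknown stitch mode {mode!r}")
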