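"""Signal conditioning and time-frequency decomposition.

Pipeline order (fixed): per-channel normalization -> 40-300 Hz band-pass ->
power-line notch comb -> Morlet wavelet spectrogram -> temporal downsampling
to the glove-aligned rate (100 Hz).  Finger trajectories are upsampled from
25 Hz to the same rate by cubic interpolation.

The Morlet transform convolves each channel with complex wavelets

    psi_f(t) = A * exp(-t^2 / (2 sigma^2)) * exp(2 pi i f t),
    sigma(f) = n_cycles / (2 pi f),

on a log-uniform frequency grid spanning the analysis band.  A is chosen so
each discretized wavelet has unit L2 norm, making amplitudes comparable
across frequencies.  The output is the amplitude |W| on axes
(electrode_channel, wavelet_frequency, time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io_dataset import RawRecording

logger = logging.getLogger("ecogflex")

__all__ = [
    "MorletParams",
    "Spectrogram",
    "PreprocessConfig",
    "interpolate_fingers",
    "normalize_channels",
    "bandpass_filter",
    "notch_filter",
    "morlet_wavelet",
    "morlet_spectrogram",
    "downsample_time",
    "preprocess_recording",
    "alt_wavelet_spectrogram",
]


@dataclass
class MorletParams:
    """Morlet filter-bank parameters.

    ``freqs`` is log-uniform over [f_lo, f_hi] with both endpoints included.
    ``n_cycles`` sets the time/frequency resolution trade-off through
    sigma(f) = n_cycles / (2 pi f) seconds.
    """

    f_lo: float = 40.0
    f_hi: float = 300.0
    n_freqs: int = 40
    n_cycles: float | np.ndarray = 7.0
    freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.n_freqs < 2:
            raise ValueError("need at least 2 frequencies")
        self.freqs = np.geomspace(self.f_lo, self.f_hi, self.n_freqs)
        ncyc = np.broadcast_to(np.asarray(self.n_cycles, dtype=float), (self.n_freqs,))
        if np.any(ncyc <= 0):
            raise ValueError("n_cycles must be positive")
        self._ncyc = ncyc

    def sigma(self, f: np.ndarray | float) -> np.ndarray:
        """Gaussian envelope width in seconds at center frequency f."""
        f = np.asarray(f, dtype=float)
        ncyc = np.interp(f, self.freqs, self._ncyc)
        return ncyc / (2.0 * np.pi * f)

    @property
    def n_cycles_per_freq(self) -> np.ndarray:
        return self._ncyc


@dataclass
class Spectrogram:
    """Wavelet amplitude array on axes (electrode_channel, wavelet_frequency, time)."""

    values: np.ndarray
    fs: float
    freqs: np.ndarray
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"spectrogram must be 3-D (c, f, t), got {self.values.shape}")
        if self.values.shape[1] != len(self.freqs):
            raise ValueError("frequency axis length does not match freqs")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.values.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]


@dataclass
class PreprocessConfig:
    """End-to-end preprocessing settings."""

    morlet: MorletParams = field(default_factory=MorletParams)
    band_lo: float = 40.0
    band_hi: float = 300.0
    line_freq: float = 60.0
    n_harmonics: int = 5  # 60..300 Hz at fs=1000
    notch_q: float = 30.0
    out_fs: float = 100.0
    power: bool = False  # amplitude |W| by default; |W|^2 when True


def interpolate_fingers(fingers: np.ndarray, fs_in: float = 25.0, target_fs: float = 100.0) -> np.ndarray:
    """Upsample glove traces by cubic-spline interpolation.

    Output has ``round(n * target_fs / fs_in)`` samples per finger and passes
    through the original samples at the original time points.
    """
    fingers = np.asarray(fingers, dtype=float)
    if fingers.ndim != 2:
        raise ValueError("fingers must be 2-D (n_fingers, n_time)")
    n = fingers.shape[1]
    if n < 4:
        raise ValueError(f"cubic interpolation needs >= 4 samples, got {n}")
    ratio = target_fs / fs_in
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target_fs must be an integer multiple of the glove rate")
    m = int(round(n * ratio))
    t_in = np.arange(n) / fs_in
    t_out = np.arange(m) / target_fs
    spl = CubicSpline(t_in, fingers, axis=1)
    return spl(t_out)


def normalize_channels(ecog: np.ndarray) -> np.ndarray:
    """Per-channel z-score followed by removal of the channel median.

    Each channel is standardized (subtract mean, divide by SD), then the
    median of the standardized trace is subtracted, so every output channel
    has median exactly zero.
    """
    ecog = np.asarray(ecog, dtype=float)
    if ecog.ndim != 2 or ecog.shape[1] < 2:
        raise ValueError("ecog must be (n_channels, n_time >= 2)")
    sd = ecog.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s) {bad.tolist()}: cannot standardize")
    z = (ecog - ecog.mean(axis=1, keepdims=True)) / sd[:, None]
    return z - np.median(z, axis=1, keepdims=True)


def bandpass_filter(
    ecog: np.ndarray, fs: float, lo: float = 40.0, hi: float = 300.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    if hi >= fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ecog, dtype=float), axis=-1)


def notch_filter(
    ecog: np.ndarray,
    fs: float,
    line: float = 60.0,
    harmonics: list[float] | None = None,
    q: float = 30.0,
) -> np.ndarray:
    """Zero-phase notch comb at the line frequency and its harmonics.

    Harmonics at or above Nyquist are skipped with a warning rather than
    failing, so the same config works across sampling rates.
    """
    out = np.asarray(ecog, dtype=float)
    if harmonics is None:
        harmonics = [line * k for k in range(1, int(fs / 2 / line) + 1)]
    else:
        harmonics = [line] + [h for h in harmonics if h != line]
    for f0 in harmonics:
        if f0 >= fs / 2:
            logger.warning("notch harmonic %.1f Hz >= Nyquist %.1f Hz: skipped", f0, fs / 2)
            continue
        b, a = signal.iirnotch(f0, q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def morlet_wavelet(f: float, sigma: float, fs: float, n_sigmas: float = 5.0) -> np.ndarray:
    """Discretized complex Morlet wavelet with unit L2 norm.

    The support is truncated at ``n_sigmas`` Gaussian widths on each side.
    """
    half = int(np.ceil(n_sigmas * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    psi = np.exp(-(t**2) / (2.0 * sigma**2)) * np.exp(2j * np.pi * f * t)
    return psi / np.linalg.norm(psi)


def morlet_spectrogram(
    ecog: np.ndarray,
    fs: float,
    params: MorletParams | None = None,
    channel_ids: list[str] | None = None,
    power: bool = False,
) -> Spectrogram:
    """Complex Morlet convolution per channel and frequency; amplitude output.

    Each channel is convolved ("same" length) with the filter bank; the
    result is |W| (or |W|^2 with ``power=True``) of shape
    (n_channels, n_freqs, n_time), time axis unchanged.
    """
    params = params or MorletParams()
    ecog = np.atleast_2d(np.asarray(ecog, dtype=float))
    c, t = ecog.shape
    sigmas = params.sigma(params.freqs)
    out = np.empty((c, params.n_freqs, t), dtype=np.float32)
    for j, (f, sig) in enumerate(zip(params.freqs, sigmas)):
        psi = morlet_wavelet(f, sig, fs)
        if psi.size > t:
            raise ValueError(
                f"wavelet support ({psi.size} samples at {f:.1f} Hz) exceeds signal "
                f"length {t}; reduce n_cycles or provide a longer signal"
            )
        w = signal.fftconvolve(ecog, psi[None, :], mode="same", axes=-1)
        amp = np.abs(w)
        out[:, j, :] = amp**2 if power else amp
    ids = channel_ids or [f"ch{i}" for i in range(c)]
    return Spectrogram(values=out, fs=fs, freqs=params.freqs, channel_ids=ids)


def downsample_time(spec: Spectrogram, out_fs: float = 100.0) -> Spectrogram:
    """Reduce the time axis by block-mean aggregation.

    Consecutive non-overlapping blocks of ``fs / out_fs`` samples are
    averaged (anti-aliasing the envelope); a trailing partial block is
    dropped, so the output length is ``floor(t / factor)``.
    """
    ratio = spec.fs / out_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(f"fs={spec.fs} must be an integer multiple of out_fs={out_fs}")
    k = int(round(ratio))
    c, f, t = spec.values.shape
    n_out = t // k
    v = spec.values[:, :, : n_out * k].reshape(c, f, n_out, k).mean(axis=3)
    return Spectrogram(values=v, fs=out_fs, freqs=spec.freqs, channel_ids=list(spec.channel_ids))


def preprocess_recording(
    rec: RawRecording, cfg: PreprocessConfig | None = None
) -> tuple[Spectrogram, np.ndarray]:
    """Full conditioning chain for one recording.

    ECoG: normalize -> band-pass -> notch -> Morlet -> block-mean downsample.
    Fingers: cubic upsampling to ``cfg.out_fs``.  The two time axes are
    truncated to a common length (they can differ by edge effects of the
    two resampling rules).

    Returns ``(spectrogram @ out_fs, fingers (5, T) @ out_fs)``.
    """
    cfg = cfg or PreprocessConfig()
    x = normalize_channels(rec.ecog)
    x = bandpass_filter(x, rec.fs_ecog, cfg.band_lo, cfg.band_hi)
    x = notch_filter(
        x, rec.fs_ecog, cfg.line_freq,
        harmonics=[cfg.line_freq * k for k in range(1, cfg.n_harmonics + 1)],
        q=cfg.notch_q,
    )
    spec = morlet_spectrogram(x, rec.fs_ecog, cfg.morlet, list(rec.channel_ids), power=cfg.power)
    spec = downsample_time(spec, cfg.out_fs)

    if rec.fingers.shape[1]:
        fingers = interpolate_fingers(rec.fingers, rec.fs_glove, cfg.out_fs)
        t = min(spec.n_times, fingers.shape[1])
        fingers = fingers[:, :t]
        spec = Spectrogram(
            values=spec.values[:, :, :t], fs=spec.fs, freqs=spec.freqs,
            channel_ids=list(spec.channel_ids),
        )
    else:
        fingers = np.empty((5, 0))
    return spec, fingers


# ---------------------------------------------------------------------------
# Alternative wavelet families (ablation arm)
# ---------------------------------------------------------------------------

_ALT_FAMILIES = {"haar": "haar", "daubechies": "db4", "symlet": "sym4"}


def alt_wavelet_spectrogram(
    ecog: np.ndarray,
    fs: float,
    family: str,
    params: MorletParams | None = None,
    channel_ids: list[str] | None = None,
) -> Spectrogram:
    """Time-frequency amplitudes using a compactly supported mother wavelet.

    For each grid frequency the discrete mother wavelet (from PyWavelets'
    ``wavefun``) is rescaled so its central frequency lands on the target,
    L2-normalized, and convolved with the signal ("same" length); the output
    is the rectified convolution magnitude on the same (c, f, t) axes as the
    Morlet transform, so the downstream model is unchanged.  Used by the
    ablation harness only.
    """
    import pywt

    key = family.lower()
    if key not in _ALT_FAMILIES:
        raise ValueError(f"unsupported wavelet family {family!r}; choose from {sorted(_ALT_FAMILIES)}")
    params = params or MorletParams()
    ecog = np.atleast_2d(np.asarray(ecog, dtype=float))
    c, t = ecog.shape

    wav = pywt.Wavelet(_ALT_FAMILIES[key])
    _, psi_ref, x_ref = wav.wavefun(level=10)
    fc = pywt.central_frequency(wav)  # cycles per unit of x_ref
    span = x_ref[-1] - x_ref[0]

    out = np.empty((c, params.n_freqs, t), dtype=np.float32)
    for j, f in enumerate(params.freqs):
        scale = fc * fs / f  # samples per unit of x_ref
        n_taps = max(int(np.ceil(span * scale)), 2)
        xk = x_ref[0] + np.arange(n_taps) / scale
        kern = np.interp(xk, x_ref, psi_ref)
        kern = kern - kern.mean()  # re-impose zero mean after resampling
        nrm = np.linalg.norm(kern)
        if nrm == 0:
            raise ValueError(f"degenerate kernel at {f:.1f} Hz for family {family}")
        kern /= nrm
        w = signal.fftconvolve(ecog, kern[None, :], mode="same", axes=-1)
        out[:, j, :] = np.abs(w)
    ids = channel_ids or [f"ch{i}" for i in range(c)]
    return Spectrogram(values=out, fs=fs, freqs=params.freqs, channel_ids=ids)
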