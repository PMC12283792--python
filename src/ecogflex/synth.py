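"""Synthetic ECoG-like fixture generator with a planted band-power code.

Emulates the structure of the cued finger-movement recordings: a cue/rest
paradigm (2 s cue, 2 s rest) cycling through the five fingers, where the
cued finger performs 3-5 smooth flexion bumps per cue.  Each finger is
assigned a disjoint high-gamma sub-band (within 70-170 Hz) and a set of
electrode channels; those channels carry band-limited carrier noise whose
amplitude envelope follows the finger's trajectory.  On top of the coded
carriers every channel receives pink (1/f) background noise, a 60 Hz line
component and a small shared Gaussian term.

The generator makes no attempt at biophysical realism — it plants a known
band-power -> trajectory coupling so the full decoding pipeline can be
exercised and scored without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io_dataset import RawRecording, save_recording

__all__ = ["SynthConfig", "generate_trajectories", "generate_ecog",
           "generate_recording", "make_fixture"]

_DEFAULT_BANDS = ((70.0, 88.0), (90.0, 108.0), (110.0, 128.0), (130.0, 148.0), (150.0, 168.0))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic fixture.

    Defaults: 16 channels at 1 kHz, 120 s, 2 s cue / 2 s rest, two coding
    channels per finger in disjoint high-gamma sub-bands, unit-scale pink
    noise and line interference.
    """

    n_channels: int = 16
    fs: float = 1000.0
    duration: float = 120.0
    cue_len: float = 2.0
    rest_len: float = 2.0
    glove_fs: float = 25.0
    bands: tuple = _DEFAULT_BANDS
    channels_per_finger: int = 2
    carrier_amp: float = 1.0
    pink_amp: float = 1.0
    line_amp: float = 1.0
    shared_noise_amp: float = 0.1
    line_freq: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bands) != 5:
            raise ValueError("need exactly 5 carrier bands (one per finger)")
        for lo, hi in self.bands:
            if not (40.0 <= lo < hi <= 300.0):
                raise ValueError(f"band ({lo}, {hi}) outside the 40-300 Hz analysis band")
        if 5 * self.channels_per_finger > self.n_channels:
            raise ValueError("not enough channels for the per-finger assignment")
        if min(self.carrier_amp, self.pink_amp, self.line_amp, self.shared_noise_amp) < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def assignments(self) -> list[list[int]]:
        """Channel indices coding each finger (first 5*k channels, in order)."""
        k = self.channels_per_finger
        return [list(range(f * k, (f + 1) * k)) for f in range(5)]


def generate_trajectories(cfg: SynthConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Five flexion traces at the glove rate, values in [0, 1].

    Cues cycle thumb -> little; within each cue block the cued finger shows
    3-5 raised-cosine flexion bumps while the others stay near baseline
    with a small smooth drift.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.glove_fs))
    traj = np.zeros((5, n))
    if n == 0:
        return traj

    # slow baseline drift per finger (integrated noise, low amplitude)
    drift = rng.normal(0, 1, size=(5, n)).cumsum(axis=1)
    drift -= drift.mean(axis=1, keepdims=True)
    scale = np.abs(drift).max(axis=1, keepdims=True)
    scale[scale == 0] = 1
    traj += 0.05 + 0.02 * drift / scale

    block = cfg.cue_len + cfg.rest_len
    cue_samples = int(round(cfg.cue_len * cfg.glove_fs))
    t0, finger = 0.0, 0
    while t0 + cfg.cue_len <= cfg.duration + 1e-9:
        s0 = int(round(t0 * cfg.glove_fs))
        n_bumps = int(rng.integers(3, 6))
        seg = np.zeros(cue_samples)
        width = cue_samples / n_bumps
        for b in range(n_bumps):
            c0, c1 = int(round(b * width)), int(round((b + 1) * width))
            tau = np.linspace(0, 1, max(c1 - c0, 2), endpoint=False)
            amp = rng.uniform(0.7, 1.0)
            seg[c0:c1] = amp * 0.5 * (1 - np.cos(2 * np.pi * tau))
        end = min(s0 + cue_samples, n)
        traj[finger, s0:end] += seg[: end - s0]
        finger = (finger + 1) % 5
        t0 += block
    return np.clip(traj, 0.0, 1.0)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise, unit SD."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _band_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian carrier, unit SD."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.normal(0, 1, n))
    return x / x.std()


def generate_ecog(trajectories: np.ndarray, cfg: SynthConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Channels x time signal at ``cfg.fs`` with the planted band-power code.

    Assigned channels carry their finger's band-limited carrier, amplitude
    modulated by the finger's upsampled trajectory; unassigned channels are
    noise-only, and zero trajectories leave only the noise components.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = int(round(trajectories.shape[1] / cfg.glove_fs * cfg.fs))
    c = cfg.n_channels
    ecog = np.zeros((c, n))
    if n == 0:
        return ecog

    t_glove = np.arange(trajectories.shape[1]) / cfg.glove_fs
    t_hi = np.arange(n) / cfg.fs
    traj_hi = np.stack([np.interp(t_hi, t_glove, trajectories[f]) for f in range(5)])

    for f, chans in enumerate(cfg.assignments):
        lo, hi = cfg.bands[f]
        env = traj_hi[f]
        for ch in chans:
            carrier = _band_noise(n, lo, hi, cfg.fs, rng)
            ecog[ch] += cfg.carrier_amp * env * carrier

    shared = rng.normal(0, 1, n)
    for ch in range(c):
        ecog[ch] += cfg.pink_amp * _pink_noise(n, rng)
        phase = rng.uniform(0, 2 * np.pi)
        ecog[ch] += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t_hi + phase)
        ecog[ch] += cfg.shared_noise_amp * shared
    return ecog


def generate_recording(cfg: SynthConfig, subject_id: str = "synth") -> RawRecording:
    """One full-duration synthetic recording (seeded, deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    traj = generate_trajectories(cfg, rng)
    ecog = generate_ecog(traj, cfg, rng)
    return RawRecording(
        ecog=ecog, fingers=traj, fs_ecog=cfg.fs, fs_glove=cfg.glove_fs,
        subject_id=subject_id,
        meta={"synthetic": "planted band-power code", "seed": cfg.seed},
    )


def make_fixture(cfg: SynthConfig, out_dir=None) -> tuple[RawRecording, RawRecording]:
    """Chronological 2:1 train/test split of one synthetic recording.

    Writes ``train.h5`` and ``test.h5`` under ``out_dir`` when given; the
    files round-trip through the recording I/O.
    """
    rec = generate_recording(cfg)
    n_ecog = rec.ecog.shape[1]
    n_glove = rec.fingers.shape[1]
    cut_g = int(round(n_glove * 2 / 3))
    cut_e = int(round(cut_g / cfg.glove_fs * cfg.fs))

    def _part(sl_e, sl_g, tag):
        return RawRecording(
            ecog=rec.ecog[:, sl_e], fingers=rec.fingers[:, sl_g],
            fs_ecog=cfg.fs, fs_glove=cfg.glove_fs,
            subject_id=f"{rec.subject_id}-{tag}", meta=dict(rec.meta),
        )

    train = _part(slice(0, cut_e), slice(0, cut_g), "train")
    test = _part(slice(cut_e, n_ecog), slice(cut_g, n_glove), "test")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_recording(train, out / "train.h5")
        save_recording(test, out / "test.h5")
    return train, test
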