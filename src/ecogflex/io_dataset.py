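"""Recording containers and on-disk I/O.

The canonical in-memory object is :class:`RawRecording`: a paired ECoG matrix
(channels x time, typically 1 kHz) and a dataglove finger-flexion matrix
(5 fingers x time, typically 25 Hz).  Recordings enter the pipeline either
from the public competition release (MATLAB v5 ``.mat`` files) or from the
synthetic generator, and are persisted as HDF5 with datasets ``ecog`` and
``fingers`` plus scalar attributes — portable and partial-read friendly.

All arrays are channel-major: the channel/finger axis first, time last.
Channel order is preserved verbatim; the competition provider scrambled the
electrode montage, so row order carries no spatial meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.io import loadmat

__all__ = [
    "RawRecording",
    "FormatError",
    "FINGER_NAMES",
    "load_competition_recording",
    "save_recording",
    "load_recording",
    "save_spectrogram_arrays",
    "load_spectrogram_arrays",
]

#: Dataglove row order (competition convention).
FINGER_NAMES = ("thumb", "index", "middle", "ring", "little")

#: Default MATLAB variable names in the public competition release.
DEFAULT_MAT_VARS = {
    "train_ecog": "train_data",
    "train_fingers": "train_dg",
    "test_ecog": "test_data",
}


class FormatError(ValueError):
    """A file does not have the expected layout (missing/ill-shaped variables)."""


@dataclass
class RawRecording:
    """Paired ECoG and finger-trajectory recording.

    Parameters
    ----------
    ecog : ndarray, shape (n_channels, n_time_ecog)
        Cortical surface potentials, channel-major.
    fingers : ndarray, shape (5, n_time_glove)
        Dataglove flexion traces in :data:`FINGER_NAMES` order.  May have
        zero time samples (test split of the competition data).
    fs_ecog, fs_glove : float
        Sampling rates in Hz (1000 and 25 for the competition data).
    subject_id : str
        Free-form label.
    channel_ids : list of str
        One label per ECoG row; ``channel_ids[i]`` always indexes row *i*.
    meta : dict
        Provenance metadata (e.g. the provider's acquisition band-pass).
    """

    ecog: np.ndarray
    fingers: np.ndarray
    fs_ecog: float = 1000.0
    fs_glove: float = 25.0
    subject_id: str = "unknown"
    channel_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecog = np.asarray(self.ecog)
        self.fingers = np.asarray(self.fingers)
        if self.ecog.ndim != 2 or self.ecog.shape[0] < 1:
            raise ValueError("ecog must be a (n_channels >= 1, n_time) matrix")
        if self.fingers.ndim != 2 or self.fingers.shape[0] != 5:
            raise ValueError(
                f"fingers must have exactly 5 rows ({'/'.join(FINGER_NAMES)}); "
                f"got shape {self.fingers.shape}"
            )
        if not np.all(np.isfinite(self.ecog)):
            raise ValueError("non-finite values in ECoG matrix")
        if self.fingers.size and not np.all(np.isfinite(self.fingers)):
            raise ValueError("non-finite values in finger matrix")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.ecog.shape[0])]
        if len(self.channel_ids) != self.ecog.shape[0]:
            raise ValueError("channel_ids length must match number of ECoG rows")
        if self.fingers.shape[1]:
            # durations must agree to within one glove sample period
            d_ecog = self.ecog.shape[1] / self.fs_ecog
            d_glove = self.fingers.shape[1] / self.fs_glove
            if abs(d_ecog - d_glove) > 1.0 / self.fs_glove + 1e-9:
                raise ValueError(
                    f"ECoG duration {d_ecog:.3f}s and glove duration "
                    f"{d_glove:.3f}s differ by more than one glove sample"
                )

    @property
    def n_channels(self) -> int:
        return self.ecog.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (from the ECoG axis)."""
        return self.ecog.shape[1] / self.fs_ecog


def _channel_major(a: np.ndarray) -> np.ndarray:
    """Transpose a 2-D array to channel-major if it is stored time-major.

    Heuristic: neural recordings always have far more time samples than
    channels, so the long axis is time.
    """
    a = np.asarray(a)
    if a.ndim != 2:
        raise FormatError(f"expected a 2-D matrix, got shape {a.shape}")
    if a.shape[0] > a.shape[1]:
        return a.T
    return a


def load_competition_recording(
    path,
    split: str = "train",
    *,
    var_names: dict | None = None,
    subject_id: str | None = None,
) -> RawRecording:
    """Read one subject's MATLAB-v5 file from the public competition release.

    Parameters
    ----------
    path : path-like
        ``.mat`` file containing an ECoG matrix and, for ``split="train"``,
        a dataglove matrix.
    split : {"train", "test"}
        Which variables to look for.  The test split carries no glove data;
        ``fingers`` is returned with zero time samples.
    var_names : dict, optional
        Overrides for the MATLAB variable names; defaults match the public
        release (``train_data``, ``train_dg``, ``test_data``).

    Returns
    -------
    RawRecording
        With ``fs_ecog=1000`` and ``fs_glove=25``, matrices channel-major.
    """
    if split not in ("train", "test"):
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    names = dict(DEFAULT_MAT_VARS)
    if var_names:
        names.update(var_names)
    try:
        mat = loadmat(str(path))
    except Exception as exc:  # noqa: BLE001 - surface with path context
        raise FormatError(f"cannot read MATLAB file {path}: {exc}") from exc

    ecog_key = names["train_ecog"] if split == "train" else names["test_ecog"]
    if ecog_key not in mat:
        raise FormatError(f"{path}: missing expected ECoG variable {ecog_key!r}")
    ecog = _channel_major(np.asarray(mat[ecog_key], dtype=np.float64))
    if not np.all(np.isfinite(ecog)):
        raise ValueError(f"{path}: NaN/Inf in ECoG variable {ecog_key!r}")

    if split == "train":
        dg_key = names["train_fingers"]
        if dg_key not in mat:
            raise FormatError(f"{path}: missing expected dataglove variable {dg_key!r}")
        fingers = _channel_major(np.asarray(mat[dg_key], dtype=np.float64))
    else:
        fingers = np.empty((5, 0))

    return RawRecording(
        ecog=ecog,
        fingers=fingers,
        fs_ecog=1000.0,
        fs_glove=25.0,
        subject_id=subject_id or str(path),
        meta={"split": split, "provider_bandpass_hz": (0.15, 200.0)},
    )


def save_recording(rec: RawRecording, path) -> None:
    """Write a recording to HDF5 (lossless round trip of all fields)."""
    try:
        with h5py.File(str(path), "w") as f:
            f.create_dataset("ecog", data=rec.ecog)
            f.create_dataset("fingers", data=rec.fingers)
            f.attrs["fs_ecog"] = rec.fs_ecog
            f.attrs["fs_glove"] = rec.fs_glove
            f.attrs["subject_id"] = rec.subject_id
            f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
            for k, v in rec.meta.items():
                f.attrs[f"meta_{k}"] = np.asarray(v) if not isinstance(v, str) else v
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc


def load_recording(path) -> RawRecording:
    """Read a recording written by :func:`save_recording`."""
    try:
        with h5py.File(str(path), "r") as f:
            if "ecog" not in f or "fingers" not in f:
                raise FormatError(f"{path}: not a recording file (missing datasets)")
            meta = {}
            for k, v in f.attrs.items():
                if k.startswith("meta_"):
                    if isinstance(v, bytes):
                        v = v.decode()
                    elif isinstance(v, np.ndarray):
                        v = tuple(v.tolist()) if v.ndim else v.item()
                    meta[k[5:]] = v
            return RawRecording(
                ecog=f["ecog"][()],
                fingers=f["fingers"][()],
                fs_ecog=float(f.attrs["fs_ecog"]),
                fs_glove=float(f.attrs["fs_glove"]),
                subject_id=str(f.attrs["subject_id"]),
                channel_ids=[str(c) for c in f.attrs["channel_ids"]],
                meta=meta,
            )
    except OSError as exc:
        raise FormatError(f"cannot read recording from {path}: {exc}") from exc


def save_spectrogram_arrays(path, values, freqs, fs, channel_ids, fingers=None, fingers_fs=None):
    """Persist a (c, f, t) spectrogram — and optionally aligned targets — to HDF5."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("values", data=values)
        f.create_dataset("freqs", data=np.asarray(freqs, dtype=float))
        f.attrs["fs"] = float(fs)
        f.attrs["channel_ids"] = [str(c) for c in channel_ids]
        if fingers is not None:
            f.create_dataset("fingers", data=fingers)
            f.attrs["fingers_fs"] = float(fingers_fs if fingers_fs is not None else fs)


def load_spectrogram_arrays(path):
    """Inverse of :func:`save_spectrogram_arrays`.

    Returns ``(values, freqs, fs, channel_ids, fingers_or_None)``.
    """
    with h5py.File(str(path), "r") as f:
        if "values" not in f or "freqs" not in f:
            raise FormatError(f"{path}: not a spectrogram file (missing datasets)")
        fingers = f["fingers"][()] if "fingers" in f else None
        return (
            f["values"][()],
            f["freqs"][()],
            float(f.attrs["fs"]),
            [str(c) for c in f.attrs["channel_ids"]],
            fingers,
        )
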