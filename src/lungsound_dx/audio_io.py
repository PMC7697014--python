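"""Reading, writing and normalizing mono lung-sound recordings.

Recordings are PCM WAV files (the respiratory-sound databases this package
targets distribute 16-bit PCM at a nominal 44.1 kHz).  Feature tables are
plain CSV with one header row of feature names plus a final ``label`` column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

CLASSES = ("COPD", "pneumonia", "healthy")

__all__ = [
    "CLASSES",
    "AudioRecording",
    "FeatureTable",
    "read_wav",
    "write_wav",
    "write_features",
    "read_features",
]


@dataclass
class AudioRecording:
    """A mono amplitude sequence with its sampling rate and optional label.

    Parameters
    ----------
    samples
        Real-valued amplitudes; peak-normalized recordings lie in [-1, 1].
    fs
        Sampling rate in Hz, > 0.
    label
        Optional class in {"COPD", "pneumonia", "healthy"}.
    source_id
        Free-text identifier (file stem, synthetic seed tag, ...).
    """

    samples: np.ndarray
    fs: float
    label: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size == 0:
            raise ValueError("AudioRecording requires a non-empty sample sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}; expected one of {CLASSES}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.fs

    def normalized(self) -> "AudioRecording":
        """Return a copy peak-normalized to max |sample| = 1 (no-op on silence)."""
        peak = np.max(np.abs(self.samples))
        samples = self.samples / peak if peak > 0 else self.samples.copy()
        return AudioRecording(samples, self.fs, self.label, self.source_id)


@dataclass
class FeatureTable:
    """Recordings x features matrix with labels and per-row provenance."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, len(self.feature_names))
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = list(self.feature_names)
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"row count {self.matrix.shape[0]} != label count {self.labels.shape[0]}"
            )
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError(
                f"column count {self.matrix.shape[1]} != feature-name count "
                f"{len(self.feature_names)}"
            )
        if self.provenance is None:
            self.provenance = np.array(["original"] * self.matrix.shape[0], dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset by feature name, preserving the requested order."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.matrix[:, idx], self.labels, list(names), self.provenance)


def read_wav(path: str | os.PathLike, normalize: bool = True) -> AudioRecording:
    """Read a PCM WAV file as a mono :class:`AudioRecording`.

    Stereo files are averaged to mono.  Integer PCM is scaled by its type's
    full-scale value; with ``normalize`` the result is additionally
    peak-normalized (an all-zero file is returned as-is).
    """
    try:
        fs, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise ValueError(f"unsupported or corrupt WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        samples = data.mean(axis=1, dtype=np.float64)
    else:
        samples = data.astype(np.float64)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        samples = samples / max(abs(info.min), info.max)
    rec = AudioRecording(samples, float(fs), source_id=os.path.splitext(os.path.basename(path))[0])
    return rec.normalized() if normalize else rec


def write_wav(rec: AudioRecording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), int(round(rec.fs)), pcm)


def write_features(table: FeatureTable, path: str | os.PathLike) -> None:
    """Persist a feature table as CSV: feature columns, then ``label`` and
    ``provenance`` columns.  Values round-trip at 12 significant digits."""
    df = pd.DataFrame(table.matrix, columns=table.feature_names)
    df["label"] = table.labels
    df["provenance"] = table.provenance
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | os.PathLike) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_features`."""
    df = pd.read_csv(path)
    meta = [c for c in ("label", "provenance") if c in df.columns]
    names = [c for c in df.columns if c not in meta]
    labels = df["label"].to_numpy(dtype=object) if "label" in meta else np.array([None] * len(df))
    prov = (
        df["provenance"].to_numpy(dtype=object)
        if "provenance" in meta
        else None
    )
    matrix = df[names].to_numpy(dtype=np.float64).reshape(len(df), len(names))
    return FeatureTable(matrix, labels, names, prov)
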