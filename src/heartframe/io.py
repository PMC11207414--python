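"""WAV audio and CSV table input/output.

The whole pipeline works at a fixed 2 kHz sample rate (the rate of the
source recordings); any input audio is resampled on ingest with an
antialiasing filter. Feature tables and manifests are plain CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

WORKING_FS = 2000
"""Working sample rate (Hz) for the whole pipeline."""

MANIFEST_REQUIRED = ("path", "signal_id", "label")
TABLE_KEY_COLUMNS = ("signal_id", "frame_index", "label", "split")


@dataclass
class AudioSignal:
    """A mono heart-sound recording.

    samples are dimensionless amplitudes in [-1, 1]; ``label`` is the
    class name ("" when unlabeled); ``subject_meta`` carries optional
    per-subject annotations such as age and sex.
    """

    samples: np.ndarray
    fs: float
    signal_id: str = ""
    label: str = ""
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sample rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal holds mono (1-D) sample arrays")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        """Copy of this signal with ``samples`` replaced."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class Manifest:
    """Association between audio files, signal ids and class labels."""

    entries: list

    def __post_init__(self) -> None:
        ids = [e["signal_id"] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("manifest signal_id values must be unique")

    def __len__(self) -> int:
        return len(self.entries)


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file as a mono float signal scaled to [-1, 1).

    Integer PCM is scaled by the full-scale magnitude of its dtype
    (e.g. int16 -32768 maps to -1.0). Multichannel input is averaged
    to mono with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fs, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max + 1))
        if info.min == 0:  # unsigned PCM (uint8): recentre
            half = (info.max + 1) / 2
            samples = (data.astype(np.float64) - half) / half
        else:
            samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim > 1:
        warnings.warn(f"{path.name}: {samples.shape[1]}-channel audio averaged to mono")
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, fs=float(fs), signal_id=path.stem)


def write_wav(signal: AudioSignal, path, bit_depth: int = 16):
    """Write ``signal`` as integer PCM WAV. Returns the path."""
    samples = signal.samples
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain NaN or infinity")
    if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-12:
        raise ValueError("samples out of range [-1, 1]")
    if bit_depth == 16:
        dtype, full = np.int16, 32768
    elif bit_depth == 32:
        dtype, full = np.int32, 2147483648
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")
    quantized = np.clip(np.round(samples * full), -full, full - 1).astype(dtype)
    wavfile.write(Path(path), int(round(signal.fs)), quantized)
    return Path(path)


def resample(signal: AudioSignal, target_fs: float = WORKING_FS) -> AudioSignal:
    """Resample to ``target_fs`` with a polyphase antialiasing filter.

    A signal already at the target rate is returned unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if signal.fs == target_fs:
        return signal
    ratio = Fraction(target_fs / signal.fs).limit_denominator(10000)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return replace(signal, samples=out, fs=float(target_fs))


def read_manifest(path) -> Manifest:
    """Load a manifest CSV (columns path, signal_id, label[, extra...])."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    extra = [c for c in df.columns if c not in MANIFEST_REQUIRED]
    entries = []
    for _, row in df.iterrows():
        entries.append(
            {
                "path": row["path"],
                "signal_id": row["signal_id"],
                "label": row["label"],
                "subject_meta": {c: row[c] for c in extra if row[c] != ""},
            }
        )
    return Manifest(entries=entries)


def write_manifest(manifest: Manifest, path):
    """Write a manifest back to CSV."""
    rows = []
    for e in manifest.entries:
        row = {k: e[k] for k in MANIFEST_REQUIRED}
        row.update(e.get("subject_meta", {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_feature_table(table: pd.DataFrame, path):
    """Write a frame-feature table to CSV at full float precision."""
    missing = [c for c in TABLE_KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    dup = table.duplicated(subset=["signal_id", "frame_index"])
    if dup.any():
        raise ValueError("duplicate (signal_id, frame_index) rows")
    table.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_feature_table(path) -> pd.DataFrame:
    """Read a frame-feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if df.duplicated(subset=["signal_id", "frame_index"]).any():
        raise ValueError("duplicate (signal_id, frame_index) rows")
    df["label"] = df["label"].astype(str)
    df["split"] = df["split"].astype(str)
    return df
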