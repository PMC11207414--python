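"""Framing and leakage-aware dataset construction.

Signals are cut into 5 s windows with a 1 s shift (overlapping frames
multiply the number of training observations) and every frame inherits
its parent signal's label. Two train/test strategies are provided:

* frame-level: frames of all signals are pooled, balanced by random
  removal down to the smallest class, then split 80/20 per class. Frames
  of one signal can land in both sets, so overlap leaks information and
  inflates test accuracy.
* signal-level: whole signals are split 80/20 per class first, then
  framed and balanced within each side, so no signal contributes frames
  to both sets. This is the realistic new-patient protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .io import AudioSignal
from .preprocess import preprocess_signal

BOOKKEEPING_COLUMNS = ["signal_id", "frame_index", "label", "split"]

DEFAULT_WINDOW = 5.0  # s
DEFAULT_SHIFT = 1.0  # s


@dataclass
class Frame:
    """One fixed-length window of a parent signal."""

    samples: np.ndarray
    signal_id: str
    frame_index: int
    start_time: float
    label: str = ""
    fs: float = 2000.0


@dataclass
class SplitConfig:
    strategy: str = "frame_level"  # or "signal_level"
    train_fraction: float = 0.8
    window: float = DEFAULT_WINDOW
    shift: float = DEFAULT_SHIFT
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.strategy not in ("frame_level", "signal_level"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def frame_signal(
    signal: AudioSignal, window: float = DEFAULT_WINDOW, shift: float = DEFAULT_SHIFT
) -> list[Frame]:
    """Cut a signal into overlapping fixed-length frames.

    Yields floor((duration - window)/shift) + 1 frames for signals at
    least one window long, none otherwise (short tails are discarded).
    """
    if window <= 0 or shift <= 0:
        raise ValueError("window and shift must be positive")
    n_win = int(round(window * signal.fs))
    n_shift = int(round(shift * signal.fs))
    n = len(signal.samples)
    frames = []
    idx = 0
    for start in range(0, n - n_win + 1, n_shift):
        frames.append(
            Frame(
                samples=signal.samples[start : start + n_win],
                signal_id=signal.signal_id,
                frame_index=idx,
                start_time=start / signal.fs,
                label=signal.label,
                fs=signal.fs,
            )
        )
        idx += 1
    return frames


def extract_frame_table(frames: list[Frame]) -> pd.DataFrame:
    """Feature table (bookkeeping + 33 feature columns) for a frame list."""
    rows = []
    for fr in frames:
        row = {
            "signal_id": fr.signal_id,
            "frame_index": fr.frame_index,
            "label": fr.label,
            "split": "none",
        }
        row.update(extract_features(fr.samples, fr.fs))
        rows.append(row)
    return pd.DataFrame(rows, columns=BOOKKEEPING_COLUMNS + FEATURE_NAMES)


def balance_frames(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalize class counts by randomly removing excess rows.

    Every class ends at exactly the minimum class count; the minimum
    class itself is never touched. Deterministic per seed.
    """
    counts = table["label"].value_counts()
    if len(counts) == 0 or (counts == 0).any():
        raise ValueError("every class must have at least one row")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    kept = []
    for label in sorted(counts.index):
        cls = table[table["label"] == label]
        if len(cls) > n_min:
            keep_idx = rng.choice(cls.index.to_numpy(), size=n_min, replace=False)
            cls = cls.loc[np.sort(keep_idx)]
        kept.append(cls)
    return pd.concat(kept, ignore_index=True)


def split_frame_level(table: pd.DataFrame, config: SplitConfig) -> pd.DataFrame:
    """Tag a balanced frame table with 80/20 train/test per class.

    floor(train_fraction · n) rows per class go to train, the remainder
    to test, after a seeded per-class shuffle.
    """
    counts = table["label"].value_counts()
    rng = np.random.default_rng(config.seed)
    out = table.copy()
    out["split"] = "none"
    for label in sorted(counts.index):
        idx = out.index[out["label"] == label].to_numpy()
        n_train = int(np.floor(config.train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(f"class {label!r} too small to populate both splits")
        perm = rng.permutation(idx)
        out.loc[perm[:n_train], "split"] = "train"
        out.loc[perm[n_train:], "split"] = "test"
    return out


def split_signals_by_class(signals, train_fraction: float, seed: int):
    """80/20 signal-id partition per class (the leakage-free first step)."""
    by_class: dict[str, list] = {}
    for sig in signals:
        by_class.setdefault(sig.label, []).append(sig)
    rng = np.random.default_rng(seed)
    train_ids, test_ids = set(), set()
    for label in sorted(by_class):
        group = sorted(by_class[label], key=lambda s: s.signal_id)
        if len(group) < 2:
            raise ValueError(f"class {label!r} needs at least 2 signals for a signal-level split")
        n_train = int(np.floor(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        perm = rng.permutation(len(group))
        for i in perm[:n_train]:
            train_ids.add(group[i].signal_id)
        for i in perm[n_train:]:
            test_ids.add(group[i].signal_id)
    return train_ids, test_ids


def split_signal_level(table: pd.DataFrame, signals, config: SplitConfig) -> pd.DataFrame:
    """Tag frames so no signal_id occurs in both splits, then balance
    each side independently."""
    train_ids, test_ids = split_signals_by_class(signals, config.train_fraction, config.seed)
    out = table.copy()
    out["split"] = np.where(out["signal_id"].isin(list(train_ids)), "train", "test")
    parts = []
    for split_name, offset in (("train", 1), ("test", 2)):
        part = out[out["split"] == split_name]
        parts.append(balance_frames(part, seed=config.seed + offset))
    result = pd.concat(parts, ignore_index=True)
    overlap = set(result.loc[result["split"] == "train", "signal_id"]) & set(
        result.loc[result["split"] == "test", "signal_id"]
    )
    assert not overlap, f"signal leakage across splits: {sorted(overlap)[:5]}"
    return result


def build_dataset(
    signals, mode: str = "multiclass", config: SplitConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess, frame, extract features and split.

    Returns (train table, test table); both carry the 33 feature columns
    plus bookkeeping, and are fully determined by ``config.seed``.
    """
    config = config or SplitConfig()
    processed = [preprocess_signal(sig, mode=mode) for sig in signals]
    frames: list[Frame] = []
    for sig in processed:
        frames.extend(frame_signal(sig, config.window, config.shift))
    table = extract_frame_table(frames)
    if config.strategy == "frame_level":
        table = balance_frames(table, seed=config.seed)
        table = split_frame_level(table, config)
    else:
        table = split_signal_level(table, signals, config)
    train = table[table["split"] == "train"].reset_index(drop=True)
    test = table[table["split"] == "test"].reset_index(drop=True)
    return train, test


def stratified_fold_indices(labels, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Per-row fold assignment (0..folds-1), stratified by class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if len(idx) < folds:
            raise ValueError(f"class {label!r} has fewer rows than folds")
        perm = rng.permutation(idx)
        for fold, chunk in enumerate(np.array_split(perm, folds)):
            assignment[chunk] = fold
    return assignment
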