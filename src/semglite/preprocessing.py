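"""Windowing, trial-level splitting, and training-set normalization.

Recordings are cut into fixed-length windows with 50% overlap by default
(250 ms at 1000 Hz). Windows that straddle a label change are dropped, so
every emitted window is label-homogeneous. Normalization is zero-mean /
unit-variance with statistics pooled over the *training* windows only; the
same statistics are applied unchanged to validation data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import RawRecording

__all__ = [
    "Window",
    "NormStats",
    "SplitSpec",
    "segment_windows",
    "split_by_trial",
    "fit_normalizer",
    "apply_normalizer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """One fixed-length segment with its class label and provenance tags."""

    x: np.ndarray
    label: int
    subject_id: int = 0
    session_id: int = 0
    trial_id: int = 0

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class NormStats:
    """Pooled mean/std of the training windows; std must be positive."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"std must be positive, got {self.std}")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validate trial-id sets (e.g. train {1,3,4}, validate {2})."""

    train_trials: frozenset[int]
    validate_trials: frozenset[int]

    def __init__(self, train_trials, validate_trials):
        object.__setattr__(self, "train_trials", frozenset(train_trials))
        object.__setattr__(self, "validate_trials", frozenset(validate_trials))
        if not self.train_trials or not self.validate_trials:
            raise ValueError("train and validate trial sets must be non-empty")
        overlap = self.train_trials & self.validate_trials
        if overlap:
            raise ValueError(f"train/validate trial sets overlap: {sorted(overlap)}")


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def segment_windows(
    rec: RawRecording,
    window_ms: float = 250.0,
    overlap_frac: float = 0.5,
    drop_rest: bool = True,
) -> list[Window]:
    """Cut a recording into label-homogeneous overlapping windows.

    The window length is W = round(window_ms * fs / 1000) samples and the
    hop is step = round(W * (1 - overlap_frac)). Within each maximal run of
    constant (label, trial) the window starts form the arithmetic progression
    0, step, 2*step, ... relative to the run start; windows that would cross
    a run boundary are never emitted. Rest windows (label 0) are excluded
    unless ``drop_rest`` is False.

    Returns an empty list (with a logged warning) when no homogeneous run is
    long enough to hold one window.
    """
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    W = _round_half_up(window_ms * rec.fs / 1000.0)
    if W < 1:
        raise ValueError("window shorter than one sample")
    step = max(_round_half_up(W * (1.0 - overlap_frac)), 1)

    labels = rec.trial_labels
    trials = rec.trial_ids
    # run boundaries where either label or trial id changes
    change = np.flatnonzero((np.diff(labels) != 0) | (np.diff(trials) != 0)) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])

    windows: list[Window] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        lab = int(labels[lo])
        if drop_rest and lab == 0:
            continue
        for start in range(lo, hi - W + 1, step):
            windows.append(
                Window(
                    x=rec.samples[start:start + W].copy(),
                    label=lab,
                    subject_id=rec.subject_id,
                    session_id=rec.session_id,
                    trial_id=int(trials[lo]),
                )
            )
    if not windows:
        logger.warning(
            "no homogeneous segment of length >= %d samples; returning no windows", W
        )
    return windows


def split_by_trial(
    windows: list[Window], spec: SplitSpec
) -> tuple[list[Window], list[Window]]:
    """Partition windows into (train, validate) by their trial id.

    Every window's trial must appear in exactly one of the two sets;
    an uncovered trial id raises a configuration error naming it.
    """
    train, val = [], []
    for w in windows:
        if w.trial_id in spec.train_trials:
            train.append(w)
        elif w.trial_id in spec.validate_trials:
            val.append(w)
        else:
            raise ValueError(
                f"trial_id {w.trial_id} is in neither the train nor the validate set"
            )
    return train, val


def fit_normalizer(train: list[Window]) -> NormStats:
    """Pooled zero-mean/unit-variance statistics from training windows only."""
    if len(train) < 2:
        raise ValueError("need at least 2 training windows to fit normalization")
    pooled = np.concatenate([w.x for w in train])
    mean = float(pooled.mean())
    std = float(pooled.std())
    if std <= 0:
        raise ValueError("training signal is constant; normalization is degenerate")
    return NormStats(mean=mean, std=std)


def apply_normalizer(stats: NormStats, w: Window) -> Window:
    """Standardize one window with (training-set) stats; provenance is kept."""
    return replace(w, x=(w.x - stats.mean) / stats.std)
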