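"""Scoring formulas for the behavioral and imaging assays.

Two small analyses: the hermaphrodite-preference choice index computed from
worm counts on pheromone-bearing vs pheromone-free food lawns, and calcium
event counting from a fluorescence time series (events are threshold
crossings of dF/F0 relative to a baseline established from a fixed fraction
of frames).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LawnCounts",
    "choice_index",
    "CalciumTrace",
    "CalciumEvents",
    "count_calcium_events",
    "read_trace",
]


@dataclass(frozen=True)
class LawnCounts:
    """Worms counted on lawns with pheromone vs lawns without."""

    n_with: int
    n_without: int

    def __post_init__(self) -> None:
        if self.n_with < 0 or self.n_without < 0:
            raise ValueError("counts must be non-negative")


def choice_index(counts: LawnCounts) -> float:
    """(n_with - n_without) / (n_with + n_without), in [-1, 1]."""
    total = counts.n_with + counts.n_without
    if total == 0:
        raise ValueError("choice index is undefined when no worms were counted")
    return (counts.n_with - counts.n_without) / total


@dataclass
class CalciumTrace:
    """Per-frame fluorescence (arbitrary units) at a fixed frame rate."""

    f: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 20:
            raise ValueError("trace must be a 1-D series of at least 20 frames")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def duration_minutes(self) -> float:
        return self.f.size / self.frame_rate / 60.0


@dataclass(frozen=True)
class CalciumEvents:
    count: int
    per_minute: float
    f0: float


def count_calcium_events(
    trace: CalciumTrace,
    baseline_fraction: float = 0.05,
    threshold: float = 1.0,
    baseline: str = "first",
) -> CalciumEvents:
    """Count calcium events as maximal contiguous runs of frames with
    dF/F0 > threshold.

    F0 is the mean of the first ceil(baseline_fraction * n) frames
    (``baseline="first"``) or of the dimmest such frames
    (``baseline="dimmest"``).  Events separated by even a single sub-threshold
    frame count as distinct — no gap merging.
    """
    if not 0.0 < baseline_fraction < 1.0:
        raise ValueError("baseline_fraction must lie in (0, 1)")
    if baseline not in ("first", "dimmest"):
        raise ValueError("baseline must be 'first' or 'dimmest'")
    n0 = math.ceil(baseline_fraction * trace.f.size)
    if baseline == "first":
        f0 = float(trace.f[:n0].mean())
    else:
        f0 = float(np.sort(trace.f)[:n0].mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0={f0:g} is non-positive; dF/F0 is undefined")
    ratio = (trace.f - f0) / f0
    above = ratio > threshold
    # rising edges of the boolean mask = event starts
    starts = np.flatnonzero(np.diff(np.concatenate(([False], above)).astype(int)) == 1)
    count = int(starts.size)
    return CalciumEvents(count=count, per_minute=count / trace.duration_minutes, f0=f0)


def read_trace(path: str | Path, frame_rate: float) -> CalciumTrace:
    """Read a single-column (F) or two-column (time, F) delimited text file."""
    df = pd.read_csv(path, sep=r"[,\t; ]+", engine="python", header=None, comment="#")
    first = df.iloc[0]
    try:
        [float(x) for x in first]
    except (TypeError, ValueError):  # header row
        df = df.iloc[1:]
    values = df.astype(float).to_numpy()
    f = values[:, -1]
    return CalciumTrace(f=f, frame_rate=frame_rate)
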