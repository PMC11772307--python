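"""Activity classification from longitudinal acceleration.

The degree of locomotor activity is indexed by the standard deviation of
longitudinal acceleration over each whole minute of the record.  Minutes
with SD strictly below 0.5 m s^-2 are "resting"; 0.5 m s^-2 and above is
"moving" (the boundary value itself classifies as moving, reading the
"lower than ... otherwise" rule strictly).  Maximal runs of the same status
lasting at least 2 minutes become phases; shorter runs belong to no phase at
all — they are excluded from the heart-rate statistics rather than merged
into a neighbour.

The minute grid is aligned to the deployment clock origin and
non-overlapping; an incomplete trailing minute is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .channels import Channel
from .exceptions import ValidationError
from .simulate import MOVING, RESTING

__all__ = [
    "MinuteSDSeries",
    "Phase",
    "minute_sd",
    "classify_minutes",
    "segment_phases",
]


@dataclass
class MinuteSDSeries:
    """Per-minute acceleration SD (m s^-2), indexed by minute number from
    the record start; one value per complete minute."""

    values: np.ndarray
    source_rate: float
    start_minute: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and self.values.min() < 0:
            raise ValidationError("minute SDs must be non-negative")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Phase:
    """A maximal classified interval: [start_min, end_min) whole minutes of
    one status."""

    status: str
    start_min: int
    end_min: int

    def __post_init__(self):
        if self.status not in (RESTING, MOVING):
            raise ValidationError(f"unknown phase status {self.status!r}")
        if not self.end_min > self.start_min:
            raise ValidationError("phase must span at least one minute")

    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min

    @property
    def start_s(self) -> float:
        return self.start_min * 60.0

    @property
    def end_s(self) -> float:
        return self.end_min * 60.0


def minute_sd(accel: Channel, ddof: int = 1) -> MinuteSDSeries:
    """Sample SD of acceleration for every complete minute.

    Minute ``m`` collects the samples whose time falls in
    ``[60 m, 60 (m+1))`` on the deployment clock; minutes with fewer samples
    than a full minute's worth (leading minutes before a staggered start, or
    the trailing remainder) are excluded.  A record shorter than one minute
    yields an empty series with a warning.
    """
    if accel.rate < 1:
        raise ValidationError("acceleration rate must be >= 1 Hz")
    expected = int(round(accel.rate * 60))
    n = accel.n
    if accel.t0 == 0 and abs(accel.rate * 60 - expected) < 1e-9:
        # fast path: contiguous full minutes from the origin
        n_min = n // expected
        if n_min == 0:
            warnings.warn("record shorter than one minute; empty SD series")
            return MinuteSDSeries(np.empty(0), source_rate=accel.rate)
        x = accel.values[: n_min * expected].reshape(n_min, expected)
        sds = x.std(axis=1, ddof=ddof)
        return MinuteSDSeries(sds, source_rate=accel.rate)

    t = accel.times()
    minute = np.floor(t / 60.0).astype(int)
    counts = np.bincount(minute - minute.min())
    first = int(minute.min())
    sds, kept_start = [], None
    for m in range(first, int(minute.max()) + 1):
        c = counts[m - first]
        if c != expected:
            if kept_start is not None:
                break  # only the leading/trailing partials are tolerated
            continue
        if kept_start is None:
            kept_start = m
        sel = accel.values[minute == m]
        sds.append(sel.std(ddof=ddof))
    if not sds:
        warnings.warn("record contains no complete minute; empty SD series")
        return MinuteSDSeries(np.empty(0), source_rate=accel.rate)
    return MinuteSDSeries(np.asarray(sds), source_rate=accel.rate,
                          start_minute=int(kept_start))


def classify_minutes(sds: MinuteSDSeries, threshold: float = 0.5) -> np.ndarray:
    """Per-minute status: SD strictly below the threshold is resting,
    otherwise moving (the boundary value is moving)."""
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    return np.where(sds.values < threshold, RESTING, MOVING)


def segment_phases(statuses: np.ndarray, min_minutes: int = 2) -> list[Phase]:
    """Maximal same-status runs of at least ``min_minutes`` become phases.

    Shorter runs are unclassified: they belong to no phase.  A run is kept
    whole — a 5-minute run is one 5-minute phase, never stacked shorter
    phases.  Output is ordered by start minute.
    """
    if min_minutes < 1:
        raise ValidationError("min_minutes must be >= 1")
    statuses = np.asarray(statuses)
    n = statuses.size
    if n == 0:
        return []
    change = np.flatnonzero(statuses[1:] != statuses[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [
        Phase(status=str(statuses[s]), start_min=int(s), end_min=int(e))
        for s, e in zip(starts, ends)
        if e - s >= min_minutes
    ]
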