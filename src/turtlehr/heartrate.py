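"""Phase-conditioned heart-rate statistics.

Heart rate is an event rate, not an RR-interval average: for each phase it
is the number of detected R waves falling in the phase divided by the phase
duration in minutes.  Before any rate is computed, the first hours after the
animal is returned to the water (default 12 h) are excluded to eliminate
handling effects — events before the cutoff are dropped and any phase that
starts before the cutoff is dropped entirely (truncating it could create a
sub-minimum phase).  Per-status grand means are unweighted means over phase
rates, reported with the sample SD and the number of contributing phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import Phase
from .ecg import RWaveTrain
from .exceptions import ValidationError
from .simulate import MOVING, RESTING

__all__ = [
    "PhaseHeartRate",
    "StatusStats",
    "HeartRateSummary",
    "exclude_handling",
    "phase_heart_rate",
    "summarize",
]


@dataclass(frozen=True)
class PhaseHeartRate:
    """R-wave count and resulting rate (beats min^-1) for one phase."""

    phase: Phase
    count: int
    turtle_id: str | None = None

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError("count must be >= 0")

    @property
    def heart_rate_bpm(self) -> float:
        return self.count / self.phase.duration_min


@dataclass(frozen=True)
class StatusStats:
    """Grand mean, sample SD and phase count for one status.  SD is NaN
    (undefined) when fewer than two phases contribute."""

    mean_bpm: float
    sd_bpm: float
    n: int


@dataclass
class HeartRateSummary:
    """Per-status grand means with the exclusion window that was applied."""

    stats: dict[str, StatusStats] = field(default_factory=dict)
    exclusion_hours: float | None = None
    pooling: str = "pooled"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"status": s, "mean_bpm": st.mean_bpm, "sd_bpm": st.sd_bpm, "n": st.n}
            for s, st in self.stats.items()
        ]
        return pd.DataFrame(rows, columns=["status", "mean_bpm", "sd_bpm", "n"])


def exclude_handling(
    train: RWaveTrain,
    phases: list[Phase],
    hours: float = 12.0,
) -> tuple[RWaveTrain, list[Phase]]:
    """Drop events and phases from the post-handling window.

    R waves with time strictly before ``hours`` (on the deployment clock)
    are removed; an event exactly at the cutoff is retained.  A phase is
    kept only if it *starts* at or after the cutoff — straddling phases are
    dropped whole.  Warns when nothing survives.
    """
    if hours < 0:
        raise ValidationError("exclusion hours must be >= 0")
    cutoff_s = hours * 3600.0
    keep = train.times >= cutoff_s
    trimmed = RWaveTrain(train.times[keep], source=train.source, params=dict(train.params))
    kept_phases = [p for p in phases if p.start_s >= cutoff_s]
    if (phases or train.n) and not kept_phases and trimmed.n == 0:
        warnings.warn(
            f"record lies entirely within the {hours}-h handling-exclusion window; "
            "no analyzable data remain"
        )
    return trimmed, kept_phases


def phase_heart_rate(train: RWaveTrain, phase: Phase, turtle_id: str | None = None) -> PhaseHeartRate:
    """Count R waves in the phase's half-open interval [start, end) and form
    the rate.  An event exactly at the phase end belongs to the following
    interval, so the timeline is partitioned without double counting."""
    count = train.count_in(phase.start_s, phase.end_s)
    return PhaseHeartRate(phase=phase, count=count, turtle_id=turtle_id)


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    n = values.size
    if n == 0:
        return (math.nan, math.nan, 0)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n >= 2 else math.nan
    return mean, sd, int(n)


def summarize(
    phase_hrs: list[PhaseHeartRate],
    exclusion_hours: float | None = None,
    pooling: str = "pooled",
) -> HeartRateSummary:
    """Per-status grand mean, SD and n over phase heart rates.

    ``pooling="pooled"`` (default) treats every phase of every animal as one
    observation.  ``pooling="per_individual"`` first averages phases within
    each ``turtle_id`` and then takes mean/SD across individuals; it requires
    every entry to carry a turtle_id.  Empty input yields an empty summary.
    """
    if pooling not in ("pooled", "per_individual"):
        raise ValidationError(f"unknown pooling mode {pooling!r}")
    summary = HeartRateSummary(exclusion_hours=exclusion_hours, pooling=pooling)
    for status in (RESTING, MOVING):
        items = [ph for ph in phase_hrs if ph.phase.status == status]
        if not items:
            continue
        if pooling == "pooled":
            vals = np.array([ph.heart_rate_bpm for ph in items])
        else:
            if any(ph.turtle_id is None for ph in items):
                raise ValidationError(
                    "per_individual pooling requires a turtle_id on every phase rate"
                )
            per_id: dict[str, list[float]] = {}
            for ph in items:
                per_id.setdefault(ph.turtle_id, []).append(ph.heart_rate_bpm)
            vals = np.array([float(np.mean(v)) for v in per_id.values()])
        mean, sd, n = _mean_sd(vals)
        summary.stats[status] = StatusStats(mean_bpm=mean, sd_bpm=sd, n=n)
    return summary
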