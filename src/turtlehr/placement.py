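"""Electrode-placement evaluation summaries.

Each animal's signal at a given plastron placement (A: humeral scute, B:
gular scute, C: intergular scute, closest to the neck) is graded
undetectable / unclear / clear.  The summary reports, per placement, grade
counts and percentages over the number of animals *evaluated at that
placement* (not every animal was tested at every position), with
percentages rounded half-up to one decimal.  A second statistic captures the
key practical finding: the fraction of study animals that were unclear at
the conventional placement A but clear at placement C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .channels import PLACEMENTS
from .ecg import GRADES
from .exceptions import ValidationError

__all__ = [
    "PlacementEvaluation",
    "PlacementSummary",
    "summarize_placements",
    "cross_position_improvement",
    "read_evaluations",
]


@dataclass(frozen=True)
class PlacementEvaluation:
    """One (turtle, placement) grade."""

    turtle_id: str
    placement: str
    grade: str

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")
        if self.grade not in GRADES:
            raise ValidationError(f"unknown grade {self.grade!r}; expected one of {GRADES}")


def _round1(x: float) -> float:
    """Round half-up to one decimal (matches hand-rounded printed tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PlacementSummary:
    """Grade counts, totals and one-decimal percentages per placement."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: grade rows, one count and one percentage
        column per placement evaluated."""
        cols: dict[str, list] = {}
        for p in sorted(self.counts):
            cols[f"{p}_n"] = [self.counts[p][g] for g in GRADES]
            cols[f"{p}_pct"] = [self.percentages[p][g] for g in GRADES]
        return pd.DataFrame(cols, index=list(GRADES))


def summarize_placements(evals: list[PlacementEvaluation]) -> PlacementSummary:
    """Aggregate per-animal grades into the per-placement summary.

    Input order is irrelevant; duplicate (turtle, placement) pairs are a
    validation error.  Percentages use each placement's own evaluated total
    as denominator, so columns sum to 100 up to rounding slack.
    """
    seen: set[tuple[str, str]] = set()
    summary = PlacementSummary()
    for ev in evals:
        key = (ev.turtle_id, ev.placement)
        if key in seen:
            raise ValidationError(f"duplicate evaluation for {key}")
        seen.add(key)
        summary.counts.setdefault(ev.placement, {g: 0 for g in GRADES})[ev.grade] += 1
    for p, by_grade in summary.counts.items():
        total = sum(by_grade.values())
        summary.totals[p] = total
        summary.percentages[p] = {
            g: _round1(100.0 * c / total) for g, c in by_grade.items()
        }
    return summary


def cross_position_improvement(
    evals: list[PlacementEvaluation], total_turtles: int
) -> tuple[int, float]:
    """Count animals graded unclear at placement A but clear at placement C,
    and the percentage over the supplied study total (one decimal)."""
    if total_turtles <= 0:
        raise ValidationError("total_turtles must be positive")
    by_turtle: dict[str, dict[str, str]] = {}
    for ev in evals:
        by_turtle.setdefault(ev.turtle_id, {})[ev.placement] = ev.grade
    count = sum(
        1
        for grades in by_turtle.values()
        if grades.get("A") == "unclear" and grades.get("C") == "clear"
    )
    return count, _round1(100.0 * count / total_turtles)


def read_evaluations(path: str | Path) -> list[PlacementEvaluation]:
    """Read a tab-separated evaluations file with columns
    turtle_id, placement, grade (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["turtle_id", "placement", "grade"]:
        df = df.iloc[1:]
    if df.shape[1] != 3:
        raise ValidationError(
            f"{path}: expected 3 tab-separated columns (turtle_id, placement, grade)"
        )
    return [
        PlacementEvaluation(turtle_id=r[0], placement=r[1], grade=r[2])
        for r in df.itertuples(index=False)
    ]
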