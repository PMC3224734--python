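"""Leave-one-out cross-validation of hotspot-position prediction.

For every non-reference row of the seed alignment: drop the row, rebuild
the profile from the remaining rows with identical parameters, align the
dropped row's degapped sequence, and compare the predicted F87-equivalent
position against the row's true position (the degapped position of its
residue at the hotspot column of the full seed, or a gap when the row shows
``-`` there).  The reference row is exempt — it defines the coordinate
system the annotation is expressed in, so it can never be held out.

The profile is rebuilt from the *fixed* alignment with the row removed; the
alignment itself is input data here and is not recomputed per fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .profilehmm import BuildParams, align_query, build_profile
from .seedmodel import (
    SeedAlignment,
    SeedAnnotation,
    SeedError,
    column_to_row_pos_or_none,
)
from .seqio import GAP

CATEGORIES = ("exact", "deviation_1", "deviation_2", "wrong", "gap")

#: Marker for a missing position on either side of a comparison.
GAP_CALL = None


@dataclass(frozen=True)
class LooOutcome:
    row_id: str
    true_position: int | None
    predicted_position: int | None
    category: str


@dataclass(frozen=True)
class LooReport:
    outcomes: tuple[LooOutcome, ...]
    accuracy_exact: float
    accuracy_within_2: float

    @property
    def n(self) -> int:
        return len(self.outcomes)

    def count(self, category: str) -> int:
        return sum(o.category == category for o in self.outcomes)


def compare_positions(
    true_pos: int | None, predicted_pos: int | None
) -> str:
    """Categorise a predicted hotspot position against the true one.

    ``gap`` when either side is missing; otherwise exact / deviation_1 /
    deviation_2 / wrong by absolute difference.
    """
    if true_pos is GAP_CALL or predicted_pos is GAP_CALL:
        return "gap"
    if true_pos < 1 or predicted_pos < 1:
        raise ValueError("positions are 1-based")
    delta = abs(predicted_pos - true_pos)
    if delta == 0:
        return "exact"
    if delta <= 2:
        return f"deviation_{delta}"
    return "wrong"


def leave_one_out(
    seed: SeedAlignment,
    ann: SeedAnnotation,
    build_params: BuildParams | None = None,
) -> LooReport:
    """Run the hold-out validation over every non-reference seed row.

    A fold whose held-out profile cannot model the hotspot (the dropped row
    was the anchor column's sole observer) is reported as a ``gap``
    outcome, not an error.
    """
    if len(seed.rows) < 3:
        raise SeedError("leave-one-out needs at least 3 rows")
    build_params = build_params or BuildParams()
    outcomes: list[LooOutcome] = []
    for row in seed.rows:
        if row.id == seed.reference_id:
            continue
        true_pos = column_to_row_pos_or_none(row, ann.f87_col)
        reduced = seed.drop_row(row.id)
        try:
            profile = build_profile(reduced, ann, build_params)
        except Exception:
            outcomes.append(
                LooOutcome(
                    row_id=row.id,
                    true_position=true_pos,
                    predicted_position=GAP_CALL,
                    category="gap",
                )
            )
            continue
        mapping = align_query(
            profile, row.to_sequence(), allow_fragment=True
        )
        predicted = mapping.assignments[profile.anchor_states["f87"]]
        outcomes.append(
            LooOutcome(
                row_id=row.id,
                true_position=true_pos,
                predicted_position=predicted,
                category=compare_positions(true_pos, predicted),
            )
        )
    n = len(outcomes)
    exact = sum(o.category == "exact" for o in outcomes)
    within2 = sum(
        o.category in ("exact", "deviation_1", "deviation_2")
        for o in outcomes
    )
    return LooReport(
        outcomes=tuple(outcomes),
        accuracy_exact=exact / n,
        accuracy_within_2=within2 / n,
    )


def report_to_rows(report: LooReport) -> list[dict]:
    return [
        {
            "row_id": o.row_id,
            "true_position": "." if o.true_position is None else o.true_position,
            "predicted_position": (
                "." if o.predicted_position is None else o.predicted_position
            ),
            "category": o.category,
        }
        for o in report.outcomes
    ]
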