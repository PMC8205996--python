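"""Map total evidence points plus panel flags to a validity classification.

Band edges on the 0-18 point scale: a total of exactly 0 is No Known
Relationship; (0, 7) is Limited; [7, 12) is Moderate; [12, 18] is Strong,
upgraded to Definitive when the association is replicated over time across
independent cohorts. Disputed and Refuted are expert-panel overrides that
dominate any point total. The bands partition the whole representable scale:
the published band descriptions leave (6, 7) unstated, and it is assigned to
Limited so that half-point totals such as 6.5 classify conservatively.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from decimal import Decimal
from enum import Enum

from .evidence import ExpertOverride, GeneDiseaseRecord
from .experimental import ExperimentalBreakdown, experimental_subtotal
from .genetic import GeneticBreakdown, genetic_subtotal
from .matrix import ScoreMatrix, as_points

__all__ = [
    "ValidityClass",
    "Classification",
    "CLASS_RANK",
    "MODERATE_FLOOR",
    "STRONG_FLOOR",
    "total_score",
    "classify",
    "preliminary_classification",
    "replication_supported",
]

MODERATE_FLOOR = Decimal(7)
STRONG_FLOOR = Decimal(12)


class ValidityClass(str, Enum):
    no_known_relationship = "no_known_relationship"
    limited = "limited"
    moderate = "moderate"
    strong = "strong"
    definitive = "definitive"
    disputed = "disputed"
    refuted = "refuted"
    needs_panel_review = "needs_panel_review"


#: Evidence-strength rank of the point-driven classes (overrides excluded).
CLASS_RANK = {
    ValidityClass.no_known_relationship: 0,
    ValidityClass.limited: 1,
    ValidityClass.moderate: 2,
    ValidityClass.strong: 3,
    ValidityClass.definitive: 3,
}


@dataclass(frozen=True)
class Classification:
    value: ValidityClass
    total_points: Decimal
    preliminary: bool = False


def total_score(g: GeneticBreakdown, e: ExperimentalBreakdown) -> Decimal:
    """Sum of the capped genetic and experimental subtotals (at most 18)."""
    return g.genetic_subtotal + e.experimental_subtotal


def classify(
    total: Decimal | float | int,
    replicated: bool,
    override: ExpertOverride = ExpertOverride.none,
    *,
    preliminary: bool = False,
) -> Classification:
    """Band classification of a total score with override dominance."""
    total = as_points(total)
    if not (Decimal(0) <= total <= STRONG_FLOOR + Decimal(6)):
        raise ValueError(f"total {total} outside [0, 18]")
    if override == ExpertOverride.disputed:
        value = ValidityClass.disputed
    elif override == ExpertOverride.refuted:
        value = ValidityClass.refuted
    elif total == 0:
        value = ValidityClass.no_known_relationship
    elif total < MODERATE_FLOOR:
        value = ValidityClass.limited
    elif total < STRONG_FLOOR:
        value = ValidityClass.moderate
    elif replicated:
        value = ValidityClass.definitive
    else:
        value = ValidityClass.strong
    return Classification(value=value, total_points=total, preliminary=preliminary)


def preliminary_classification(
    record: GeneDiseaseRecord, matrix: ScoreMatrix
) -> Classification:
    """Points-only classification as produced by one blinded curation team.

    Expert overrides and the replication upgrade are panel-level decisions
    applied after dual curation, so both are suppressed here: the result is
    the pure band of the achieved total, flagged preliminary.
    """
    g = genetic_subtotal(record, matrix)
    e = experimental_subtotal(record.experimental_evidence, matrix)
    return classify(
        total_score(g, e),
        replicated=False,
        override=ExpertOverride.none,
        preliminary=True,
    )


def replication_supported(
    publication_dates: list[datetime.date], min_publications: int = 2,
    min_span_years: int = 3,
) -> bool:
    """Advisory predicate for replication over time.

    True when at least ``min_publications`` independent reports span at
    least ``min_span_years`` years. The stored ``replicated_over_time`` flag
    on a record remains the panel's judgment; this helper only assists it.
    """
    if len(publication_dates) < min_publications:
        return False
    span = max(publication_dates) - min(publication_dates)
    return span.days >= min_span_years * 365
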