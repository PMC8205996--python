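"""Experimental-evidence scoring with group caps and the model-phenotype gate.

Experimental evidence falls into three groups — protein function
(biochemical function, interaction, expression), functional alteration in
patient or non-patient cells, and model systems plus rescue — each capped
(2 / 2 / 4 in the shipped matrix) before the experimental subtotal cap (6).

The panel-specific gate: evidence from a model system or rescue experiment
whose phenotype the expert panel judged inconsistent with the disease
contributes zero points, regardless of any adjudicated award. The
consistency judgment itself is curator input, never inferred here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from .evidence import (
    ExperimentalCategory,
    ExperimentalEvidenceItem,
    MODEL_SYSTEM_CATEGORIES,
)
from .matrix import ScoreMatrix

__all__ = ["ExperimentalBreakdown", "score_experimental_item", "experimental_subtotal"]


@dataclass(frozen=True)
class ExperimentalBreakdown:
    points_by_category: dict[str, Decimal] = field(default_factory=dict)
    function_points: Decimal = Decimal(0)
    functional_alteration_points: Decimal = Decimal(0)
    models_rescue_points: Decimal = Decimal(0)
    experimental_subtotal: Decimal = Decimal(0)


def score_experimental_item(
    item: ExperimentalEvidenceItem, matrix: ScoreMatrix
) -> Decimal:
    """Points for one experimental item, applying the phenotype gate."""
    spec = matrix.experimental.categories[item.category.value]
    if item.category in MODEL_SYSTEM_CATEGORIES:
        if item.phenotype_consistent is None:
            raise ValueError(
                f"{item.category.value}: phenotype_consistent is required "
                "for model-system and rescue evidence"
            )
        if not item.phenotype_consistent:
            return Decimal(0)
    if item.awarded_points is None:
        return spec.default
    if not spec.contains(item.awarded_points):
        lo, hi = spec.range
        raise ValueError(
            f"awarded_points {item.awarded_points} outside range [{lo}, {hi}] "
            f"for category {item.category.value}"
        )
    return item.awarded_points


def experimental_subtotal(
    items: list[ExperimentalEvidenceItem], matrix: ScoreMatrix
) -> ExperimentalBreakdown:
    """Group-capped experimental breakdown, clamped at the experimental cap."""
    by_category: dict[str, Decimal] = {}
    for item in items:
        pts = score_experimental_item(item, matrix)
        key = item.category.value
        by_category[key] = by_category.get(key, Decimal(0)) + pts

    group_points: dict[str, Decimal] = {}
    for name, group in matrix.experimental.groups.items():
        raw = sum(
            (by_category.get(c, Decimal(0)) for c in group.categories), Decimal(0)
        )
        group_points[name] = min(raw, group.cap)

    subtotal = min(
        sum(group_points.values(), Decimal(0)), matrix.experimental.cap
    )
    return ExperimentalBreakdown(
        points_by_category=by_category,
        function_points=group_points.get("function", Decimal(0)),
        functional_alteration_points=group_points.get(
            "functional_alteration", Decimal(0)
        ),
        models_rescue_points=group_points.get("models_rescue", Decimal(0)),
        experimental_subtotal=subtotal,
    )
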