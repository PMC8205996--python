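"""Genetic-evidence scoring: variant points, segregation LOD, case-control.

The genetic subtotal combines three components, each with its own caps
before an overall cap (12 points in the shipped matrix):

* case-level variant evidence — per-proband points by resolved category
  (null variant, other variant with gene impact, de novo, biallelic
  in-trans/phase-unknown for recessive disease), summed with per-category
  caps and a combined variant-evidence cap;
* segregation — family LOD scores (published, or estimated from counted
  informative meioses as n*log10(2) under a fully informative, fully
  penetrant dominant approximation) summed per sequencing approach and
  mapped through configured LOD bins, capped at 3;
* case-control — adjudicated per-study points (0-6 each) summed and capped.

Adjudicated awards outside the matrix range for their category are an
error, never silently clamped: curation files record panel decisions and a
value outside the permitted range signals a data problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal

from .evidence import (
    DeNovoStatus,
    GeneDiseaseRecord,
    Inheritance,
    Phase,
    ProbandVariantEvidence,
    SegregationEvidence,
    CaseControlEvidence,
    VariantClass,
)
from .matrix import ScoreMatrix

__all__ = [
    "GeneticBreakdown",
    "resolve_variant_category",
    "score_proband_variant",
    "variant_evidence_subtotal",
    "estimate_segregation_lod",
    "segregation_points",
    "case_control_points",
    "genetic_subtotal",
]

LOG10_2 = math.log10(2.0)

_BIALLELIC = {Inheritance.AR, Inheritance.semidominant}


@dataclass(frozen=True)
class GeneticBreakdown:
    """Component-wise decomposition of the genetic subtotal."""

    variant_points_by_category: dict[str, Decimal] = field(default_factory=dict)
    variant_points_capped: Decimal = Decimal(0)
    segregation_lod_total: float = 0.0
    segregation_points: Decimal = Decimal(0)
    case_control_points: Decimal = Decimal(0)
    genetic_subtotal: Decimal = Decimal(0)


def resolve_variant_category(
    ev: ProbandVariantEvidence, inheritance: Inheritance
) -> str:
    """Map a proband observation to its matrix scoring category.

    For biallelic inheritance (AR, semidominant) the phase drives the
    category; phase ``not_applicable`` is unresolvable there. For monoallelic
    inheritance, null variants score as ``proband_null`` whatever their de
    novo status (curators upgrade within the range), while non-null variants
    with confirmed or assumed de novo occurrence move to the dedicated
    de novo category.
    """
    if inheritance in _BIALLELIC:
        if ev.phase_for_AR == Phase.in_trans:
            return "ar_in_trans"
        if ev.phase_for_AR == Phase.unknown:
            return "ar_phase_unknown"
        raise ValueError(
            f"phase {ev.phase_for_AR.value!r} unresolvable under "
            f"{inheritance.value} inheritance"
        )
    if ev.variant_class == VariantClass.predicted_or_proven_null:
        return "proband_null"
    if ev.de_novo != DeNovoStatus.none:
        return "proband_other_de_novo"
    return "proband_other"


def score_proband_variant(
    ev: ProbandVariantEvidence, inheritance: Inheritance, matrix: ScoreMatrix
) -> Decimal:
    """Points for one proband variant: the adjudicated award, else the default."""
    category = resolve_variant_category(ev, inheritance)
    spec = matrix.genetic.variant_categories[category]
    if ev.awarded_points is None:
        return spec.default
    if not spec.contains(ev.awarded_points):
        lo, hi = spec.range
        raise ValueError(
            f"awarded_points {ev.awarded_points} outside range [{lo}, {hi}] "
            f"for category {category}"
        )
    return ev.awarded_points


def variant_evidence_subtotal(
    evs: list[ProbandVariantEvidence],
    inheritance: Inheritance,
    matrix: ScoreMatrix,
) -> tuple[dict[str, Decimal], Decimal]:
    """Per-category sums (clamped at category caps) and the capped combined total."""
    sums: dict[str, Decimal] = {}
    for ev in evs:
        category = resolve_variant_category(ev, inheritance)
        sums[category] = sums.get(category, Decimal(0)) + score_proband_variant(
            ev, inheritance, matrix
        )
    capped: dict[str, Decimal] = {}
    for category, total in sums.items():
        cap = matrix.genetic.variant_categories[category].cap
        capped[category] = min(total, cap) if cap is not None else total
    subtotal = min(sum(capped.values(), Decimal(0)), matrix.genetic.variant_cap)
    return capped, subtotal


def estimate_segregation_lod(seg: SegregationEvidence) -> float:
    """LOD score for one family.

    A published LOD passes through unchanged. Otherwise the LOD is estimated
    from counted informative meioses as n*log10(2) — the likelihood-ratio
    contribution of n phenotype-concordant transmissions under full
    penetrance with no phenocopies.
    """
    if seg.published_lod is not None:
        if seg.informative_meioses is not None:
            raise ValueError(
                "informative_meioses and published_lod are mutually exclusive"
            )
        return float(seg.published_lod)
    if seg.informative_meioses is None:
        raise ValueError(
            "one of informative_meioses / published_lod must be supplied"
        )
    return seg.informative_meioses * LOG10_2

def segregation_points(
    segs: list[SegregationEvidence], matrix: ScoreMatrix
) -> Decimal:
    """Convert summed family LODs to points via the matrix mapping.

    LODs are summed per sequencing approach (candidate-gene studies map to
    full points, exome/genome to half in the shipped matrix), each sum is
    looked up in its approach's bins, and the combined result is clamped at
    the segregation cap.
    """
    spec = matrix.genetic.segregation
    lod_by_approach: dict[str, float] = {}
    for seg in segs:
        key = seg.sequencing_approach.value
        lod_by_approach[key] = lod_by_approach.get(key, 0.0) + estimate_segregation_lod(seg)
    total = Decimal(0)
    for approach, lod in lod_by_approach.items():
        bins = spec.bins[approach]
        points = Decimal(0)
        for b in bins:  # bins sorted ascending; take the highest threshold met
            if Decimal(str(lod)) >= b.min_lod:
                points = b.points
        total += points
    return min(total, spec.cap)


def case_control_points(
    studies: list[CaseControlEvidence], matrix: ScoreMatrix
) -> Decimal:
    """Sum of adjudicated per-study points, clamped at the case-control cap."""
    spec = matrix.genetic.case_control
    lo, hi = spec.per_study_range
    total = Decimal(0)
    for study in studies:
        if not (lo <= study.awarded_points <= hi):
            raise ValueError(
                f"case-control award {study.awarded_points} outside [{lo}, {hi}]"
            )
        total += study.awarded_points
    return min(total, spec.cap)


def genetic_subtotal(
    record: GeneDiseaseRecord, matrix: ScoreMatrix
) -> GeneticBreakdown:
    """Score all genetic evidence of a record into a capped breakdown."""
    by_category, variant_capped = variant_evidence_subtotal(
        record.proband_evidence, record.inheritance, matrix
    )
    lod_total = sum(
        estimate_segregation_lod(s) for s in record.segregation_evidence
    )
    seg_points = segregation_points(record.segregation_evidence, matrix)
    cc_points = case_control_points(record.case_control_evidence, matrix)
    subtotal = min(variant_capped + seg_points + cc_points, matrix.genetic.cap)
    return GeneticBreakdown(
        variant_points_by_category=by_category,
        variant_points_capped=variant_capped,
        segregation_lod_total=lod_total,
        segregation_points=seg_points,
        case_control_points=cc_points,
        genetic_subtotal=subtotal,
    )
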