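"""Genetic scoring: category resolution, caps, LOD conversion, oracles."""

import math
import random
from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arvcurate.evidence import (
    CaseControlEvidence,
    DeNovoStatus,
    GeneDiseaseRecord,
    Inheritance,
    Phase,
    ProbandVariantEvidence,
    SegregationEvidence,
    SequencingApproach,
    VariantClass,
)
from arvcurate.genetic import (
    case_control_points,
    estimate_segregation_lod,
    genetic_subtotal,
    score_proband_variant,
    segregation_points,
    variant_evidence_subtotal,
)

D = Decimal


def null_ev(points=None, **kw):
    return ProbandVariantEvidence(
        proband_id=kw.pop("proband_id", "p"),
        variant_class=VariantClass.predicted_or_proven_null,
        awarded_points=None if points is None else D(str(points)),
        **kw,
    )


def other_ev(points=None, **kw):
    return ProbandVariantEvidence(
        proband_id=kw.pop("proband_id", "p"),
        variant_class=VariantClass.other_with_gene_impact,
        awarded_points=None if points is None else D(str(points)),
        **kw,
    )


@pytest.mark.parametrize(
    "ev, inheritance, expected",
    [
        (null_ev(), Inheritance.AD, D("1.5")),
        (other_ev(), Inheritance.AD, D("0.1")),
        (other_ev(de_novo=DeNovoStatus.confirmed), Inheritance.AD, D("0.5")),
        (null_ev(2.0), Inheritance.AD, D("2.0")),
        (other_ev(phase_for_AR=Phase.in_trans), Inheritance.AR, D("2")),
        (other_ev(phase_for_AR=Phase.unknown), Inheritance.AR, D("1")),
    ],
)
def test_proband_variant_defaults_and_awards(ev, inheritance, expected, matrix):
    assert score_proband_variant(ev, inheritance, matrix) == expected


def test_unresolvable_ar_phase_errors(matrix):
    with pytest.raises(ValueError, match="unresolvable"):
        score_proband_variant(
            other_ev(phase_for_AR=Phase.not_applicable), Inheritance.AR, matrix
        )


def test_out_of_range_award_errors_not_clamps(matrix):
    with pytest.raises(ValueError, match="outside range"):
        score_proband_variant(null_ev(3.5), Inheritance.AD, matrix)


def test_variant_subtotal_hand_sum(matrix):
    evs = [null_ev(proband_id=f"p{i}") for i in range(3)]
    by_cat, subtotal = variant_evidence_subtotal(evs, Inheritance.AD, matrix)
    assert subtotal == D("4.5")
    assert by_cat == {"proband_null": D("4.5")}


def test_variant_category_cap_clamps(matrix):
    evs = [null_ev(3, proband_id=f"p{i}") for i in range(5)]  # raw 15
    by_cat, subtotal = variant_evidence_subtotal(evs, Inheritance.AD, matrix)
    assert by_cat["proband_null"] == D(10)
    assert subtotal == D(10)


def test_variant_subtotal_empty(matrix):
    assert variant_evidence_subtotal([], Inheritance.AD, matrix) == ({}, D(0))


@pytest.mark.parametrize(
    "meioses, expected",
    [(0, 0.0), (10, 10 * math.log10(2))],
)
def test_lod_from_meioses(meioses, expected):
    seg = SegregationEvidence(family_id="f", informative_meioses=meioses)
    assert estimate_segregation_lod(seg) == pytest.approx(expected, abs=1e-4)


def test_published_lod_passes_through():
    seg = SegregationEvidence(family_id="f", published_lod=D("2.3"))
    assert estimate_segregation_lod(seg) == 2.3


@given(n=st.integers(0, 40), m=st.integers(0, 40))
@settings(derandomize=True, max_examples=60)
def test_lod_additivity(n, m):
    def lod(k):
        return estimate_segregation_lod(
            SegregationEvidence(family_id="f", informative_meioses=k)
        )

    assert lod(n + m) == pytest.approx(lod(n) + lod(m), abs=1e-9)


@pytest.mark.parametrize(
    "lod, approach, expected",
    [
        (1.0, SequencingApproach.candidate_gene, D(0)),
        (3.5, SequencingApproach.candidate_gene, D(2)),
        (3.5, SequencingApproach.exome_genome, D(1)),
        (5.2, SequencingApproach.candidate_gene, D(3)),
    ],
)
def test_segregation_bins(lod, approach, expected, matrix):
    segs = [
        SegregationEvidence(
            family_id="f", published_lod=D(str(lod)), sequencing_approach=approach
        )
    ]
    assert segregation_points(segs, matrix) == expected


def test_segregation_summed_across_families(matrix):
    # 6 + 5 informative meioses -> LOD 11*log10(2) = 3.311 -> 2 points
    segs = [
        SegregationEvidence(family_id="f1", informative_meioses=6),
        SegregationEvidence(family_id="f2", informative_meioses=5),
    ]
    assert segregation_points(segs, matrix) == D(2)


def test_case_control_sum_and_cap(matrix):
    studies = [
        CaseControlEvidence(study_id="s1", awarded_points=D(4)),
        CaseControlEvidence(study_id="s2", awarded_points=D(3)),
    ]
    assert case_control_points(studies, matrix) == D(7)
    three_max = [
        CaseControlEvidence(study_id=f"s{i}", awarded_points=D(6)) for i in range(3)
    ]
    assert case_control_points(three_max, matrix) == D(12)
    assert case_control_points([], matrix) == D(0)


def test_genetic_subtotal_overall_cap(matrix):
    record = GeneDiseaseRecord(
        gene_symbol="PKP2",
        proband_evidence=[null_ev(3, proband_id=f"p{i}") for i in range(4)],  # 10
        segregation_evidence=[
            SegregationEvidence(family_id="f", published_lod=D("5.5"))
        ],  # 3
        case_control_evidence=[
            CaseControlEvidence(study_id="s", awarded_points=D(2))
        ],  # 2
    )
    bd = genetic_subtotal(record, matrix)
    assert bd.variant_points_capped == D(10)
    assert bd.segregation_points == D(3)
    assert bd.case_control_points == D(2)
    assert bd.genetic_subtotal == D(12)  # 15 clamped at cap


def test_empty_record_scores_zero(matrix):
    assert genetic_subtotal(
        GeneDiseaseRecord(gene_symbol="X"), matrix
    ).genetic_subtotal == D(0)


# --- property tests -------------------------------------------------------

grid = st.integers(0, 60).map(lambda k: D(k) * D("0.05"))


@st.composite
def evidence_lists(draw, max_items=6):
    n = draw(st.integers(0, max_items))
    evs = []
    for i in range(n):
        kind = draw(st.sampled_from(["null", "other", "de_novo"]))
        if kind == "null":
            evs.append(null_ev(draw(grid), proband_id=f"p{i}"))
        elif kind == "other":
            evs.append(
                other_ev(
                    min(draw(grid), D("1.5")), proband_id=f"p{i}"
                )
            )
        else:
            evs.append(
                other_ev(
                    draw(grid),
                    proband_id=f"p{i}",
                    de_novo=DeNovoStatus.confirmed,
                )
            )
    return evs


@given(evs=evidence_lists())
@settings(derandomize=True, max_examples=100)
def test_variant_subtotal_order_independent(evs, matrix):
    _, a = variant_evidence_subtotal(evs, Inheritance.AD, matrix)
    rng = random.Random(0)
    shuffled = evs[:]
    rng.shuffle(shuffled)
    _, b = variant_evidence_subtotal(shuffled, Inheritance.AD, matrix)
    assert a == b


@given(evs=evidence_lists(max_items=5), extra=grid)
@settings(derandomize=True, max_examples=100)
def test_adding_evidence_never_decreases_subtotal(evs, extra, matrix):
    _, before = variant_evidence_subtotal(evs, Inheritance.AD, matrix)
    _, after = variant_evidence_subtotal(
        evs + [null_ev(extra, proband_id="extra")], Inheritance.AD, matrix
    )
    assert after >= before
    assert after <= D(12)
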