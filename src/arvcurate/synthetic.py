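"""Synthetic evidence generation with construction-time ground truth.

Every generator here records what its output *should* score via an
independent tally — plain running sums with caps applied once at the end,
re-derived in this module and deliberately sharing no code with the scoring
modules — so the scoring path can be checked against a ground truth that
was fixed before scoring ran. This module therefore imports only the domain
types and the matrix configuration, never the scoring modules.

Also packages the 26-gene ARVC curation fixture: per-gene evidence records
whose totals and bands reproduce the published panel outcome, paired team
files for dual curation, the evidence-tier map and the transcribed ClinVar
variant-class table.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from decimal import ROUND_CEILING, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .evidence import (
    CaseControlEvidence,
    DeNovoStatus,
    ExperimentalCategory,
    ExperimentalEvidenceItem,
    ExpertOverride,
    FrequencyAssessment,
    GeneDiseaseRecord,
    Inheritance,
    MODEL_SYSTEM_CATEGORIES,
    Phase,
    ProbandVariantEvidence,
    SegregationEvidence,
    SequencingApproach,
    VariantClass,
    save_curation,
)
from .matrix import POINT_STEP, ScoreMatrix, as_points, default_matrix

__all__ = [
    "ExpectedBreakdown",
    "SyntheticCuration",
    "ArvcFixture",
    "generate_curation",
    "simulate_segregation",
    "generate_variant_table",
    "arvc_fixture",
    "fixture_to_dir",
]

_LOG10_2 = math.log10(2.0)

# Point-band edges, restated here so the oracle does not depend on the
# classification module.
_MODERATE_FLOOR = Decimal(7)
_STRONG_FLOOR = Decimal(12)
_TOTAL_MAX = Decimal(18)

_SCORABLE_TARGETS = (
    "no_known_relationship",
    "limited",
    "moderate",
    "strong",
    "definitive",
)


@dataclass(frozen=True)
class ExpectedBreakdown:
    """Generator-side ground truth for one record."""

    gene_symbol: str
    genetic_subtotal: Decimal
    experimental_subtotal: Decimal
    total: Decimal
    classification: str


@dataclass(frozen=True)
class SyntheticCuration:
    record: GeneDiseaseRecord
    expected: ExpectedBreakdown
    seed: int


def _band(total: Decimal, replicated: bool) -> str:
    if total == 0:
        return "no_known_relationship"
    if total < _MODERATE_FLOOR:
        return "limited"
    if total < _STRONG_FLOOR:
        return "moderate"
    return "definitive" if replicated else "strong"


def _resolve_category(ev: ProbandVariantEvidence, inheritance: Inheritance) -> str:
    if inheritance in (Inheritance.AR, Inheritance.semidominant):
        return (
            "ar_in_trans" if ev.phase_for_AR == Phase.in_trans else "ar_phase_unknown"
        )
    if ev.variant_class == VariantClass.predicted_or_proven_null:
        return "proband_null"
    if ev.de_novo != DeNovoStatus.none:
        return "proband_other_de_novo"
    return "proband_other"


def _independent_tally(
    record: GeneDiseaseRecord, matrix: ScoreMatrix
) -> ExpectedBreakdown:
    """Running-sum tally with caps applied once at the end (the oracle)."""
    cat_sums: dict[str, Decimal] = {}
    for ev in record.proband_evidence:
        cat = _resolve_category(ev, record.inheritance)
        spec = matrix.genetic.variant_categories[cat]
        pts = ev.awarded_points if ev.awarded_points is not None else spec.default
        cat_sums[cat] = cat_sums.get(cat, Decimal(0)) + pts
    variant = Decimal(0)
    for cat, total in cat_sums.items():
        cap = matrix.genetic.variant_categories[cat].cap
        variant += total if cap is None else min(total, cap)
    variant = min(variant, matrix.genetic.variant_cap)

    lod_by_approach: dict[str, float] = {}
    for seg in record.segregation_evidence:
        lod = (
            float(seg.published_lod)
            if seg.published_lod is not None
            else (seg.informative_meioses or 0) * _LOG10_2
        )
        key = seg.sequencing_approach.value
        lod_by_approach[key] = lod_by_approach.get(key, 0.0) + lod
    seg_points = Decimal(0)
    for approach, lod in lod_by_approach.items():
        pts = Decimal(0)
        for b in matrix.genetic.segregation.bins[approach]:
            if Decimal(str(lod)) >= b.min_lod:
                pts = b.points
        seg_points += pts
    seg_points = min(seg_points, matrix.genetic.segregation.cap)

    cc = sum(
        (s.awarded_points for s in record.case_control_evidence), Decimal(0)
    )
    cc = min(cc, matrix.genetic.case_control.cap)
    genetic = min(variant + seg_points + cc, matrix.genetic.cap)

    exp_by_cat: dict[str, Decimal] = {}
    for item in record.experimental_evidence:
        if item.category in MODEL_SYSTEM_CATEGORIES and not item.phenotype_consistent:
            pts = Decimal(0)
        else:
            spec = matrix.experimental.categories[item.category.value]
            pts = (
                item.awarded_points
                if item.awarded_points is not None
                else spec.default
            )
        key = item.category.value
        exp_by_cat[key] = exp_by_cat.get(key, Decimal(0)) + pts
    experimental = Decimal(0)
    for name, group in matrix.experimental.groups.items():
        raw = sum(
            (exp_by_cat.get(c, Decimal(0)) for c in group.categories), Decimal(0)
        )
        experimental += min(raw, group.cap)
    experimental = min(experimental, matrix.experimental.cap)

    total = genetic + experimental
    return ExpectedBreakdown(
        gene_symbol=record.gene_symbol,
        genetic_subtotal=genetic,
        experimental_subtotal=experimental,
        total=total,
        classification=_band(total, record.replicated_over_time),
    )


def _grid(rng: random.Random, lo: Decimal, hi: Decimal) -> Decimal:
    """Uniform draw on the 0.05-point grid within [lo, hi]."""
    steps = int((hi - lo) / POINT_STEP)
    return lo + POINT_STEP * rng.randint(0, steps)


def _snap_up(x: Decimal) -> Decimal:
    q = (x / POINT_STEP).quantize(Decimal(1), rounding=ROUND_CEILING)
    return max(q * POINT_STEP, POINT_STEP)


def _draw_random_evidence(
    rng: random.Random, gene: str, matrix: ScoreMatrix
) -> GeneDiseaseRecord:
    cats = matrix.genetic.variant_categories
    probands = []
    for i in range(rng.randint(0, 4)):
        probands.append(
            ProbandVariantEvidence(
                proband_id=f"{gene}-P{i}",
                variant_class=VariantClass.predicted_or_proven_null,
                awarded_points=_grid(rng, *cats["proband_null"].range),
            )
        )
    for i in range(rng.randint(0, 3)):
        probands.append(
            ProbandVariantEvidence(
                proband_id=f"{gene}-M{i}",
                variant_class=VariantClass.other_with_gene_impact,
                awarded_points=_grid(rng, *cats["proband_other"].range),
            )
        )
    segs = [
        SegregationEvidence(
            family_id=f"{gene}-F{i}",
            informative_meioses=rng.randint(0, 12),
            sequencing_approach=rng.choice(list(SequencingApproach)),
        )
        for i in range(rng.randint(0, 2))
    ]
    ccs = [
        CaseControlEvidence(
            study_id=f"{gene}-CC{i}",
            awarded_points=_grid(rng, *matrix.genetic.case_control.per_study_range),
        )
        for i in range(rng.randint(0, 1))
    ]
    items = []
    for i in range(rng.randint(0, 4)):
        cat = rng.choice(list(ExperimentalCategory))
        spec = matrix.experimental.categories[cat.value]
        items.append(
            ExperimentalEvidenceItem(
                category=cat,
                phenotype_consistent=(
                    rng.random() > 0.2 if cat in MODEL_SYSTEM_CATEGORIES else None
                ),
                awarded_points=_grid(rng, *spec.range),
            )
        )
    return GeneDiseaseRecord(
        gene_symbol=gene,
        proband_evidence=probands,
        segregation_evidence=segs,
        case_control_evidence=ccs,
        experimental_evidence=items,
    )


def generate_curation(
    seed: int,
    target_class: str,
    matrix: ScoreMatrix | None = None,
    gene: str = "GENE1",
) -> SyntheticCuration:
    """Draw a random evidence set whose tally lands in the target band.

    Evidence counts and award values are drawn uniformly within matrix
    ranges, then items are added or removed until the generator's own tally
    lands in the target band. The expected breakdown is the tally, recorded
    before the scoring modules ever see the record. Reproducible per seed.
    """
    if target_class not in _SCORABLE_TARGETS:
        raise ValueError(
            f"target_class must be one of {_SCORABLE_TARGETS}, got {target_class!r}"
        )
    matrix = matrix or default_matrix()
    rng = random.Random(seed)
    replicated = target_class == "definitive"

    if target_class == "no_known_relationship":
        record = GeneDiseaseRecord(gene_symbol=gene)
        expected = _independent_tally(record, matrix)
        return SyntheticCuration(record=record, expected=expected, seed=seed)

    lo = {
        "limited": POINT_STEP,
        "moderate": _MODERATE_FLOOR,
        "strong": _STRONG_FLOOR,
        "definitive": _STRONG_FLOOR,
    }[target_class]
    hi = {
        "limited": _MODERATE_FLOOR - POINT_STEP,
        "moderate": _STRONG_FLOOR - POINT_STEP,
        "strong": _TOTAL_MAX,
        "definitive": _TOTAL_MAX,
    }[target_class]

    record = _draw_random_evidence(rng, gene, matrix)
    record = record.model_copy(update={"replicated_over_time": replicated})
    null_range = matrix.genetic.variant_categories["proband_null"].range
    cc_range = matrix.genetic.case_control.per_study_range
    for _ in range(1000):
        tally = _independent_tally(record, matrix)
        if lo <= tally.total <= hi:
            return SyntheticCuration(record=record, expected=tally, seed=seed)
        if tally.total > hi:
            lists = [
                lst
                for lst in (
                    record.proband_evidence,
                    record.segregation_evidence,
                    record.case_control_evidence,
                    record.experimental_evidence,
                )
                if lst
            ]
            victim = rng.choice(lists)
            victim.pop(rng.randrange(len(victim)))
        else:
            shortfall = _snap_up(lo - tally.total)
            null_sum = sum(
                (
                    ev.awarded_points or Decimal(0)
                    for ev in record.proband_evidence
                    if ev.variant_class == VariantClass.predicted_or_proven_null
                ),
                Decimal(0),
            )
            null_cap = matrix.genetic.variant_categories["proband_null"].cap
            if null_cap is None or null_sum < null_cap:
                record.proband_evidence.append(
                    ProbandVariantEvidence(
                        proband_id=f"{gene}-X{len(record.proband_evidence)}",
                        variant_class=VariantClass.predicted_or_proven_null,
                        awarded_points=min(null_range[1], shortfall),
                    )
                )
            else:
                record.case_control_evidence.append(
                    CaseControlEvidence(
                        study_id=f"{gene}-XCC{len(record.case_control_evidence)}",
                        awarded_points=min(cc_range[1], shortfall),
                    )
                )
    raise RuntimeError(f"could not reach target band {target_class!r}")


def simulate_segregation(
    seed: int, n_meioses: int, noise_fraction: float = 0.0
) -> tuple[SegregationEvidence, float]:
    """One family with a known count of informative meioses and its true LOD.

    With a nonzero noise fraction, each meiosis is independently marked
    uninformative (ungenotyped or phenotype-discordant) and excluded from
    the count; the true LOD reflects the informative count only.
    """
    if n_meioses < 0:
        raise ValueError("n_meioses must be nonnegative")
    if not (0.0 <= noise_fraction <= 1.0):
        raise ValueError("noise_fraction must be in [0, 1]")
    rng = random.Random(seed)
    informative = sum(1 for _ in range(n_meioses) if rng.random() >= noise_fraction)
    seg = SegregationEvidence(
        family_id=f"SIM{seed}", informative_meioses=informative
    )
    return seg, informative * _LOG10_2


def generate_variant_table(
    spec: dict[str, dict[str, int]], seed: int = 0
) -> pd.DataFrame:
    """Variant table with exactly the requested per-gene class counts.

    Rows carry synthetic variant identifiers and are shuffled per seed.
    """
    rows = []
    for gene in sorted(spec):
        for cls in sorted(spec[gene]):
            count = spec[gene][cls]
            if count < 0:
                raise ValueError(f"negative count for {gene}/{cls}")
            for i in range(count):
                rows.append(
                    {
                        "gene": gene,
                        "variant_id": f"{gene}:syn.{cls}.{i + 1}",
                        "significance": cls,
                    }
                )
    rng = random.Random(seed)
    rng.shuffle(rows)
    return pd.DataFrame(rows, columns=["gene", "variant_id", "significance"])


# ---------------------------------------------------------------------------
# Packaged 26-gene ARVC fixture


@dataclass(frozen=True)
class ArvcFixture:
    """The packaged 26-gene curation fixture."""

    records: list[GeneDiseaseRecord]
    pairs: list[tuple[GeneDiseaseRecord, GeneDiseaseRecord]]
    tier_map: dict[str, str]
    variant_table: pd.DataFrame
    expected: dict[str, ExpectedBreakdown] = field(default_factory=dict)


def _fixture_spec() -> dict:
    ref = resources.files("arvcurate.data").joinpath("arvc_fixture.json")
    return json.loads(ref.read_text())


def _build_genetic(
    gene: str, g: Decimal
) -> tuple[list[ProbandVariantEvidence], list[SegregationEvidence]]:
    """Evidence whose genetic tally is exactly ``g`` (g <= 12, 0.5 grid)."""
    variant_target = min(g, Decimal(10))
    seg_needed = g - variant_target
    probands = []
    rem = variant_target
    i = 0
    while rem > 0:
        award = min(Decimal(3), rem)
        probands.append(
            ProbandVariantEvidence(
                proband_id=f"{gene}-proband-{i}",
                variant_class=VariantClass.predicted_or_proven_null,
                awarded_points=award,
            )
        )
        rem -= award
        i += 1
    seg_families = {
        Decimal("0"): [],
        Decimal("0.5"): [("exome_genome", "2.5")],
        Decimal("1"): [("candidate_gene", "2.5")],
        Decimal("1.5"): [("candidate_gene", "2.5"), ("exome_genome", "2.5")],
        Decimal("2"): [("candidate_gene", "3.5")],
        Decimal("2.5"): [("candidate_gene", "3.5"), ("exome_genome", "2.5")],
        Decimal("3"): [("candidate_gene", "5.5")],
    }[seg_needed]
    segs = [
        SegregationEvidence(
            family_id=f"{gene}-family-{j}",
            published_lod=Decimal(lod),
            sequencing_approach=SequencingApproach(approach),
        )
        for j, (approach, lod) in enumerate(seg_families)
    ]
    return probands, segs


def _build_experimental(e: Decimal) -> list[ExperimentalEvidenceItem]:
    """Items whose experimental tally is exactly ``e`` (e <= 6)."""
    items = []
    function_part = min(e, Decimal(2))
    if function_part > 0:
        items.append(
            ExperimentalEvidenceItem(
                category=ExperimentalCategory.expression,
                awarded_points=function_part,
            )
        )
    model_part = e - function_part
    if model_part > 0:
        items.append(
            ExperimentalEvidenceItem(
                category=ExperimentalCategory.model_organism,
                phenotype_consistent=True,
                awarded_points=model_part,
            )
        )
    return items


def _build_record(
    gene: str,
    disease: str,
    g: Decimal,
    e: Decimal,
    replicated: bool,
    override: str,
    team: str,
) -> GeneDiseaseRecord:
    probands, segs = _build_genetic(gene, g)
    items = _build_experimental(e)
    if gene == "CTNNA3":
        # knockout model with a dilated, not ARVC-consistent, phenotype:
        # gated to zero points by panel rule
        items.append(
            ExperimentalEvidenceItem(
                category=ExperimentalCategory.model_organism,
                phenotype_consistent=False,
                awarded_points=Decimal(2),
            )
        )
    if gene == "LDB3" and probands:
        probands[0] = probands[0].model_copy(
            update={
                "variant_frequency_check": FrequencyAssessment(
                    threshold=1e-4,
                    filtering_af=2.9e-4,
                    worst_population="European (non-Finnish)",
                    passes=False,
                    reason="allele frequency above cutoff in Europeans",
                )
            }
        )
    return GeneDiseaseRecord(
        gene_symbol=gene,
        disease_label=disease,
        proband_evidence=probands,
        segregation_evidence=segs,
        experimental_evidence=items,
        replicated_over_time=replicated,
        expert_override=ExpertOverride(override),
        curator_id=f"team-{team}",
    )


def _perturb(g: Decimal, e: Decimal) -> tuple[Decimal, Decimal]:
    """Team-B split: shift half a point while staying in the same band."""
    total = g + e
    if total == 0:
        return g, e
    half = Decimal("0.5")
    for delta in (-half, half):
        new_e = e + delta
        if Decimal(0) <= new_e <= Decimal(6) and _band(
            total + delta, False
        ) == _band(total, False):
            return g, new_e
    return g, e


def arvc_fixture() -> ArvcFixture:
    """The packaged 26-gene ARVC fixture with paired curations.

    Tier membership, overrides, replication flags and the pinned totals
    follow the published panel outcome; per-gene genetic/experimental splits
    are synthetic placeholders constrained to the published bands.
    """
    spec = _fixture_spec()
    disease = spec["disease"]
    records, pairs, tier_map, expected = [], [], {}, {}
    for gene, info in spec["genes"].items():
        g, e = as_points(info["genetic"]), as_points(info["experimental"])
        rec_a = _build_record(
            gene, disease, g, e, info["replicated"], info["override"], "A"
        )
        gb, eb = _perturb(g, e)
        rec_b = _build_record(
            gene, disease, gb, eb, info["replicated"], info["override"], "B"
        )
        records.append(rec_a)
        pairs.append((rec_a, rec_b))
        tier_map[gene] = info["tier"]
        total = g + e
        if info["override"] != "none":
            final = info["override"]
        else:
            final = _band(total, info["replicated"])
        expected[gene] = ExpectedBreakdown(
            gene_symbol=gene,
            genetic_subtotal=g,
            experimental_subtotal=e,
            total=total,
            classification=final,
        )
    table = generate_variant_table(spec["clinvar_counts"], seed=0)
    return ArvcFixture(
        records=records,
        pairs=pairs,
        tier_map=tier_map,
        variant_table=table,
        expected=expected,
    )


def fixture_to_dir(path: str | Path) -> Path:
    """Write the fixture as paired ``<GENE>.A.json`` / ``<GENE>.B.json`` files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fixture = arvc_fixture()
    for rec_a, rec_b in fixture.pairs:
        save_curation(rec_a, path / f"{rec_a.gene_symbol}.A.json")
        save_curation(rec_b, path / f"{rec_b.gene_symbol}.B.json")
    return path
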