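"""Curation orchestration: dual-blinded scoring, concordance, consensus,
per-gene reports and variant-class distribution summaries.

Dual curation scores two independently assembled records for the same
gene-disease pair with no information flow between them; concordance is
defined on the preliminary classifications (the point bands), not on raw
points, with point differences reported for context. Consensus applies the
panel-level flags — expert overrides and the replication upgrade — only
when the two preliminary classes agree; a mismatch is never resolved
silently and is surfaced as ``needs_panel_review``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from .classification import (
    Classification,
    ValidityClass,
    classify,
    preliminary_classification,
    total_score,
)
from .evidence import (
    ExpertOverride,
    GeneDiseaseRecord,
    load_curation,
    validate_record,
)
from .experimental import ExperimentalBreakdown, experimental_subtotal
from .genetic import GeneticBreakdown, genetic_subtotal
from .matrix import ScoreMatrix, default_matrix

__all__ = [
    "ScoreBreakdown",
    "DualCurationResult",
    "ConcordanceReport",
    "VariantClassSummary",
    "SIGNIFICANCE_MAP",
    "score_record",
    "dual_curation",
    "concordance_report",
    "consensus_classification",
    "normalize_significance",
    "summarize_variant_classes",
    "run_full_curation",
]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Scored summary of one record: subtotals, total and point-band class."""

    gene_symbol: str
    genetic_subtotal: Decimal
    experimental_subtotal: Decimal
    total: Decimal
    classification: ValidityClass
    genetic: Optional[GeneticBreakdown] = None
    experimental: Optional[ExperimentalBreakdown] = None


def score_record(record: GeneDiseaseRecord, matrix: ScoreMatrix) -> ScoreBreakdown:
    """Score every evidence component of a record into a full breakdown."""
    g = genetic_subtotal(record, matrix)
    e = experimental_subtotal(record.experimental_evidence, matrix)
    total = total_score(g, e)
    prelim = preliminary_classification(record, matrix)
    return ScoreBreakdown(
        gene_symbol=record.gene_symbol,
        genetic_subtotal=g.genetic_subtotal,
        experimental_subtotal=e.experimental_subtotal,
        total=total,
        classification=prelim.value,
        genetic=g,
        experimental=e,
    )


@dataclass(frozen=True)
class DualCurationResult:
    gene_symbol: str
    breakdown_a: ScoreBreakdown
    breakdown_b: ScoreBreakdown
    class_a: Classification
    class_b: Classification

    @property
    def match(self) -> bool:
        return self.class_a.value == self.class_b.value

    @property
    def point_difference(self) -> Decimal:
        return abs(self.breakdown_a.total - self.breakdown_b.total)


def dual_curation(
    record_a: GeneDiseaseRecord,
    record_b: GeneDiseaseRecord,
    matrix: ScoreMatrix,
) -> DualCurationResult:
    """Independently score and preliminarily classify two blinded curations."""
    if record_a.gene_symbol != record_b.gene_symbol:
        raise ValueError(
            f"dual curation requires one gene: got {record_a.gene_symbol!r} "
            f"and {record_b.gene_symbol!r}"
        )
    a = score_record(record_a, matrix)
    b = score_record(record_b, matrix)
    return DualCurationResult(
        gene_symbol=record_a.gene_symbol,
        breakdown_a=a,
        breakdown_b=b,
        class_a=preliminary_classification(record_a, matrix),
        class_b=preliminary_classification(record_b, matrix),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    per_gene: list[tuple[str, ValidityClass, ValidityClass, bool, Decimal]]
    fraction_concordant: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": g,
                    "class_A": a.value,
                    "class_B": b.value,
                    "match": m,
                    "point_difference": str(d),
                }
                for g, a, b, m, d in self.per_gene
            ]
        )


def concordance_report(pairs: list[DualCurationResult]) -> ConcordanceReport:
    """Per-gene preliminary-classification agreement and overall fraction."""
    if not pairs:
        raise ValueError("concordance requires at least one dual-curation pair")
    rows = [
        (
            p.gene_symbol,
            p.class_a.value,
            p.class_b.value,
            p.match,
            p.point_difference,
        )
        for p in pairs
    ]
    fraction = sum(1 for r in rows if r[3]) / len(rows)
    return ConcordanceReport(per_gene=rows, fraction_concordant=fraction)


def consensus_classification(
    pair: DualCurationResult,
    panel_override: ExpertOverride = ExpertOverride.none,
    panel_replicated: bool = False,
) -> Classification:
    """Panel consensus from a concordant dual curation.

    A concordant pair keeps its band with the panel flags applied (override
    dominates; replication upgrades Strong to Definitive). A discordant pair
    returns ``needs_panel_review`` — resolution requires the panel, never
    this code.
    """
    if not pair.match:
        return Classification(
            value=ValidityClass.needs_panel_review,
            total_points=pair.breakdown_a.total,
            preliminary=False,
        )
    return classify(
        pair.breakdown_a.total,
        replicated=panel_replicated,
        override=panel_override,
    )


# ClinVar clinical-significance vocabulary normalization. Combined
# pathogenic/likely-pathogenic assertions count with the less confident
# class; conflicting interpretations bin as VUS.
SIGNIFICANCE_MAP = {
    "P": "P",
    "LP": "LP",
    "VUS": "VUS",
    "B": "B",
    "LB": "LB",
    "Pathogenic": "P",
    "Likely pathogenic": "LP",
    "Pathogenic/Likely pathogenic": "LP",
    "Uncertain significance": "VUS",
    "Conflicting interpretations of pathogenicity": "VUS",
    "Conflicting classifications of pathogenicity": "VUS",
    "Benign": "B",
    "Likely benign": "LB",
    "Benign/Likely benign": "LB",
}

SIGNIFICANCE_CLASSES = ("P", "LP", "VUS", "B", "LB")


def normalize_significance(value: str) -> str:
    try:
        return SIGNIFICANCE_MAP[value.strip()]
    except KeyError:
        raise ValueError(f"unrecognized clinical significance {value!r}") from None


@dataclass(frozen=True)
class VariantClassSummary:
    counts: dict[str, dict[str, int]]
    tier_map: dict[str, str]
    plp_fraction_by_tier: dict[str, float]
    total_plp: int

    @property
    def undefined(self) -> bool:
        """True when no P/LP variant exists, leaving fractions undefined."""
        return self.total_plp == 0

    def plp_percent_by_tier(self) -> dict[str, float]:
        """Tier P/LP percentages rounded to one decimal."""
        return {
            tier: round(100.0 * frac, 1)
            for tier, frac in self.plp_fraction_by_tier.items()
        }


def summarize_variant_classes(
    table: pd.DataFrame, tier_map: dict[str, str]
) -> VariantClassSummary:
    """Per-gene significance-class counts and P/LP fraction per evidence tier.

    ``table`` needs columns ``gene`` and ``significance`` (raw ClinVar
    wording accepted). Genes absent from ``tier_map`` are binned as
    ``"other"`` with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    plp_by_tier: dict[str, int] = {}
    total_plp = 0
    for _, row in table.iterrows():
        gene = str(row["gene"])
        cls = normalize_significance(str(row["significance"]))
        gene_counts = counts.setdefault(
            gene, {c: 0 for c in SIGNIFICANCE_CLASSES}
        )
        gene_counts[cls] += 1
        if gene not in tier_map:
            warnings.warn(
                f"gene {gene!r} missing from tier map; binned as 'other'",
                stacklevel=2,
            )
        tier = tier_map.get(gene, "other")
        if cls in ("P", "LP"):
            plp_by_tier[tier] = plp_by_tier.get(tier, 0) + 1
            total_plp += 1
    fractions = (
        {tier: n / total_plp for tier, n in plp_by_tier.items()}
        if total_plp
        else {}
    )
    return VariantClassSummary(
        counts=counts,
        tier_map=dict(tier_map),
        plp_fraction_by_tier=fractions,
        total_plp=total_plp,
    )


def _discover_pairs(input_dir: Path) -> list[tuple[str, Path, Path]]:
    pairs = []
    problems = []
    a_files = sorted(input_dir.glob("*.A.json"))
    if not a_files:
        raise FileNotFoundError(
            f"{input_dir}: no paired curation files (*.A.json / *.B.json) found"
        )
    for a_path in a_files:
        gene = a_path.name[: -len(".A.json")]
        b_path = input_dir / f"{gene}.B.json"
        if not b_path.exists():
            problems.append(f"{gene}: missing team-B file {b_path.name}")
            continue
        pairs.append((gene, a_path, b_path))
    if problems:
        raise FileNotFoundError("; ".join(problems))
    return pairs


def run_full_curation(
    input_dir: str | Path,
    matrix: ScoreMatrix | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Score every paired curation in a directory and write the reports.

    Expects ``<GENE>.A.json`` / ``<GENE>.B.json`` pairs. All results are
    computed (and all inputs validated) before any file is written, so a
    failure never leaves partial reports behind. Outputs: ``scores.tsv``,
    ``concordance.tsv``, ``classifications.tsv`` and ``run_log.json``
    (matrix checksum and input inventory); reruns on identical inputs are
    byte-identical.

    The panel flags (override, replication) are read from the records and
    must agree between the two teams' files.
    """
    input_dir = Path(input_dir)
    matrix = matrix or default_matrix()

    results: list[DualCurationResult] = []
    finals: list[Classification] = []
    errors: list[str] = []
    genes: list[str] = []
    for gene, a_path, b_path in _discover_pairs(input_dir):
        try:
            rec_a = load_curation(a_path)
            rec_b = load_curation(b_path)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        gene_errors = [
            f"{path}: " + "; ".join(violations)
            for rec, path in ((rec_a, a_path), (rec_b, b_path))
            if (violations := validate_record(rec, matrix))
        ]
        if gene_errors:
            errors.extend(gene_errors)
            continue
        if (
            rec_a.expert_override != rec_b.expert_override
            or rec_a.replicated_over_time != rec_b.replicated_over_time
        ):
            errors.append(f"{gene}: panel flags differ between team files")
            continue
        pair = dual_curation(rec_a, rec_b, matrix)
        results.append(pair)
        finals.append(
            consensus_classification(
                pair,
                panel_override=rec_a.expert_override,
                panel_replicated=rec_a.replicated_over_time,
            )
        )
        genes.append(gene)
    if errors:
        raise ValueError("unreadable or invalid inputs:\n" + "\n".join(errors))

    concordance = concordance_report(results)
    score_rows = []
    class_rows = []
    for gene, pair, final in zip(genes, results, finals):
        for team, bd in (("A", pair.breakdown_a), ("B", pair.breakdown_b)):
            score_rows.append(
                {
                    "gene": gene,
                    "team": team,
                    "genetic": str(bd.genetic_subtotal),
                    "experimental": str(bd.experimental_subtotal),
                    "total": str(bd.total),
                    "preliminary_class": bd.classification.value,
                }
            )
        class_rows.append(
            {
                "gene": gene,
                "genetic": str(pair.breakdown_a.genetic_subtotal),
                "experimental": str(pair.breakdown_a.experimental_subtotal),
                "total": str(pair.breakdown_a.total),
                "preliminary_class": pair.class_a.value.value,
                "final_class": final.value.value,
                "override": "none"
                if final.value
                not in (ValidityClass.disputed, ValidityClass.refuted)
                else final.value.value,
                "replicated": final.value == ValidityClass.definitive,
            }
        )

    scores = pd.DataFrame(score_rows)
    classifications = pd.DataFrame(class_rows)
    run_log = {
        "matrix_checksum": matrix.checksum(),
        "n_genes": len(genes),
        "inputs": sorted(p.name for p in input_dir.glob("*.json")),
        "fraction_concordant": concordance.fraction_concordant,
    }

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(output_dir / "scores.tsv", sep="\t", index=False)
        concordance.to_frame().to_csv(
            output_dir / "concordance.tsv", sep="\t", index=False
        )
        classifications.to_csv(
            output_dir / "classifications.tsv", sep="\t", index=False
        )
        (output_dir / "run_log.json").write_text(
            json.dumps(run_log, sort_keys=True, indent=2) + "\n"
        )

    return {
        "scores": scores,
        "classifications": classifications,
        "concordance": concordance,
        "finals": dict(zip(genes, finals)),
        "run_log": run_log,
    }


def plot_score_decomposition(classifications: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar figure of genetic vs experimental points per gene."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = classifications.copy()
    df["genetic"] = df["genetic"].astype(float)
    df["experimental"] = df["experimental"].astype(float)
    df = df.sort_values("total", key=lambda s: s.astype(float), ascending=False)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(df["gene"], df["genetic"], label="genetic", color="#1f3f77")
    ax.bar(
        df["gene"],
        df["experimental"],
        bottom=df["genetic"],
        label="experimental",
        color="#7fa8d9",
    )
    ax.set_ylabel("evidence points")
    ax.legend()
    plt.xticks(rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
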