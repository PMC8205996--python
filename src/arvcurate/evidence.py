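"""Domain types for gene-disease curation evidence, with validation and I/O.

One :class:`GeneDiseaseRecord` holds everything a curation team collected for
a single gene-disease-inheritance triple: proband variant observations,
family segregation data, case-control studies, experimental work, and the
panel-level assertion flags (replication across cohorts, disputed/refuted
overrides). Records serialize canonically to JSON (sorted keys, schema
version tag); YAML is accepted on input.

Validation is two-layered: pydantic enforces types and basic bounds at
construction, while :func:`validate_record` collects every cross-field and
matrix-range violation as messages rather than raising, so a curation file
with several problems reports them all at once.
"""

from __future__ import annotations

import datetime
import json
from decimal import Decimal
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .matrix import POINT_STEP, ScoreMatrix, _PointsModel, as_points

SCHEMA_VERSION = "1.0"

__all__ = [
    "Inheritance",
    "VariantClass",
    "DeNovoStatus",
    "Phase",
    "SequencingApproach",
    "ExperimentalCategory",
    "ExpertOverride",
    "FrequencyAssessment",
    "ProbandVariantEvidence",
    "SegregationEvidence",
    "CaseControlEvidence",
    "ExperimentalEvidenceItem",
    "GeneDiseaseRecord",
    "validate_record",
    "load_curation",
    "save_curation",
]


class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"
    semidominant = "semidominant"


class VariantClass(str, Enum):
    predicted_or_proven_null = "predicted_or_proven_null"
    other_with_gene_impact = "other_with_gene_impact"


class DeNovoStatus(str, Enum):
    confirmed = "confirmed"
    assumed = "assumed"
    none = "none"


class Phase(str, Enum):
    in_trans = "in_trans"
    unknown = "unknown"
    not_applicable = "not_applicable"


class SequencingApproach(str, Enum):
    candidate_gene = "candidate_gene"
    exome_genome = "exome_genome"


class ExperimentalCategory(str, Enum):
    biochemical_function = "biochemical_function"
    protein_interaction = "protein_interaction"
    expression = "expression"
    functional_alteration_patient_cells = "functional_alteration_patient_cells"
    functional_alteration_nonpatient_cells = "functional_alteration_nonpatient_cells"
    model_organism = "model_organism"
    cell_culture_model = "cell_culture_model"
    rescue_human = "rescue_human"
    rescue_model_organism = "rescue_model_organism"
    rescue_cell_culture = "rescue_cell_culture"
    rescue_patient_cells = "rescue_patient_cells"


#: Model-system and rescue categories subject to the panel's phenotype gate:
#: evidence from a model whose phenotype the panel judged inconsistent with
#: the disease contributes zero points.
MODEL_SYSTEM_CATEGORIES = frozenset(
    {
        ExperimentalCategory.model_organism,
        ExperimentalCategory.cell_culture_model,
        ExperimentalCategory.rescue_human,
        ExperimentalCategory.rescue_model_organism,
        ExperimentalCategory.rescue_cell_culture,
        ExperimentalCategory.rescue_patient_cells,
    }
)


class ExpertOverride(str, Enum):
    none = "none"
    disputed = "disputed"
    refuted = "refuted"


class FrequencyAssessment(_PointsModel):
    """Outcome of the allele-frequency admissibility check for one variant."""

    threshold: float
    filtering_af: float
    worst_population: str = ""
    passes: Optional[bool] = None
    reason: str = ""


class ProbandVariantEvidence(_PointsModel):
    proband_id: str
    variant_class: VariantClass
    de_novo: DeNovoStatus = DeNovoStatus.none
    phase_for_AR: Phase = Phase.not_applicable
    meets_diagnostic_criteria: bool = True
    awarded_points: Optional[Decimal] = None
    variant_frequency_check: Optional[FrequencyAssessment] = None


class SegregationEvidence(_PointsModel):
    family_id: str
    informative_meioses: Optional[int] = Field(default=None, ge=0)
    published_lod: Optional[Decimal] = None
    sequencing_approach: SequencingApproach = SequencingApproach.candidate_gene


class CaseControlEvidence(_PointsModel):
    study_id: str
    design: str = "single_variant"  # single_variant | aggregate
    case_allele_count: Optional[int] = Field(default=None, ge=0)
    case_allele_number: Optional[int] = Field(default=None, ge=0)
    control_allele_count: Optional[int] = Field(default=None, ge=0)
    control_allele_number: Optional[int] = Field(default=None, ge=0)
    awarded_points: Decimal = Decimal(0)

    @field_validator("design")
    @classmethod
    def _design_known(cls, v):
        if v not in ("single_variant", "aggregate"):
            raise ValueError("design must be single_variant or aggregate")
        return v


class ExperimentalEvidenceItem(_PointsModel):
    category: ExperimentalCategory
    phenotype_consistent: Optional[bool] = None
    awarded_points: Optional[Decimal] = None


class GeneDiseaseRecord(_PointsModel):
    """One gene-disease-inheritance curation with all collected evidence."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    gene_symbol: str = Field(min_length=1)
    disease_label: str = "arrhythmogenic right ventricular cardiomyopathy"
    inheritance: Inheritance = Inheritance.AD
    proband_evidence: list[ProbandVariantEvidence] = Field(default_factory=list)
    segregation_evidence: list[SegregationEvidence] = Field(default_factory=list)
    case_control_evidence: list[CaseControlEvidence] = Field(default_factory=list)
    experimental_evidence: list[ExperimentalEvidenceItem] = Field(default_factory=list)
    replicated_over_time: bool = False
    expert_override: ExpertOverride = ExpertOverride.none
    curator_id: str = ""
    curation_date: Optional[datetime.date] = None


def _points_granular(points: Decimal) -> bool:
    return points % POINT_STEP == 0


def validate_record(record: GeneDiseaseRecord, matrix: ScoreMatrix) -> list[str]:
    """Collect every invariant and matrix-range violation as a message.

    Returns an empty list iff the record is internally consistent and every
    adjudicated award falls inside the matrix range for its category.
    Violations are reported, never raised, and the result is independent of
    evidence-list order (messages are sorted).
    """
    from .genetic import resolve_variant_category  # local import, no cycle at load

    violations: list[str] = []
    if not record.gene_symbol.strip():
        violations.append("gene_symbol: must be a nonempty HGNC symbol")

    for ev in record.proband_evidence:
        tag = f"proband_evidence[{ev.proband_id}]"
        try:
            category = resolve_variant_category(ev, record.inheritance)
        except ValueError as exc:
            violations.append(f"{tag}.variant_class: {exc}")
            continue
        if ev.awarded_points is not None:
            spec = matrix.genetic.variant_categories[category]
            if not spec.contains(ev.awarded_points):
                lo, hi = spec.range
                violations.append(
                    f"{tag}.awarded_points: {ev.awarded_points} outside "
                    f"range [{lo}, {hi}] for category {category}"
                )
            if not _points_granular(ev.awarded_points):
                violations.append(
                    f"{tag}.awarded_points: {ev.awarded_points} is not a "
                    f"multiple of {POINT_STEP}"
                )

    for seg in record.segregation_evidence:
        tag = f"segregation_evidence[{seg.family_id}]"
        given = [
            seg.informative_meioses is not None,
            seg.published_lod is not None,
        ]
        if sum(given) != 1:
            violations.append(
                f"{tag}: exactly one of informative_meioses / published_lod "
                "must be supplied"
            )

    for cc in record.case_control_evidence:
        tag = f"case_control_evidence[{cc.study_id}]"
        lo, hi = matrix.genetic.case_control.per_study_range
        if not (lo <= cc.awarded_points <= hi):
            violations.append(
                f"{tag}.awarded_points: {cc.awarded_points} outside [{lo}, {hi}]"
            )
        for side in ("case", "control"):
            ac = getattr(cc, f"{side}_allele_count")
            an = getattr(cc, f"{side}_allele_number")
            if ac is not None and an is not None and ac > an:
                violations.append(
                    f"{tag}.{side}_allele_count: {ac} exceeds allele_number {an}"
                )

    for i, item in enumerate(record.experimental_evidence):
        tag = f"experimental_evidence[{i}:{item.category.value}]"
        spec = matrix.experimental.categories[item.category.value]
        if item.category in MODEL_SYSTEM_CATEGORIES and item.phenotype_consistent is None:
            violations.append(
                f"{tag}.phenotype_consistent: required for model-system and "
                "rescue categories"
            )
        if item.awarded_points is not None and not spec.contains(item.awarded_points):
            lo, hi = spec.range
            violations.append(
                f"{tag}.awarded_points: {item.awarded_points} outside [{lo}, {hi}]"
            )

    return sorted(violations)


def _canonical_payload(record: GeneDiseaseRecord) -> dict:
    data = record.model_dump(mode="json", exclude_none=True)
    data["schema_version"] = SCHEMA_VERSION
    return data


def save_curation(
    record: GeneDiseaseRecord, path: str | Path, matrix: ScoreMatrix | None = None
) -> None:
    """Write a record to canonical JSON; refuses to persist an invalid record."""
    from .matrix import default_matrix

    matrix = matrix or default_matrix()
    violations = validate_record(record, matrix)
    if violations:
        raise ValueError(
            "refusing to save invalid record:\n" + "\n".join(violations)
        )
    payload = _canonical_payload(record)
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n"
    )


def load_curation(path: str | Path) -> GeneDiseaseRecord:
    """Read a curation record from JSON (canonical) or YAML.

    Raises ``ValueError`` with file context on malformed input or an
    unrecognized schema version.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"{path}: cannot parse curation file: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"{path}: curation file must hold a single mapping")
    version = data.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unknown schema version {version!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    return GeneDiseaseRecord.model_validate(data)
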