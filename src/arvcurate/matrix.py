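"""Score-matrix configuration: per-category defaults, ranges and caps.

The matrix carries every numeric constant of the semiquantitative framework
(variant-evidence defaults and caps, the segregation LOD-to-points mapping,
case-control and subtotal caps) so that panel-specific revisions are a config
edit, not a code change. A default matrix is shipped with the package; users
may supply their own YAML/JSON file. Every pipeline run logs the matrix
checksum so reports are traceable to the exact constants used.
"""

from __future__ import annotations

import hashlib
import json
from decimal import Decimal
from pathlib import Path
from typing import Any, get_args

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from importlib import resources

__all__ = [
    "CategorySpec",
    "SegregationBin",
    "ScoreMatrix",
    "load_matrix",
    "default_matrix",
]

POINT_STEP = Decimal("0.05")


def as_points(value: Any) -> Decimal:
    """Coerce a numeric value to an exact Decimal (floats via repr)."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, bool):
        raise TypeError("points may not be boolean")
    return Decimal(str(value))


class _PointsModel(BaseModel):
    """Base model coercing every Decimal field through :func:`as_points`."""

    model_config = ConfigDict(extra="forbid")

    @field_validator("*", mode="before")
    @classmethod
    def _coerce_decimal(cls, v, info):
        field = cls.model_fields.get(info.field_name)
        if field is None or v is None:
            return v
        ann = field.annotation
        if ann is Decimal or set(get_args(ann)) == {Decimal, type(None)}:
            return as_points(v)
        return v


class CategorySpec(_PointsModel):
    """Default points, permitted range and optional cap for one category."""

    default: Decimal
    range: tuple[Decimal, Decimal]
    cap: Decimal | None = None

    @field_validator("range", mode="before")
    @classmethod
    def _coerce_range(cls, v):
        lo, hi = v
        return (as_points(lo), as_points(hi))

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.range
        if not (lo <= self.default <= hi):
            raise ValueError(f"default {self.default} outside range [{lo}, {hi}]")
        if lo > hi:
            raise ValueError("range lower bound exceeds upper bound")
        if self.cap is not None and self.cap < 0:
            raise ValueError("cap must be nonnegative")
        return self

    def contains(self, points: Decimal) -> bool:
        lo, hi = self.range
        return lo <= points <= hi


class SegregationBin(_PointsModel):
    min_lod: Decimal
    points: Decimal


class SegregationSpec(_PointsModel):
    cap: Decimal
    bins: dict[str, list[SegregationBin]]

    @model_validator(mode="after")
    def _sorted_bins(self):
        for approach, bins in self.bins.items():
            self.bins[approach] = sorted(bins, key=lambda b: b.min_lod)
        return self


class CaseControlSpec(_PointsModel):
    per_study_range: tuple[Decimal, Decimal]
    cap: Decimal

    @field_validator("per_study_range", mode="before")
    @classmethod
    def _coerce_range(cls, v):
        lo, hi = v
        return (as_points(lo), as_points(hi))


class GeneticSpec(_PointsModel):
    cap: Decimal
    variant_cap: Decimal
    variant_categories: dict[str, CategorySpec]
    segregation: SegregationSpec
    case_control: CaseControlSpec


class ExperimentalGroup(_PointsModel):
    cap: Decimal
    categories: list[str]


class ExperimentalSpec(_PointsModel):
    cap: Decimal
    groups: dict[str, ExperimentalGroup]
    categories: dict[str, CategorySpec]

    @model_validator(mode="after")
    def _groups_cover_categories(self):
        grouped = [c for g in self.groups.values() for c in g.categories]
        if sorted(grouped) != sorted(self.categories):
            raise ValueError("experimental groups must partition the category set")
        return self

    def group_of(self, category: str) -> str:
        for name, group in self.groups.items():
            if category in group.categories:
                return name
        raise KeyError(f"category {category!r} not in any experimental group")


class ScoreMatrix(_PointsModel):
    """Full scoring configuration for one curation framework revision."""

    schema_version: str
    total_max: Decimal
    genetic: GeneticSpec
    experimental: ExperimentalSpec

    @model_validator(mode="after")
    def _caps_consistent(self):
        if self.genetic.cap + self.experimental.cap != self.total_max:
            raise ValueError(
                "genetic cap + experimental cap must equal total maximum"
            )
        return self

    def checksum(self) -> str:
        """SHA-256 over the canonical JSON dump of the matrix."""
        payload = json.dumps(
            self.model_dump(mode="json"), sort_keys=True, separators=(",", ":")
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def load_matrix(path: str | Path) -> ScoreMatrix:
    """Load a score matrix from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return ScoreMatrix.model_validate(data)


def default_matrix() -> ScoreMatrix:
    """The matrix shipped with the package (framework SOP defaults)."""
    ref = resources.files("arvcurate.data").joinpath("score_matrix.yaml")
    return ScoreMatrix.model_validate(yaml.safe_load(ref.read_text()))
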