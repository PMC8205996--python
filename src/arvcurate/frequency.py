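"""Allele-frequency admissibility of candidate variants.

For a dominant disease of prevalence P, a pathogenic variant cannot be more
common in the population than the disease it causes allows. The maximum
credible population allele frequency is

    AF_max = prevalence x max_allelic_contribution x (1 / penetrance)
             x inheritance_factor

where max_allelic_contribution bounds the fraction of cases attributable to
the single most common pathogenic variant, and the inheritance factor
converts affected genotypes to alleles (0.5 for monoallelic dominant
disease).

An observed allele count is compared through its filtering allele
frequency: the one-sided lower confidence bound on the true frequency given
ac observed alleles among an sampled, obtained by inverting the Poisson
tail P(X >= ac | lambda) = 1 - confidence and dividing lambda by an. This
is deliberately conservative — a variant seen a few times in a small
population is not condemned by its noisy point estimate.

A variant passes when its worst (highest) filtering frequency across
adequately sampled populations does not exceed the threshold. Founder
variants may be exempted explicitly with a logged justification, since a
bona fide founder allele legitimately exceeds generic cutoffs in its
founder region.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .evidence import FrequencyAssessment

__all__ = [
    "FrequencyParams",
    "PopulationFrequency",
    "FrequencyAssessment",
    "max_credible_af",
    "filtering_allele_frequency",
    "assess_variant",
    "ARVC_DEFAULTS",
]


class FrequencyParams(BaseModel):
    """Disease-model parameters for the allele-frequency threshold."""

    model_config = ConfigDict(extra="forbid")

    prevalence: float = Field(gt=0, le=1)
    max_allelic_contribution: float = Field(gt=0, le=1)
    penetrance: float = Field(gt=0, le=1)
    inheritance_factor: float = Field(gt=0, le=1)


#: Shipped defaults for ARVC (prevalence ~1/1000, dominant, reduced
#: penetrance, no single variant assumed to explain >10% of cases). These
#: are configuration, not ground truth; override per panel policy.
ARVC_DEFAULTS = FrequencyParams(
    prevalence=1 / 1000,
    max_allelic_contribution=0.1,
    penetrance=0.5,
    inheritance_factor=0.5,
)

DEFAULT_CONFIDENCE = 0.95
DEFAULT_MIN_ALLELE_NUMBER = 2000


class PopulationFrequency(BaseModel):
    """Observed allele counts for one reference population."""

    model_config = ConfigDict(extra="forbid")

    population_label: str
    allele_count: int = Field(ge=0)
    allele_number: int = Field(gt=0)

    @model_validator(mode="after")
    def _ac_le_an(self):
        if self.allele_count > self.allele_number:
            raise ValueError("allele_count exceeds allele_number")
        return self


def max_credible_af(params: FrequencyParams) -> float:
    """Highest population allele frequency compatible with causality."""
    return (
        params.prevalence
        * params.max_allelic_contribution
        * (1.0 / params.penetrance)
        * params.inheritance_factor
    )


def filtering_allele_frequency(
    ac: int, an: int, confidence: float = DEFAULT_CONFIDENCE
) -> float:
    """One-sided lower confidence bound on the true allele frequency.

    Solves P(X >= ac | Poisson(lambda)) = 1 - confidence for lambda and
    returns lambda / an; with no observations the bound is 0. The Poisson
    tail inverts in closed form through the chi-square quantile:
    lambda = chi2.ppf(1 - confidence, 2 * ac) / 2.
    """
    if an <= 0:
        raise ValueError("allele_number must be positive")
    if not (0 <= ac <= an):
        raise ValueError("allele_count must lie in [0, allele_number]")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if ac == 0:
        return 0.0
    lam = stats.chi2.ppf(1.0 - confidence, 2 * ac) / 2.0
    return float(lam) / an


def assess_variant(
    popfreqs: list[PopulationFrequency],
    params: FrequencyParams = ARVC_DEFAULTS,
    confidence: float = DEFAULT_CONFIDENCE,
    min_allele_number: int = DEFAULT_MIN_ALLELE_NUMBER,
    founder_exempt: bool = False,
) -> FrequencyAssessment:
    """Pass/fail admissibility of one variant across reference populations.

    The filtering frequency is taken as the maximum over populations with
    adequate sampling depth (allele_number >= min_allele_number); the
    assessment names the worst population. When no population is adequately
    sampled the verdict is undetermined (``passes is None``) with a warning
    rather than a silent pass.
    """
    if not popfreqs:
        raise ValueError("at least one population record is required")
    threshold = max_credible_af(params)

    if founder_exempt:
        return FrequencyAssessment(
            threshold=threshold,
            filtering_af=float("nan"),
            worst_population="",
            passes=True,
            reason="founder variant exempted from frequency filtering",
        )

    usable = [p for p in popfreqs if p.allele_number >= min_allele_number]
    if not usable:
        return FrequencyAssessment(
            threshold=threshold,
            filtering_af=0.0,
            worst_population="",
            passes=None,
            reason=(
                f"no population sampled at allele_number >= {min_allele_number}; "
                "frequency admissibility undetermined"
            ),
        )
    worst = max(
        usable,
        key=lambda p: (
            filtering_allele_frequency(p.allele_count, p.allele_number, confidence),
            p.population_label,
        ),
    )
    faf = filtering_allele_frequency(
        worst.allele_count, worst.allele_number, confidence
    )
    passes = faf <= threshold
    if passes:
        reason = (
            f"filtering allele frequency {faf:.3g} <= threshold "
            f"{threshold:.3g} (worst population: {worst.population_label})"
        )
    else:
        reason = (
            f"filtering allele frequency {faf:.3g} exceeds threshold "
            f"{threshold:.3g} in population {worst.population_label}"
        )
    return FrequencyAssessment(
        threshold=threshold,
        filtering_af=faf,
        worst_population=worst.population_label,
        passes=passes,
        reason=reason,
    )
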