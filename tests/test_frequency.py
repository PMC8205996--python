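"""Allele-frequency admissibility: threshold formula, Poisson bound, assessment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from arvcurate.frequency import (
    ARVC_DEFAULTS,
    FrequencyParams,
    PopulationFrequency,
    assess_variant,
    filtering_allele_frequency,
    max_credible_af,
)


def params(**kw):
    base = dict(
        prevalence=1 / 1000,
        max_allelic_contribution=0.1,
        penetrance=0.5,
        inheritance_factor=0.5,
    )
    base.update(kw)
    return FrequencyParams(**base)


class TestMaxCredibleAF:
    def test_worked_example(self):
        assert max_credible_af(params()) == pytest.approx(1.0e-4)

    def test_upper_bound_limit(self):
        p = params(max_allelic_contribution=1, penetrance=1)
        assert max_credible_af(p) == pytest.approx(p.prevalence / 2)

    def test_halving_penetrance_doubles_threshold(self):
        assert max_credible_af(params(penetrance=0.25)) == pytest.approx(
            2 * max_credible_af(params())
        )

    def test_linear_in_prevalence_and_contribution(self):
        base = max_credible_af(params())
        assert max_credible_af(params(prevalence=3 / 1000)) == pytest.approx(3 * base)
        assert max_credible_af(
            params(max_allelic_contribution=0.2)
        ) == pytest.approx(2 * base)


def _poisson_bound_oracle(ac: int, confidence: float) -> float:
    """Dense grid search for lambda with P(X >= ac | lambda) = 1 - confidence."""
    import numpy as np

    grid = np.linspace(1e-6, ac * 3 + 10, 2_000_001)
    tails = stats.poisson.sf(ac - 1, grid)  # P(X >= ac)
    idx = int(np.argmin(np.abs(tails - (1 - confidence))))
    return float(grid[idx])


class TestFilteringAlleleFrequency:
    def test_zero_observations_zero_bound(self):
        assert filtering_allele_frequency(0, 10_000) == 0.0

    def test_worked_example_against_grid_oracle(self):
        got = filtering_allele_frequency(5, 10_000, 0.95)
        assert got == pytest.approx(1.970e-4, abs=1e-6)
        assert got == pytest.approx(_poisson_bound_oracle(5, 0.95) / 10_000, abs=1e-7)

    @pytest.mark.parametrize("ac", [1, 3, 17, 120])
    def test_matches_grid_oracle(self, ac):
        an = 50_000
        assert filtering_allele_frequency(ac, an, 0.95) == pytest.approx(
            _poisson_bound_oracle(ac, 0.95) / an, rel=1e-4
        )

    def test_monomorphic_bracket(self):
        b = filtering_allele_frequency(1000, 1000, 0.95)
        assert 0.0 < b < 1.0

    def test_an_zero_errors(self):
        with pytest.raises(ValueError):
            filtering_allele_frequency(1, 0)

    @given(
        ac=st.integers(1, 500),
        an=st.integers(1000, 100_000),
        conf=st.floats(0.5, 0.99),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotonicity(self, ac, an, conf):
        f = filtering_allele_frequency(ac, an, conf)
        assert f <= filtering_allele_frequency(ac + 1, an, conf)  # increasing in AC
        assert f >= filtering_allele_frequency(ac, an + 500, conf)  # decreasing in AN
        assert f >= filtering_allele_frequency(ac, an, conf + 0.005)  # dec. in conf.


def pop(label, ac, an):
    return PopulationFrequency(population_label=label, allele_count=ac, allele_number=an)


class TestAssessVariant:
    def test_absent_everywhere_passes(self):
        pops = [pop("global", 0, 100_000), pop("eur", 0, 30_000)]
        assert assess_variant(pops).passes is True

    def test_subpopulation_failure_names_worst(self):
        pops = [pop("global", 10, 200_000), pop("European", 40, 20_000)]
        a = assess_variant(pops)
        assert a.passes is False
        assert a.worst_population == "European"

    def test_direct_threshold_comparison(self):
        # AC/AN chosen so the bound clearly exceeds the 1e-4 threshold
        a = assess_variant([pop("global", 100, 100_000)])
        assert a.filtering_af > a.threshold
        assert a.passes is False

    def test_permutation_invariant(self):
        pops = [pop("a", 3, 50_000), pop("b", 9, 40_000), pop("c", 0, 90_000)]
        first = assess_variant(pops)
        second = assess_variant(list(reversed(pops)))
        assert (first.passes, first.worst_population, first.filtering_af) == (
            second.passes,
            second.worst_population,
            second.filtering_af,
        )

    def test_all_populations_undersampled_is_undetermined(self):
        a = assess_variant([pop("tiny", 1, 500)])
        assert a.passes is None
        assert "undetermined" in a.reason

    def test_founder_exemption(self):
        a = assess_variant([pop("founder", 500, 20_000)], founder_exempt=True)
        assert a.passes is True
        assert "founder" in a.reason

    def test_no_populations_errors(self):
        with pytest.raises(ValueError):
            assess_variant([])
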