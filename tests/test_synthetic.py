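"""Synthetic generators: seed determinism, ground-truth tallies, the fixture."""

import math
from decimal import Decimal

import pytest

import arvcurate.synthetic as synthetic
from arvcurate.classification import ValidityClass
from arvcurate.pipeline import score_record
from arvcurate.synthetic import (
    arvc_fixture,
    generate_curation,
    generate_variant_table,
    simulate_segregation,
)

D = Decimal

TARGETS = ("no_known_relationship", "limited", "moderate", "strong", "definitive")
BAND_RANGES = {
    "no_known_relationship": (D(0), D(0)),
    "limited": (D("0.05"), D("6.95")),
    "moderate": (D(7), D("11.95")),
    "strong": (D(12), D(18)),
    "definitive": (D(12), D(18)),
}


@pytest.mark.parametrize("target", TARGETS)
def test_generator_lands_in_target_band(target, matrix):
    for seed in range(5):
        sc = generate_curation(seed, target, matrix)
        lo, hi = BAND_RANGES[target]
        assert lo <= sc.expected.total <= hi
        assert sc.expected.classification == target


def test_same_seed_same_record(matrix):
    a = generate_curation(11, "moderate", matrix)
    b = generate_curation(11, "moderate", matrix)
    assert a.record == b.record
    assert a.expected == b.expected


def test_oracle_module_shares_no_scoring_imports():
    """The generator's tally must be independent of the scoring modules."""
    import arvcurate.experimental
    import arvcurate.genetic

    assert "arvcurate.genetic" not in {
        getattr(v, "__name__", None) for v in vars(synthetic).values()
    }
    source = open(synthetic.__file__).read()
    for banned in ("from .genetic", "from .experimental", "from .classification",
                   "from .pipeline", "import genetic", "import experimental"):
        assert banned not in source


class TestSimulateSegregation:
    def test_zero_meioses_zero_lod(self):
        seg, lod = simulate_segregation(0, 0)
        assert seg.informative_meioses == 0 and lod == 0.0

    def test_seventeen_meioses_reaches_top_bin(self, matrix):
        from arvcurate.genetic import segregation_points

        seg, lod = simulate_segregation(1, 17)
        assert lod == pytest.approx(17 * math.log10(2), abs=1e-3)
        assert segregation_points([seg], matrix) == D(3)

    def test_full_noise_excludes_everything(self):
        seg, lod = simulate_segregation(3, 20, noise_fraction=1.0)
        assert seg.informative_meioses == 0 and lod == 0.0

    def test_partial_noise_reduces_count(self):
        seg, _ = simulate_segregation(5, 200, noise_fraction=0.5)
        assert 0 < seg.informative_meioses < 200


class TestVariantTable:
    def test_exact_counts(self):
        df = generate_variant_table({"PKP2": {"P": 3}}, seed=1)
        assert len(df) == 3
        assert (df["gene"] == "PKP2").all()
        assert (df["significance"] == "P").all()

    def test_empty_spec(self):
        assert generate_variant_table({}, seed=1).empty

    def test_shuffle_is_seeded(self):
        spec = {"A": {"P": 5}, "B": {"VUS": 5}}
        assert generate_variant_table(spec, seed=1).equals(
            generate_variant_table(spec, seed=1)
        )
        assert not generate_variant_table(spec, seed=1).equals(
            generate_variant_table(spec, seed=2)
        )


class TestArvcFixture:
    def test_twenty_six_records(self, fixture):
        assert len(fixture.records) == 26
        assert len(fixture.pairs) == 26
        assert len({r.gene_symbol for r in fixture.records}) == 26

    def test_records_score_to_their_expected_breakdowns(self, fixture, matrix):
        for record in fixture.records:
            bd = score_record(record, matrix)
            exp = fixture.expected[record.gene_symbol]
            assert bd.genetic_subtotal == exp.genetic_subtotal, record.gene_symbol
            assert bd.experimental_subtotal == exp.experimental_subtotal
            assert bd.total == exp.total

    def test_definitive_genes_as_published(self, fixture):
        definitive = {
            g for g, e in fixture.expected.items() if e.classification == "definitive"
        }
        assert definitive == {"PKP2", "DSP", "DSG2", "DSC2", "JUP", "TMEM43"}

    def test_gated_model_contributes_nothing_for_ctnna3(self, fixture, matrix):
        ctnna3 = next(r for r in fixture.records if r.gene_symbol == "CTNNA3")
        assert any(
            it.phenotype_consistent is False for it in ctnna3.experimental_evidence
        )
        assert score_record(ctnna3, matrix).experimental_subtotal == D(0)
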