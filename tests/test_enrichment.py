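import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import regenrich as rr
from regenrich.association import TopSnpSet
from regenrich.enrichment import (
    empirical_p,
    format_p,
    maf_bin_histogram,
    maf_bin_index,
    null_histogram,
    permutation_test,
    permute_labels,
    randomization_test,
    sample_matched_set,
    summarize,
)
from regenrich.ld import TableLdSource
from regenrich.types import LdTable, RegulatoryCatalog

from conftest import make_panel


class TestMafBins:
    @pytest.mark.parametrize(
        "maf,expected",
        [(0.0, 0), (0.049, 0), (0.05, 1), (0.049999, 0), (0.45, 9),
         (0.499, 9), (0.50, 9)],
    )
    def test_bin_boundaries(self, maf, expected):
        assert maf_bin_index(maf) == expected

    def test_histogram_sums_to_set_size(self, small_study, rng):
        snps = list(rng.choice(small_study.panel.snp_ids, 37, replace=False))
        hist = maf_bin_histogram(snps, small_study.panel)
        assert hist.sum() == 37

    def test_absent_snp_raises(self, small_study):
        with pytest.raises(KeyError):
            maf_bin_histogram(["nope"], small_study.panel)


class TestSampleMatchedSet:
    def test_exact_histogram_and_no_duplicates(self, small_study, rng):
        target = maf_bin_histogram(small_study.panel.snp_ids[:40], small_study.panel)
        for _ in range(20):
            draw = sample_matched_set(small_study.panel, target, rng)
            assert len(draw) == 40
            assert np.array_equal(
                maf_bin_histogram(draw, small_study.panel), target
            )

    def test_demand_equals_supply_returns_whole_panel(self, rng):
        panel = make_panel([0.02, 0.03, 0.12, 0.13])
        target = maf_bin_histogram(panel.snp_ids, panel)
        assert sample_matched_set(panel, target, rng) == set(panel.snp_ids)

    def test_insufficient_supply_names_the_bin(self, rng):
        panel = make_panel([0.02, 0.12])
        target = np.zeros(10, dtype=int)
        target[0] = 2
        with pytest.raises(ValueError, match=r"bin 0 \[0\.00, 0\.05\)"):
            sample_matched_set(panel, target, rng)

    def test_exclusions_respected(self, rng):
        panel = make_panel([0.02, 0.03, 0.04])
        target = np.zeros(10, dtype=int)
        target[0] = 1
        for _ in range(20):
            draw = sample_matched_set(panel, target, rng, exclude={"rs0", "rs1"})
            assert draw == {"rs2"}

    def test_within_bin_draws_uniform(self):
        """chi-square goodness of fit over all 2-subsets of a 4-SNP bin."""
        from itertools import combinations

        from scipy import stats

        panel = make_panel([0.01, 0.02, 0.03, 0.04])
        target = np.zeros(10, dtype=int)
        target[0] = 2
        outcomes = {frozenset(c): 0 for c in combinations(panel.snp_ids, 2)}
        n_draws = 6000
        for i in range(n_draws):
            rng = np.random.default_rng([99, i])
            outcomes[frozenset(sample_matched_set(panel, target, rng))] += 1
        counts = np.array(list(outcomes.values()))
        res = stats.chisquare(counts)
        assert res.pvalue > 0.001


class TestEmpiricalP:
    def test_direct_formula(self):
        assert empirical_p(5, [1, 2, 3]) == 0.25

    def test_observed_at_or_below_all_nulls(self):
        assert empirical_p(1, [1, 2, 3]) == 1.0
        assert empirical_p(0, [1, 2, 3]) == 1.0

    def test_ties_count_toward_tail(self):
        assert empirical_p(3, [3, 1, 1]) == 0.5

    @given(
        st.integers(min_value=0, max_value=20),
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=50),
    )
    def test_bounds_and_monotonicity(self, observed, null):
        p = empirical_p(observed, null)
        n = len(null)
        assert 1 / (n + 1) <= p <= 1.0
        assert empirical_p(observed + 1, null) <= p


def _null_ld_source():
    return TableLdSource(LdTable())


class TestRandomizationTest:
    def test_empty_catalog_gives_p_one(self, small_study):
        top = TopSnpSet(
            small_study.panel.snp_ids[:10], 1.0,
            maf_bin_histogram(small_study.panel.snp_ids[:10], small_study.panel),
        )
        res = randomization_test(
            top, small_study.panel, RegulatoryCatalog(),
            TableLdSource(small_study.ld_table, small_study.panel),
            n_sets=50, seed=1,
        )
        assert res.observed_blocks == 0
        assert (res.null_blocks == 0).all()
        assert res.empirical_p == 1.0

    def test_minimum_p_formats_as_below_threshold(self, small_study):
        # observed above every null renders "< 0.001" at 1000 iterations
        assert format_p(1 / 1001) == "< 0.001"

    def test_deterministic_given_seed(self, small_study):
        ids = small_study.panel.snp_ids[:20]
        top = TopSnpSet(ids, 1.0, maf_bin_histogram(ids, small_study.panel))
        src = TableLdSource(small_study.ld_table, small_study.panel)
        a = randomization_test(
            top, small_study.panel, small_study.catalog, src, n_sets=30, seed=5
        )
        b = randomization_test(
            top, small_study.panel, small_study.catalog, src, n_sets=30, seed=5
        )
        assert np.array_equal(a.null_blocks, b.null_blocks)
        assert a.empirical_p == b.empirical_p

    def test_ld_expansion_grows_observed_set(self, small_study):
        ids = small_study.panel.snp_ids[:5]
        top = TopSnpSet(ids, 1.0, maf_bin_histogram(ids, small_study.panel))
        src = TableLdSource(small_study.ld_table, small_study.panel)
        raw = randomization_test(
            top, small_study.panel, small_study.catalog, src,
            n_sets=10, seed=1, ld_expand_flag=False,
        )
        exp = randomization_test(
            top, small_study.panel, small_study.catalog, src,
            n_sets=10, seed=1, ld_expand_flag=True,
        )
        assert exp.observed_members >= raw.observed_members


class TestPermutationTest:
    def test_relabelings_preserve_counts(self, rng):
        is_case = np.array([True] * 30 + [False] * 70)
        for _ in range(50):
            perm = permute_labels(is_case, rng)
            assert perm.sum() == 30 and perm.size == 100

    def test_deterministic_null_vector(self, small_study):
        src = TableLdSource(small_study.ld_table, small_study.panel)
        kw = dict(
            genotypes=small_study.genotypes, phenotype=small_study.phenotype,
            panel=small_study.panel, catalog=small_study.catalog, source=src,
            p_threshold=0.01, n_perms=3, seed=17,
        )
        a = permutation_test(**kw)
        b = permutation_test(**kw)
        assert np.array_equal(a.null_blocks, b.null_blocks)

    def test_observed_exceeds_null_with_planted_enrichment(self, small_study):
        src = TableLdSource(small_study.ld_table, small_study.panel)
        res = permutation_test(
            small_study.genotypes, small_study.phenotype, small_study.panel,
            small_study.catalog, src, p_threshold=0.01, ld_expand_flag=True,
            n_perms=100, seed=2,
        )
        assert res.observed_blocks > res.null_mean


class TestReporting:
    def test_two_point_sd_is_sqrt_two(self):
        res = rr.EnrichmentResult(
            method="randomization", mode="esnp", ld_expanded=False,
            observed_blocks=5, null_blocks=np.array([2, 4]),
            empirical_p=empirical_p(5, [2, 4]), n_iterations=2, seed=0,
        )
        df = summarize([res])
        assert df.loc[0, "expected_blocks"] == 3.00
        assert df.loc[0, "sd"] == pytest.approx(np.sqrt(2), abs=5e-3)

    @pytest.mark.parametrize(
        "p,rendered",
        [(0.0009, "< 0.001"), (0.001, "0.001"), (0.019, "0.019"), (1.0, "1.000")],
    )
    def test_p_value_formatting(self, p, rendered):
        assert format_p(p) == rendered

    def test_row_count_parity_and_histogram(self):
        res = rr.EnrichmentResult(
            method="permutation", mode="esnp", ld_expanded=True,
            observed_blocks=4, null_blocks=np.array([1, 1, 2, 3]),
            empirical_p=empirical_p(4, [1, 1, 2, 3]), n_iterations=4, seed=0,
        )
        assert len(summarize([res])) == 1
        hist = null_histogram(res)
        assert hist["frequency"].sum() == pytest.approx(1.0)
        assert dict(zip(hist["block_count"], hist["frequency"])) == {
            1: 0.5, 2: 0.25, 3: 0.25
        }
        assert (hist["observed"] == 4).all()
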