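import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import regenrich as rr
from regenrich.association import allelic_chisq, run_gwas, select_top_snps
from regenrich.types import MISSING, Phenotype


def pheno(case_mask):
    return Phenotype(np.asarray(case_mask, dtype=bool))


class TestAllelicChisq:
    def test_worked_table(self):
        """Cases 30/10 vs controls 20/20 minor/major alleles: chi2 = 16/3."""
        # 20 case samples: 10 hom-minor + 10 het -> 30 minor, 10 major
        # 20 control samples: 10 het + 10... construct exact allele counts
        codes = np.array([2] * 10 + [1] * 10 + [1] * 20)
        labels = pheno([True] * 20 + [False] * 20)
        res = allelic_chisq(codes, labels, "rsX")
        assert (res.case_minor, res.case_major) == (30, 10)
        assert (res.control_minor, res.control_major) == (20, 20)
        assert res.chi_square == pytest.approx(16 / 3, rel=1e-12)
        assert res.p_value == pytest.approx(0.02092, abs=1e-4)

    def test_equal_frequencies_give_null(self):
        codes = np.array([1, 1, 0, 2, 1, 1, 0, 2])
        labels = pheno([True] * 4 + [False] * 4)
        res = allelic_chisq(codes, labels)
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_monomorphic_flagged_degenerate(self):
        codes = np.zeros(10, dtype=int)
        res = allelic_chisq(codes, pheno([True] * 5 + [False] * 5))
        assert res.degenerate
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_missing_dropped_per_snp(self):
        codes = np.array([2, MISSING, 0, 0])
        res = allelic_chisq(codes, pheno([True, True, False, False]))
        assert res.n_used == 3
        assert res.case_minor == 2 and res.case_major == 0

    def test_all_missing_raises(self):
        codes = np.full(4, MISSING)
        with pytest.raises(ValueError, match="missing"):
            allelic_chisq(codes, pheno([True, True, False, False]))

    def test_matches_generic_contingency_oracle(self, rng):
        """Independent oracle: scipy's generic contingency chi-square."""
        for _ in range(300):
            tab = rng.integers(1, 60, size=(2, 2))
            n_case, n_ctrl = tab[0].sum(), tab[1].sum()
            # realize the allele table as genotype codes (all hets suffice
            # when counts are even; mix hom/het otherwise)
            cm, km = int(tab[0, 0]), int(tab[1, 0])
            codes = np.concatenate([
                [2] * (cm // 2), [1] * (cm % 2), [0] * ((n_case - cm) // 2 + (n_case - cm) % 2),
                [2] * (km // 2), [1] * (km % 2), [0] * ((n_ctrl - km) // 2 + (n_ctrl - km) % 2),
            ])
            ncase_s = (cm // 2) + (cm % 2) + (n_case - cm) // 2 + (n_case - cm) % 2
            labels = pheno([True] * ncase_s + [False] * (len(codes) - ncase_s))
            res = allelic_chisq(codes, labels)
            table = [
                [res.case_minor, res.case_major],
                [res.control_minor, res.control_major],
            ]
            if min(min(r) for r in table) == 0:
                continue
            expect = stats.chi2_contingency(table, correction=False)
            assert res.chi_square == pytest.approx(expect.statistic, rel=1e-9)
            assert res.p_value == pytest.approx(expect.pvalue, rel=1e-9)


class TestRunGwas:
    def test_one_result_per_panel_snp(self, small_study):
        results = run_gwas(
            small_study.genotypes, small_study.phenotype, small_study.panel
        )
        assert [r.snp_id for r in results] == small_study.panel.snp_ids

    def test_scan_equals_columnwise_oracle(self, small_study, rng):
        results = run_gwas(
            small_study.genotypes, small_study.phenotype, small_study.panel
        )
        for j in rng.choice(small_study.genotypes.n_snps, 40, replace=False):
            single = allelic_chisq(
                small_study.genotypes.column(j), small_study.phenotype,
                small_study.panel.records[j].snp_id,
            )
            assert results[j].chi_square == pytest.approx(single.chi_square, rel=1e-12)
            assert results[j].p_value == pytest.approx(single.p_value, rel=1e-12)
            assert results[j].case_minor == single.case_minor

    def test_sample_order_invariance(self, small_study, rng):
        perm = rng.permutation(small_study.genotypes.n_samples)
        shuffled = rr.GenotypeMatrix(
            small_study.genotypes.codes[perm],
            [small_study.genotypes.sample_ids[i] for i in perm],
        )
        ph = Phenotype(small_study.phenotype.is_case[perm])
        a = run_gwas(small_study.genotypes, small_study.phenotype, small_study.panel)
        b = run_gwas(shuffled, ph, small_study.panel)
        for ra, rb in zip(a, b):
            assert ra.p_value == pytest.approx(rb.p_value, rel=1e-12)

    def test_null_type_one_error_rate(self, null_study):
        """One SNP per block: fraction with p < 0.05 near 0.05."""
        results = run_gwas(
            null_study.genotypes, null_study.phenotype, null_study.panel
        )
        reps = results[:: null_study.config.snps_per_block]
        n_sig = sum(r.p_value < 0.05 for r in reps)
        lo = stats.binom.ppf(0.005, len(reps), 0.05)
        hi = stats.binom.ppf(0.995, len(reps), 0.05)
        assert lo <= n_sig <= hi


class TestSelectTopSnps:
    def _results(self, small_study):
        return run_gwas(
            small_study.genotypes, small_study.phenotype, small_study.panel
        )

    def test_strict_threshold(self, small_study):
        results = self._results(small_study)
        top = select_top_snps(results, small_study.panel, 1e-3)
        by_id = {r.snp_id: r for r in results}
        assert all(by_id[s].p_value < 1e-3 for s in top.snp_ids)
        # exactly the strict-inequality winners
        assert set(top.snp_ids) == {r.snp_id for r in results if r.p_value < 1e-3}

    def test_histogram_sums_to_member_count(self, small_study):
        top = select_top_snps(self._results(small_study), small_study.panel, 0.05)
        assert top.maf_histogram.sum() == len(top.snp_ids)

    def test_monotone_in_threshold(self, small_study):
        results = self._results(small_study)
        t1 = select_top_snps(results, small_study.panel, 1e-3)
        t2 = select_top_snps(results, small_study.panel, 1e-2)
        assert set(t1.snp_ids) <= set(t2.snp_ids)

    def test_ordering_p_then_id(self, small_study):
        top = select_top_snps(self._results(small_study), small_study.panel, 0.05)
        by_id = {r.snp_id: r for r in self._results(small_study)}
        keys = [(by_id[s].p_value, s) for s in top.snp_ids]
        assert keys == sorted(keys)

    def test_degenerate_snps_never_selected(self):
        from conftest import make_panel

        panel = make_panel([0.0, 0.3])
        codes = np.column_stack(
            [np.zeros(8, dtype=np.int8), [0, 1, 2, 1, 0, 0, 1, 0]]
        )
        geno = rr.GenotypeMatrix(codes, [f"s{i}" for i in range(8)])
        labels = pheno([True] * 4 + [False] * 4)
        results = run_gwas(geno, labels, panel)
        assert results[0].degenerate
        top = select_top_snps(results, panel, 0.999)
        assert "rs0" not in top.snp_ids


@given(
    st.lists(
        st.floats(min_value=1e-8, max_value=0.999), min_size=1, max_size=30
    ),
    st.floats(min_value=1e-4, max_value=0.5),
    st.floats(min_value=1e-4, max_value=0.5),
)
def test_select_top_monotone_property(pvals, t1, t2):
    """threshold t1 <= t2 implies top(t1) is a subset of top(t2)."""
    from regenrich.association import AssocResult

    from conftest import make_panel

    panel = make_panel([0.2] * len(pvals))
    results = [
        AssocResult(f"rs{i}", 1, 1, 1, 1, 0.0, p, len(pvals))
        for i, p in enumerate(pvals)
    ]
    lo, hi = min(t1, t2), max(t1, t2)
    top_lo = select_top_snps(results, panel, lo)
    top_hi = select_top_snps(results, panel, hi)
    assert set(top_lo.snp_ids) <= set(top_hi.snp_ids)
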