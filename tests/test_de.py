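"""Paired differential expression: folds, tests, BH, landscape filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import icpscreen as ic
from conftest import make_sample_table


def _matrix(rows: dict) -> ic.ExpressionMatrix:
    n = len(next(iter(rows.values()))) // 2
    samples = [f"T{i + 1}" for i in range(n)] + [f"N{i + 1}" for i in range(n)]
    return ic.ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


def bh_oracle(p):
    """Independent step-up implementation for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestFoldChange:
    def test_closed_form(self):
        m = _matrix({"G": [4, 4, 2, 2]})
        s = make_sample_table(2)
        assert ic.fold_change(m, s, s.tumor_samples, "G", pseudocount=0.0) == 2.0

    def test_identical_vectors_give_unity(self):
        m = _matrix({"G": [3, 5, 3, 5]})
        s = make_sample_table(2)
        for pc in (0.0, 0.5, 1.0):
            assert ic.fold_change(m, s, s.tumor_samples, "G", pseudocount=pc) == 1.0

    def test_all_zero_gene_pseudocount_identity(self):
        m = _matrix({"G": [0, 0, 0, 0]})
        s = make_sample_table(2)
        assert ic.fold_change(m, s, s.tumor_samples, "G", pseudocount=1.0) == 1.0

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_equivariance_at_zero_pseudocount(self, c):
        vals = np.array([4.0, 9.0, 1.0, 2.0, 3.0, 0.5])
        m1 = _matrix({"G": vals})
        m2 = _matrix({"G": vals * c})
        s = make_sample_table(3)
        f1 = ic.fold_change(m1, s, s.tumor_samples, "G", pseudocount=0.0)
        f2 = ic.fold_change(m2, s, s.tumor_samples, "G", pseudocount=0.0)
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_empty_stratum_rejected(self):
        m = _matrix({"G": [1, 1, 1, 1]})
        s = make_sample_table(2)
        with pytest.raises(ic.ValidationError):
            ic.fold_change(m, s, [], "G")


class TestPairedTest:
    def test_identical_tumor_normal_p_one(self):
        m = _matrix({"G": [2, 3, 4, 2, 3, 4]})
        s = make_sample_table(3)
        assert ic.paired_test(m, s, s.tumor_samples, "G") == 1.0

    def test_zero_variance_nonzero_diffs_p_zero(self):
        """Identical nonzero log2 differences: t statistic diverges, p -> 0."""
        assert ic.paired_t_pvalue([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_frozen_fixture_matches_t_oracle(self):
        diffs = np.array([0.8712, -0.2914, 1.5268, 0.0441, -0.6320,
                          1.1040, 0.3867, -0.1129, 0.9443, 0.5107])
        n = len(diffs)
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        expected = 2.0 * sps.t.sf(abs(t), n - 1)
        assert ic.paired_t_pvalue(diffs) == pytest.approx(expected, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ic.ValidationError):
            ic.paired_t_pvalue([1.0, 2.0])


class TestBHFdr:
    def test_hand_worked_examples(self):
        np.testing.assert_allclose(ic.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        np.testing.assert_allclose(ic.bh_fdr([0.005, 0.1]), [0.01, 0.1], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ic.bh_fdr([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ic.ValidationError):
            ic.bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(ic.bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_monotone_in_p_rank_and_bounded(self, p):
        q = ic.bh_fdr(p)
        assert (q <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestComputeDe:
    def test_vectorized_agrees_with_scalar_ops(self, small_cohort):
        m, s = small_cohort.matrix, small_cohort.samples
        members = s.tumor_samples
        de = ic.compute_de(m, s, members, "all")
        sub = de.set_index("gene_id")
        for gene in m.gene_ids[:15]:
            assert sub.loc[gene, "fold_change"] == pytest.approx(
                ic.fold_change(m, s, members, gene), rel=1e-12)
            assert sub.loc[gene, "p_value"] == pytest.approx(
                ic.paired_test(m, s, members, gene), abs=1e-12)

    def test_needs_three_pairs(self, small_cohort):
        m, s = small_cohort.matrix, small_cohort.samples
        with pytest.raises(ic.ValidationError, match="need >= 3"):
            ic.compute_de(m, s, s.tumor_samples[:2], "tiny")


class TestLandscapeFilter:
    def test_empty_de_table_everything_low(self, small_cohort):
        m, s = small_cohort.matrix, small_cohort.samples
        out = ic.landscape_filter(m, s, pd.DataFrame(columns=list(ic.de.DE_COLUMNS)))
        assert out["low"] == set(m.gene_ids)
        assert not out["expressed_de"] and not out["expressed_not_de"]

    def test_three_sets_partition_universe(self, small_cohort):
        m, s = small_cohort.matrix, small_cohort.samples
        de = ic.compute_de(m, s, s.tumor_samples, "all")
        out = ic.landscape_filter(m, s, de, min_fpkm=1.0, alpha=0.05)
        union = out["expressed_de"] | out["expressed_not_de"] | out["low"]
        assert union == set(m.gene_ids)
        assert len(out["expressed_de"]) + len(out["expressed_not_de"]) \
            + len(out["low"]) == len(m.gene_ids)

    def test_noise_free_cohort_separates_module_from_null(self):
        c = ic.simulate_cohort(ic.SimParams(n_pairs=20, n_module=9, n_null=60,
                                            sigma=0.0, rng_seed=11))
        de = ic.compute_de(c.matrix, c.samples, c.samples.tumor_samples, "all")
        out = ic.landscape_filter(c.matrix, c.samples, de)
        assert c.truth.module_genes <= out["expressed_de"]
        assert c.truth.null_genes <= out["expressed_not_de"]
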