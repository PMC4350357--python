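import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from accsig import (DesignError, InputError, SimConfig, bh_fdr, derive_signature,
                    generate_cohort, group_comparison, hierarchical_cluster,
                    paired_t_test, pca)
from conftest import make_matrix, make_paired_sheet, paired_matrix_from_deltas


def brute_force_bh(p, alpha=0.05):
    """Independent step-up oracle: literal definition, O(m^2)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        order = np.argsort(p, kind="stable")
        for rank, j in enumerate(order, start=1):
            if p[j] >= p[i] - 1e-300:
                candidates.append(m * p[j] / rank)
        q[i] = min(min(candidates), 1.0)
    return q, q <= alpha


class TestPairedT:
    def test_hand_computed_example(self):
        m, sheet = paired_matrix_from_deltas([[1.0, 2.0, 3.0]])
        res = paired_t_test(m, sheet)
        assert res.loc["g1", "t"] == pytest.approx(3.4641, abs=1e-4)
        assert res.loc["g1", "df"] == 2
        assert res.loc["g1", "p"] == pytest.approx(0.0742, abs=1e-4)

    def test_null_like_deltas_give_p_near_one(self):
        m, sheet = paired_matrix_from_deltas([[0.0, 0.0, 1e-4, -1e-4]])
        res = paired_t_test(m, sheet)
        assert abs(res.loc["g1", "t"]) < 0.1
        assert res.loc["g1", "p"] > 0.9

    def test_sign_symmetry(self):
        d = np.array([[0.5, 1.5, 0.7, 1.1]])
        ma, sheet = paired_matrix_from_deltas(d)
        mb, _ = paired_matrix_from_deltas(-d)
        ra, rb = paired_t_test(ma, sheet), paired_t_test(mb, sheet)
        assert ra.loc["g1", "t"] == pytest.approx(-rb.loc["g1", "t"])
        assert ra.loc["g1", "p"] == pytest.approx(rb.loc["g1", "p"])

    def test_zero_variance_flagged_missing(self):
        m, sheet = paired_matrix_from_deltas([[1.0, 1.0, 1.0]])
        res = paired_t_test(m, sheet)
        assert res.loc["g1", "zero_variance"]
        assert np.isnan(res.loc["g1", "p"])

    def test_fewer_than_two_pairs_rejected(self):
        m, sheet = paired_matrix_from_deltas([[1.0]])
        with pytest.raises(DesignError):
            paired_t_test(m, sheet)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 10), st.integers(1, 8))
    def test_matches_scipy_ttest_rel(self, seed, n_pairs, n_genes):
        """Independent route: scipy.stats.ttest_rel on the same pairs."""
        rng = np.random.default_rng(seed)
        deltas = rng.normal(0, 1, size=(n_genes, n_pairs))
        m, sheet = paired_matrix_from_deltas(deltas)
        res = paired_t_test(m, sheet)
        tumors = m.data[[f"P{j+1:02d}_T" for j in range(n_pairs)]].to_numpy()
        normals = m.data[[f"P{j+1:02d}_N" for j in range(n_pairs)]].to_numpy()
        ref = stats.ttest_rel(tumors, normals, axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, rtol=1e-10)


class TestBhFdr:
    def test_worked_example(self):
        q, sig = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], alpha=0.05)
        np.testing.assert_allclose(q, [0.005, 0.025, 1 / 30, 0.05, 0.2], rtol=1e-12)
        assert sig.tolist() == [True, True, True, True, False]

    def test_degenerate_inputs(self):
        q, sig = bh_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not sig.any()
        q, sig = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03) and sig[0]

    def test_ties_get_equal_q(self):
        q, _ = bh_fdr([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_nan_propagates_without_affecting_m(self):
        q, sig = bh_fdr([0.01, np.nan, 0.04], alpha=0.05)
        assert np.isnan(q[1]) and not sig[1]
        np.testing.assert_allclose([q[0], q[2]], [0.02, 0.04])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 50))
    def test_agrees_with_brute_force(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=m)
        q, sig = bh_fdr(p)
        q_ref, sig_ref = brute_force_bh(p)
        np.testing.assert_allclose(q, q_ref, rtol=1e-12)
        assert (sig == sig_ref).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 40))
            q, sig = bh_fdr(p)
            ref_sig, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, ref_q, rtol=1e-10)
            assert (sig == ref_sig).all()


class TestDeriveSignature:
    def test_noise_free_planted_recovery_exact(self):
        """10 planted 4-fold genes among 500 nulls, noise-free: exactly the
        planted probes come out significant."""
        rng = np.random.default_rng(3)
        n_genes, n_pairs = 510, 6
        deltas = np.zeros((n_genes, n_pairs))
        deltas[:10, :] = 2.0  # 4-fold
        m, sheet = paired_matrix_from_deltas(deltas, baseline=10.0, scale="linear")
        table = derive_signature(m, sheet, min_intensity=50.0)
        called = set(table.index[table["significant"]])
        assert called == {f"g{i+1}" for i in range(10)}

    def test_myb_top_by_fold_change(self, ):
        """MYB planted at 18-fold with everything else <= 8-fold is the top
        up-regulated row by fold change."""
        c = generate_cohort(SimConfig(seed=4, n_genes=800, fc_range=(2.0, 8.0),
                                      myb_fc=18.0, noise_sd=0.3,
                                      n_mirna=80, n_mirna_down=4, n_mirna_up=2))
        table = derive_signature(c.mrna, c.sheet)
        up = table[table["significant"] & (table["direction"] == "up")]
        assert up["fold_change"].idxmax() == "MYB"

    def test_sorted_by_q_then_fold(self, small_cohort):
        table = derive_signature(small_cohort.mrna, small_cohort.sheet)
        tested = table[table["tested"]]
        q = tested["q"].to_numpy()
        assert (np.diff(q) >= -1e-15).all()
        # within equal q, |log2 fc| is non-increasing
        for _, grp in tested.groupby("q", sort=False):
            fc = grp["log2_fc"].abs().to_numpy()
            assert (np.diff(fc) <= 1e-12).all()

    def test_filter_flags_consistent(self, small_cohort):
        table = derive_signature(small_cohort.mrna, small_cohort.sheet)
        assert (table["tested"] == (table["passed_baseline"]
                                    & table["passed_variation"])).all()
        assert not table.loc[~table["tested"], "significant"].any()

    def test_descriptive_mode_single_pair(self):
        deltas = np.array([[2.0], [0.1]])
        m, sheet = paired_matrix_from_deltas(deltas, scale="linear")
        table = derive_signature(m, sheet, min_intensity=1.0)
        assert table.attrs["mode"] == "descriptive_fc"
        assert table.loc["g1", "significant"]
        assert not table.loc["g2", "significant"]


class TestGroupComparison:
    def _matrix(self, rng, shift_probe=None, shift=0.0, n_per_group=6):
        sheet = make_paired_sheet(2 * n_per_group)
        tumors = sheet.tumor_samples()
        grouping = {t: ("positive" if i < n_per_group else "negative")
                    for i, t in enumerate(tumors)}
        values = rng.normal(8, 0.2, size=(30, len(sheet.sample_ids)))
        m = make_matrix(values, probes=[f"g{i}" for i in range(30)],
                        samples=sheet.sample_ids, scale="log2")
        if shift_probe is not None:
            cols = [m.sample_ids.index(t) for t, g in grouping.items()
                    if g == "positive"]
            m.data.iloc[shift_probe, cols] += shift
        return m, sheet, grouping

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(0)
        m, sheet, grouping = self._matrix(rng)
        res = group_comparison(m, sheet, grouping)
        assert not res["significant"].any()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        m, sheet, grouping = self._matrix(rng, shift_probe=3, shift=4.0)
        res = group_comparison(m, sheet, grouping)
        assert res.iloc[3]["significant"]
        assert not res.drop(res.index[3])["significant"].any()

    def test_equal_means_give_small_f(self):
        sheet = make_paired_sheet(4)
        m = make_matrix(np.array([[1.0, 0.0, 2.0, 0.0, 1.0, 0.0, 2.0, 0.0]]),
                        samples=sheet.sample_ids)
        grouping = dict(zip(sheet.tumor_samples(), ["a", "a", "b", "b"]))
        res = group_comparison(m, sheet, grouping)
        assert res.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        sheet = make_paired_sheet(3)
        m = make_matrix(np.zeros((2, 6)), samples=sheet.sample_ids)
        grouping = dict(zip(sheet.tumor_samples(), ["a", "a", "b"]))
        with pytest.raises(DesignError):
            group_comparison(m, sheet, grouping)


class TestClustering:
    def test_two_cluster_cut_recovers_tissue(self, noise_free_cohort):
        c = noise_free_cohort
        from accsig import log2_transform
        table = derive_signature(c.mrna, c.sheet)
        probes = list(table.index[table["significant"]])
        result = hierarchical_cluster(log2_transform(c.mrna), probes)
        labels = result.cut(2)
        tumors = {labels[s] for s in c.sheet.tumor_samples()}
        normals = {labels[s] for s in c.sheet.normal_samples()}
        assert len(tumors) == 1 and len(normals) == 1 and tumors != normals

    def test_duplicate_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 10)
        vals = np.column_stack([col, col, col + 5, col - 5])
        m = make_matrix(vals, samples=["a1", "a2", "b", "c"])
        res = hierarchical_cluster(m, m.probe_ids)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {res.sample_ids[int(res.linkage[0, 0])],
                 res.sample_ids[int(res.linkage[0, 1])]}
        assert first == {"a1", "a2"}

    def test_column_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(12, 5))
        m = make_matrix(vals, samples=list("edcba"))
        perm = make_matrix(vals[:, ::-1], samples=list("abcde"))
        r1 = hierarchical_cluster(m, m.probe_ids)
        r2 = hierarchical_cluster(perm, perm.probe_ids)
        np.testing.assert_allclose(r1.linkage, r2.linkage)
        assert r1.leaf_order == r2.leaf_order

    def test_disjoint_probe_subset_rejected(self):
        m = make_matrix(np.zeros((3, 3)))
        with pytest.raises(InputError):
            hierarchical_cluster(m, ["nope"])

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(6, 4)))
        nwk = hierarchical_cluster(m, m.probe_ids).to_newick()
        assert nwk.endswith(";")
        for s in m.sample_ids:
            assert s in nwk


class TestPca:
    def test_identical_samples_identical_scores(self):
        col = np.array([1.0, 3.0, 2.0])
        other = np.array([5.0, 0.0, 1.0])
        m = make_matrix(np.column_stack([col, col, other]))
        res = pca(m)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[1],
                                   atol=1e-10)

    def test_variance_fractions_sorted_and_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(20, 6)))
        res = pca(m)
        f = res.variance_fractions
        assert (np.diff(f) <= 1e-12).all()
        assert f.sum() == pytest.approx(1.0)

    def test_pc1_separates_tissue_on_planted_cohort(self, small_cohort):
        from accsig import log2_transform
        res = pca(log2_transform(small_cohort.mrna))
        pc1 = res.scores["PC1"]
        tumors = pc1[small_cohort.sheet.tumor_samples()]
        normals = pc1[small_cohort.sheet.normal_samples()]
        assert tumors.min() > normals.max() or tumors.max() < normals.min()

    def test_constant_matrix_all_zero(self):
        m = make_matrix(np.full((4, 3), 2.0))
        res = pca(m)
        assert np.allclose(res.scores.to_numpy(), 0.0)
        assert np.allclose(res.variance_fractions, 0.0)

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(10, 5)))
        res = pca(m)
        for c in res.loadings.columns:
            load = res.loadings[c].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0
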