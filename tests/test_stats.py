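"""Profile statistics: rmANCOVA, permutation clusters, correlations, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tractprof as tp
from tractprof import simulate as sim


def small_cohort(**kwargs):
    defaults = dict(seed=0)
    defaults.update(kwargs)
    return sim.make_profile_cohort(sim.CohortSpec(**defaults))


class TestRmAncova:
    def test_group_label_symmetry(self):
        """Swapping the two group labels leaves every F unchanged."""
        ds = small_cohort(effect_nodes=(20, 45), effect_size=0.05, seed=1)
        res_a = tp.rm_ancova(ds)
        swapped = ds.covariates.copy()
        swapped["group"] = 3 - swapped["group"]
        ds_b = tp.ProfileDataset(ds.fa, swapped, ds.behavior)
        res_b = tp.rm_ancova(ds_b)
        for a, b in zip(res_a, res_b):
            assert a.F == pytest.approx(b.F, rel=1e-10)

    def test_planted_group_effect_detected(self):
        ds = small_cohort(effect_nodes=(20, 45), effect_size=0.08, noise_sd=0.02, seed=2)
        res = {r.term: r for r in tp.rm_ancova(ds)}
        assert res["Nodes:Group"].p < tp.bonferroni_threshold(0.05, 16)
        assert 0 < res["Nodes:Group"].eta_p2 <= 1

    def test_singular_design_names_column(self):
        ds = small_cohort()
        cov = ds.covariates.copy()
        cov["protocol"] = 1  # constant
        with pytest.raises(ValueError, match="[Pp]rotocol"):
            tp.rm_ancova(tp.ProfileDataset(ds.fa, cov, ds.behavior))

    def test_type_one_error_calibrated_under_sphericity(self):
        """Null cohorts with white node noise: Nodes x Group rejects at
        ~alpha (sphericity-assumed F is exact under sphericity)."""
        hits = 0
        n_sim = 1000
        for i in range(n_sim):
            ds = small_cohort(n_nodes=20, smoothness=0.0, seed=50_000 + i)
            p = next(r.p for r in tp.rm_ancova(ds) if r.term == "Nodes:Group")
            hits += p < 0.05
        assert abs(hits / n_sim - 0.05) < 0.02

    def test_between_terms_reported(self):
        res = {r.term: r for r in tp.rm_ancova(small_cohort())}
        for term in ("Group", "Age", "Protocol", "Group:Age", "Group:Protocol"):
            assert res[term].df1 == 1
            assert res[term].df2 == 28 - 6


class TestSummaryAnova:
    def test_equal_means_give_zero_f(self):
        F, eta = tp.two_group_anova_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert F == 0.0 and eta == 0.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            tp.two_group_anova_from_summary(5.0, 0.0, 10, 6.0, 0.0, 12)

    def test_matches_pooled_t_squared_on_raw_data(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 13), rng.normal(0.8, 1.2, 15)
        F, _ = tp.two_group_anova_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        t, _ = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)


class TestNodewiseTTest:
    def test_identical_groups_give_zero_t(self):
        fa = np.tile(np.linspace(0.3, 0.6, 100), (28, 1))
        cov = pd.DataFrame(
            {"group": [1] * 13 + [2] * 15, "age": np.arange(28), "protocol": [1, 2] * 14}
        )
        t, _ = tp.nodewise_ttest(tp.ProfileDataset(fa, cov))
        assert np.allclose(t, 0.0)

    def test_matches_scipy_formula_oracle(self):
        ds = small_cohort(seed=3)
        t_mine, p_mine = tp.nodewise_ttest(ds)
        g1 = ds.group_indicator
        t_ref, p_ref = sps.ttest_ind(ds.fa[g1], ds.fa[~g1])
        assert np.abs(t_mine - t_ref).max() < 1e-10
        assert np.abs(p_mine - p_ref).max() < 1e-10

    def test_planted_difference_sign(self):
        ds = small_cohort(effect_nodes=(40, 50), effect_size=0.1, noise_sd=0.005, seed=4)
        t, _ = tp.nodewise_ttest(ds)
        # group 2 (dyslexic side) has the higher FA: t = group1 - group2 < 0
        assert np.all(t[39:50] < -5)


class TestPermutationClusters:
    def test_equal_groups_produce_no_clusters(self):
        fa = np.tile(np.linspace(0.3, 0.6, 100), (28, 1))
        cov = pd.DataFrame(
            {"group": [1] * 13 + [2] * 15, "age": np.arange(28), "protocol": [1, 2] * 14}
        )
        ds = tp.ProfileDataset(fa, cov)
        assert tp.permutation_cluster_test(ds, n_perm=200, seed=0) == []

    def test_planted_cluster_recovered(self):
        ds = small_cohort(effect_nodes=(20, 45), effect_size=0.06, noise_sd=0.03, seed=5)
        clusters = tp.permutation_cluster_test(ds, n_perm=2000, seed=1)
        sig = [c for c in clusters if c.significant and c.direction == -1]
        assert len(sig) == 1
        assert sig[0].start <= 22 and sig[0].end >= 43

    def test_invariant_to_constant_shift(self):
        ds = small_cohort(seed=6)
        a = tp.permutation_cluster_test(ds, n_perm=500, seed=2)
        ds2 = tp.ProfileDataset(ds.fa + 0.05, ds.covariates, ds.behavior)
        b = tp.permutation_cluster_test(ds2, n_perm=500, seed=2)
        assert [(c.direction, c.start, c.end, c.p) for c in a] == [
            (c.direction, c.start, c.end, c.p) for c in b
        ]

    def test_tiny_cohort_enumerates_exactly(self):
        rng = np.random.default_rng(7)
        fa = np.clip(rng.normal(0.5, 0.05, (6, 20)), 0, 1)
        cov = pd.DataFrame({"group": [1, 1, 1, 2, 2, 2], "age": np.arange(6), "protocol": [1, 2] * 3})
        ds = tp.ProfileDataset(fa, cov)
        with pytest.warns(UserWarning, match="enumerating"):
            tp.permutation_cluster_test(ds, n_perm=1000, seed=3)

    def test_node_pvalues_uniform_under_null(self):
        """KS test: node-wise t p-values are U(0,1) over null cohorts.

        Uses the pure-noise null (no age/protocol structure): the unpaired t
        is exactly calibrated only under iid normal node values."""
        pvals = []
        for i in range(1000):
            ds = small_cohort(n_nodes=5, smoothness=0.0, age_slope=0.0,
                              protocol_offset=0.0, seed=90_000 + i)
            _, p = tp.nodewise_ttest(ds)
            pvals.append(p[2])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestCorrelations:
    def test_duplicated_node_gives_unit_correlation(self):
        ds = small_cohort(seed=8)
        corr = tp.nodewise_correlation(ds, ds.fa[:, 29].copy(), covariates=())
        assert corr["r"][29] == pytest.approx(1.0, abs=1e-12)

    def test_partial_matches_inverse_correlation_identity(self):
        """Partial r equals -P_xy / sqrt(P_xx P_yy) with P the inverse of the
        correlation matrix of (x, y, covariates)."""
        ds = small_cohort(seed=9)
        covs = ("age", "group", "digit_span")
        corr = tp.nodewise_correlation(ds, "word_reading_accuracy", covariates=covs)
        m = ds.behavior["word_reading_accuracy"].to_numpy()
        Z = ds.covariates[list(covs)].to_numpy(dtype=float)
        for node in (0, 30, 77):
            R = np.corrcoef(np.column_stack([ds.fa[:, node], m, Z]).T)
            P = np.linalg.inv(R)
            expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
            assert corr["r"][node] == pytest.approx(expected, abs=1e-10)

    def test_partial_matches_pingouin(self):
        """Independent cross-check against pingouin.partial_corr."""
        pg = pytest.importorskip("pingouin")
        ds = small_cohort(seed=13)
        covs = ("age", "group", "digit_span")
        corr = tp.nodewise_correlation(ds, "ran_rt", covariates=covs)
        frame = pd.DataFrame(
            {
                "fa": ds.fa[:, 42],
                "m": ds.behavior["ran_rt"].to_numpy(),
                "age": ds.covariates["age"].to_numpy(),
                "group": ds.covariates["group"].to_numpy(),
                "dspan": ds.covariates["digit_span"].to_numpy(),
            }
        )
        ref = pg.partial_corr(frame, x="fa", y="m", covar=["age", "group", "dspan"])
        assert corr["r"][42] == pytest.approx(ref["r"].iloc[0], abs=1e-10)
        assert corr["p"][42] == pytest.approx(ref["p_val"].iloc[0], abs=1e-10)

    def test_noisy_copy_recovered_at_right_node(self):
        """Measure = node-30 FA + noise: r peaks at node 30 vs far nodes."""
        wins = 0
        for i in range(100):
            ds = small_cohort(seed=10_000 + i)
            rng = np.random.default_rng(777 + i)
            measure = ds.fa[:, 29] + rng.normal(0, ds.fa[:, 29].std(), ds.n_subjects)
            corr = tp.nodewise_correlation(ds, measure, covariates=("age",))
            r = corr["r"].to_numpy()
            far = np.abs(np.arange(100) - 29) > 10
            if r[29] > r[far].max():
                wins += 1
        assert wins >= 95

    def test_constant_measure_rejected(self):
        ds = small_cohort(seed=11)
        with pytest.raises(ValueError, match="constant"):
            tp.nodewise_correlation(ds, np.full(ds.n_subjects, 3.0))


class TestFdr:
    def test_single_p_unchanged(self):
        assert tp.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        adj = tp.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            adj = tp.bh_fdr(p)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1)

    def test_empty_input(self):
        assert len(tp.bh_fdr([])) == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            tp.bh_fdr([0.5, 1.2])


class TestCorrelationClusters:
    def test_no_significant_nodes(self):
        r = np.zeros(100)
        p = np.ones(100)
        assert tp.summarize_correlation_clusters(r, p) == []

    def test_two_clusters_from_disjoint_runs(self):
        p = np.ones(100)
        p[9:15] = 0.01  # nodes 10..15
        p[39] = 0.01    # node 40
        r = np.linspace(0, 1, 100)
        clusters = tp.summarize_correlation_clusters(r, p)
        assert [(c.start, c.end) for c in clusters] == [(10, 15), (40, 40)]

    def test_r_avg_is_arithmetic_mean(self):
        r = np.zeros(20)
        r[9:15] = [0.5, 0.6, 0.7, 0.7, 0.6, 0.5]
        p = np.ones(20)
        p[9:15] = 0.01
        clusters = tp.summarize_correlation_clusters(r, p)
        assert clusters[0].r_avg == pytest.approx(0.6)


def test_profile_dataset_validation():
    cov = pd.DataFrame({"group": [1, 1, 2, 2], "age": [1, 2, 3, 4], "protocol": [1, 2, 1, 2]})
    fa = np.full((4, 10), 0.5)
    tp.ProfileDataset(fa, cov)  # valid
    with pytest.raises(ValueError, match="missing"):
        bad = fa.copy()
        bad[0, 0] = np.nan
        tp.ProfileDataset(bad, cov)
    with pytest.raises(ValueError, match="at least 4"):
        tp.ProfileDataset(fa[:3], cov.iloc[:3])
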