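"""Wilcoxon signed-rank machinery, cluster formation, and the sign-flip
permutation engine, checked against brute-force enumeration and scipy."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pupiltrace.data_model import Cluster
from pupiltrace.stats import (
    PairedCurves,
    PermConfig,
    behavioral_paired_test,
    cluster_significance,
    form_clusters,
    permutation_null,
    pointwise_test,
    positive_rank_sum,
    run_cluster_test,
    wilcoxon_signed_rank,
)


def brute_force_two_sided_p(d):
    """Enumerate all 2^n sign assignments of |d| (independent oracle)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        ranks[np.array(signs) > 0].sum()
        for signs in itertools.product([True, False], repeat=len(d))
    ])
    return min(1.0, 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxon:
    def test_all_positive_eight_gives_exact_p(self):
        z, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6, 7, 8])
        assert p == pytest.approx(2 / 2**8)
        assert z > 0

    def test_antisymmetric_differences_give_zero_z(self):
        z, p = wilcoxon_signed_rank([1, -1, 2, -2, 3, -3], method="approx")
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_rank_sum_and_z(self):
        # diffs {1..5, -6}: W+ = 15, mean = 10.5, var = 22.75
        z, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, -6], method="approx")
        assert z == pytest.approx((15 - 10.5) / np.sqrt(22.75))
        ze, pe = wilcoxon_signed_rank([1, 2, 3, 4, 5, -6], method="exact")
        assert pe == pytest.approx(brute_force_two_sided_p([1, 2, 3, 4, 5, -6]))

    def test_all_zero_differences_untestable(self):
        z, p = wilcoxon_signed_rank([0.0] * 10)
        assert (z, p) == (0.0, 1.0)

    def test_below_five_nonzero_untestable(self):
        assert wilcoxon_signed_rank([1.0, -2.0, 3.0, 4.0]) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.standard_normal(n)
        _, p = wilcoxon_signed_rank(d, method="exact")
        assert p == pytest.approx(brute_force_two_sided_p(d), abs=1e-12)

    @pytest.mark.parametrize("n", [12, 15, 20, 25])
    def test_exact_and_normal_paths_agree_closely(self, n):
        # the normal approximation tracks the exact law tightly where the
        # decision happens (small p); mid-distribution the lattice spacing of
        # the discrete W statistic caps agreement near its pmf (~0.04 at n=12)
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = rng.standard_normal(n)
            _, p_exact = wilcoxon_signed_rank(d, method="exact")
            _, p_norm = wilcoxon_signed_rank(d, method="approx")
            assert abs(p_exact - p_norm) <= 0.05
            if p_exact < 0.1:
                assert abs(p_exact - p_norm) <= 0.01

    @pytest.mark.parametrize("n", [8, 15, 40])
    def test_agrees_with_scipy_on_both_paths(self, n):
        rng = np.random.default_rng(100 + n)
        d = rng.standard_normal(n)
        _, p = wilcoxon_signed_rank(d, method="approx")
        assert p == pytest.approx(
            sps.wilcoxon(d, correction=False, method="approx").pvalue)
        _, pe = wilcoxon_signed_rank(d, method="exact")
        assert pe == pytest.approx(sps.wilcoxon(d, method="exact").pvalue)

    def test_midranks_and_tie_correction_with_ties(self):
        d = [1.0, 1.0, -1.0, 2.0, 3.0, 3.0, -2.0, 4.0]
        _, p = wilcoxon_signed_rank(d, method="approx")
        assert p == pytest.approx(
            sps.wilcoxon(d, correction=False, method="approx").pvalue)

    def test_positive_rank_sum_convention(self):
        assert positive_rank_sum([1, 2, 3, 4, 5, -6]) == 15.0


def curves_from_diffs(diffs):
    """PairedCurves whose a-b difference matrix equals `diffs`."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, m = diffs.shape
    return PairedCurves(
        participant_ids=[f"s{i}" for i in range(n)],
        curves_a=diffs, curves_b=np.zeros_like(diffs),
        label_a="a", label_b="b", alignment=None,
    )


class TestPointwise:
    def test_identical_curves_give_zero_z(self):
        pc = curves_from_diffs(np.zeros((10, 50)))
        z, p = pointwise_test(pc)
        assert np.all(z == 0.0)
        assert np.all(p == 1.0)

    def test_constant_offset_reduces_to_all_positive_case(self, rng):
        n = 12
        pc = curves_from_diffs(np.full((n, 30), 0.2))
        z, p = pointwise_test(pc)
        z1, p1 = wilcoxon_signed_rank(np.full(n, 0.2), method="approx")
        np.testing.assert_allclose(z, z1)
        np.testing.assert_allclose(p, p1)

    def test_single_point_difference(self, rng):
        diffs = np.zeros((10, 40))
        diffs[:, 17] = rng.uniform(0.1, 0.2, 10)
        z, _ = pointwise_test(curves_from_diffs(diffs))
        assert np.flatnonzero(np.abs(z) > 0).tolist() == [17]

    def test_heavily_missing_point_is_untestable(self, rng):
        diffs = rng.standard_normal((10, 20)) + 5.0
        diffs[0:2, 7] = np.nan  # 20% missing > 10% limit
        z, p = pointwise_test(curves_from_diffs(diffs))
        assert z[7] == 0.0 and p[7] == 1.0
        assert np.all(np.abs(z[np.arange(20) != 7]) > 0)

    def test_stimulus_alignment_restricts_to_post_onset_window(self, rng):
        n_pts = 400
        curves = rng.standard_normal((12, n_pts)) * 0.01
        pc = PairedCurves(participant_ids=[f"s{i}" for i in range(12)],
                          curves_a=curves + 0.5, curves_b=curves,
                          label_a="a", label_b="b", alignment="stimulus",
                          grid_start_s=-3.0, rate_hz=50.0)
        z, p = pointwise_test(pc)
        assert len(z) == 250  # the 5 s after onset at 50 Hz


class TestClusters:
    def test_no_significant_points_gives_empty_list(self):
        z = np.zeros(100)
        p = np.ones(100)
        assert form_clusters(z, p, 0.05) == []

    def test_single_run_mass_is_summed_z(self):
        z = np.zeros(50)
        p = np.ones(50)
        z[10:20] = 3.0
        p[10:20] = 0.001
        clusters = form_clusters(z, p, 0.05)
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.sign) == (10, 20, 1)
        assert c.mass == pytest.approx(30.0)

    def test_sign_break_splits_adjacent_runs(self):
        z = np.zeros(30)
        p = np.ones(30)
        z[5:10], p[5:10] = 2.5, 0.01
        z[10:15], p[10:15] = -2.5, 0.01
        clusters = form_clusters(z, p, 0.05)
        assert len(clusters) == 2
        assert clusters[0].sign == 1 and clusters[1].sign == -1


class TestPermutationNull:
    def test_identical_curves_give_all_zero_null(self):
        pc = curves_from_diffs(np.zeros((10, 50)))
        null = permutation_null(pc, PermConfig(n_permutations=100, seed=3))
        assert np.all(null == 0.0)

    def test_fixed_seed_reproduces_null_bit_identically(self, rng):
        pc = curves_from_diffs(rng.standard_normal((15, 60)))
        cfg = PermConfig(n_permutations=200, seed=11)
        null1 = permutation_null(pc, cfg)
        null2 = permutation_null(pc, cfg)
        np.testing.assert_array_equal(null1, null2)

    def test_null_matches_exhaustive_sign_flip_enumeration(self):
        # 6 participants, one timepoint: the sampled null-mass frequencies
        # must match exhaustive enumeration of all 2^6 flip patterns.
        d = np.array([[0.3], [0.25], [0.2], [0.15], [0.35], [0.27]])
        pc = curves_from_diffs(d)
        exhaustive = []
        for signs in itertools.product([1, -1], repeat=6):
            z, p = wilcoxon_signed_rank(np.array(signs) * d[:, 0], method="approx")
            exhaustive.append(abs(z) if p < 0.05 else 0.0)
        exhaustive = np.round(exhaustive, 10)
        null = np.round(permutation_null(pc, PermConfig(n_permutations=4000, seed=5)), 10)
        assert set(null) <= set(exhaustive)
        for value in np.unique(exhaustive):
            expected = np.mean(exhaustive == value)
            observed = np.mean(null == value)
            se = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(observed - expected) < 4 * se + 1e-12

    def test_global_label_swap_negates_z_and_masses_keeps_null(self, rng):
        diffs = rng.standard_normal((20, 80)) + 0.4
        pc = curves_from_diffs(diffs)
        cfg = PermConfig(n_permutations=150, seed=9)
        res = run_cluster_test(pc, cfg)
        res_swapped = run_cluster_test(pc.swapped(), cfg)
        np.testing.assert_allclose(res_swapped.z_series, -res.z_series, atol=1e-12)
        assert len(res.clusters) == len(res_swapped.clusters)
        for c, cs in zip(res.clusters, res_swapped.clusters):
            assert cs.mass == pytest.approx(-c.mass)
            assert cs.sign == -c.sign
        np.testing.assert_array_equal(res.null_masses, res_swapped.null_masses)

    def test_effect_monotonicity_under_fixed_noise(self, rng):
        noise = rng.standard_normal((15, 100)) * 0.3
        prev = -np.inf
        for effect in (0.0, 0.1, 0.2, 0.4):
            diffs = noise.copy()
            diffs[:, 40:70] += effect
            res = run_cluster_test(curves_from_diffs(diffs),
                                   PermConfig(n_permutations=50, seed=2))
            biggest = max((abs(c.mass) for c in res.clusters), default=0.0)
            assert biggest >= prev
            prev = biggest


class TestClusterSignificance:
    def test_mass_above_all_null_gets_smallest_p(self):
        null = np.linspace(0, 10, 500)
        c = Cluster(start=0, end=5, sign=1, mass=50.0)
        out = cluster_significance([c], null, 0.05)[0]
        assert out.p_perm == pytest.approx(1 / 501)
        assert out.significant

    def test_zero_mass_never_significant(self):
        null = np.linspace(0, 10, 500)
        c = Cluster(start=0, end=1, sign=1, mass=0.0)
        out = cluster_significance([c], null, 0.05)[0]
        assert not out.significant
        assert out.p_perm == 1.0

    def test_mass_equal_to_95th_percentile_not_significant(self):
        null = np.arange(1.0, 101.0)  # 95th percentile (linear) = 95.05
        q95 = np.quantile(null, 0.95)
        c = Cluster(start=0, end=2, sign=1, mass=float(q95))
        out = cluster_significance([c], null, 0.05)[0]
        assert not out.significant

    def test_p_perm_invariant_to_permutation_order(self, rng):
        null = rng.uniform(0, 5, 300)
        c = Cluster(start=0, end=3, sign=-1, mass=-2.5)
        p1 = cluster_significance([c], null, 0.05)[0].p_perm
        p2 = cluster_significance([c], rng.permutation(null), 0.05)[0].p_perm
        assert p1 == p2


class TestRunClusterTest:
    def test_identical_conditions_give_no_significant_cluster(self, rng):
        curves = rng.standard_normal((12, 100)) * 0.1
        pc = PairedCurves(participant_ids=[f"s{i}" for i in range(12)],
                          curves_a=curves.copy(), curves_b=curves.copy(),
                          label_a="a", label_b="b", alignment=None)
        res = run_cluster_test(pc, PermConfig(n_permutations=100, seed=4))
        assert res.significant_clusters == []

    def test_cluster_window_reported_in_ms(self, rng):
        diffs = rng.standard_normal((20, 400)) * 0.05
        diffs[:, 250:350] += 0.5  # 2..4 s post-onset at 50 Hz
        pc = PairedCurves(participant_ids=[f"s{i}" for i in range(20)],
                          curves_a=diffs, curves_b=np.zeros_like(diffs),
                          label_a="a", label_b="b", alignment="stimulus",
                          grid_start_s=-3.0, rate_hz=50.0)
        res = run_cluster_test(pc, PermConfig(n_permutations=200, seed=8))
        sig = res.significant_clusters
        assert sig, "expected the injected difference to be detected"
        c = max(sig, key=lambda c: abs(c.mass))
        assert c.sign == 1
        assert c.start_ms == pytest.approx(2000.0, abs=200)
        assert c.end_ms == pytest.approx(4000.0, abs=200)


class TestBehavioral:
    def test_normal_differences_select_t_test(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.1, 40)
        y = x - rng.normal(0.1, 0.05, 40)
        assert sps.shapiro(x - y).pvalue > 0.05  # oracle for the branch
        rep = behavioral_paired_test(x, y)
        assert rep.test_name == "paired_t"
        t = sps.ttest_rel(x, y)
        assert rep.statistic == pytest.approx(t.statistic)
        assert rep.p_value == pytest.approx(t.pvalue)

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 40)
        y = np.zeros(40)
        assert sps.shapiro(x - y).pvalue <= 0.05
        rep = behavioral_paired_test(x, y)
        assert rep.test_name == "wilcoxon"
        assert rep.statistic == positive_rank_sum(x - y)

    def test_constant_differences_are_degenerate(self):
        x = np.arange(10.0)
        rep = behavioral_paired_test(x + 1.0, x)
        assert rep.test_name == "degenerate"
        assert rep.mean_diff == pytest.approx(1.0)
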