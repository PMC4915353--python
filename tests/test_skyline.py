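"""UPGMA trees, coalescent intervals, skyline estimators, Kingman oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msprime

from demoskew.sampling import DistanceMatrix
from demoskew.skyline import (
    CoalescentIntervals,
    aic_select_epsilon,
    classic_skyline,
    coalescent_intervals,
    default_epsilon_grid,
    generalized_skyline,
    is_ultrametric,
    read_newick,
    simulate_kingman_tree,
    skyline_amplitude,
    tree_depth,
    upgma_tree,
    write_newick,
)


def _dm(labels, d):
    return DistanceMatrix(labels=list(labels), d=np.array(d, dtype=float))


class TestUPGMA:
    def test_two_taxa_half_distance(self):
        tree = upgma_tree(_dm("AB", [[0, 3], [3, 0]]))
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert depths == pytest.approx([1.5, 1.5])

    def test_three_taxa_hand_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6: (A,B) joins at height 1, C at height 3
        tree = upgma_tree(_dm("ABC", [[0, 2, 6], [2, 0, 6], [6, 6, 0]]))
        iv = coalescent_intervals(tree)
        np.testing.assert_allclose(iv.durations, [1.0, 2.0])
        assert tree_depth(tree) == pytest.approx(3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ultrametric_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 9))
        pts = rng.random((m, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = upgma_tree(_dm([f"t{i}" for i in range(m)], d))
        assert is_ultrametric(tree)
        iv = coalescent_intervals(tree)
        assert iv.depth == pytest.approx(tree_depth(tree))

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(_dm("AB", [[0, -1], [-1, 0]]))


class TestCoalescentIntervals:
    def test_two_tip_tree(self):
        tree = read_newick("(A:2.5,B:2.5);")
        iv = coalescent_intervals(tree)
        np.testing.assert_array_equal(iv.k, [2])
        np.testing.assert_allclose(iv.durations, [2.5])

    def test_balanced_four_tip_tree(self):
        # merges at heights 1, 1.5, 4 -> intervals (4,1), (3,0.5), (2,2.5)
        tree = read_newick("((A:1,B:1):3,(C:1.5,D:1.5):2.5);")
        iv = coalescent_intervals(tree)
        np.testing.assert_array_equal(iv.k, [4, 3, 2])
        np.testing.assert_allclose(iv.durations, [1.0, 0.5, 2.5])

    def test_durations_sum_to_depth_on_simulated_trees(self, rng):
        for _ in range(20):
            tree = simulate_kingman_tree(8, 1.0, rng)
            iv = coalescent_intervals(tree)
            assert iv.depth == pytest.approx(tree_depth(tree))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            coalescent_intervals(read_newick("(A:1,B:1,C:1);"))

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError):
            coalescent_intervals(read_newick("(A:1,B:2);"))


class TestClassicSkyline:
    def test_two_lineage_estimate_is_duration(self):
        iv = CoalescentIntervals(k=[2], durations=[0.7])
        est = classic_skyline(iv)
        np.testing.assert_allclose(est.values, [0.7])

    def test_five_lineage_scaling(self):
        iv = CoalescentIntervals(k=[5, 4, 3, 2], durations=[0.2, 0, 0, 0])
        est = classic_skyline(iv)
        assert est.values[0] == pytest.approx(10 * 0.2)
        assert est.has_zero

    def test_unbiased_on_kingman_trees(self, rng):
        # per-interval classic estimates are Exponential(mean N); their
        # grand mean over 200 trees recovers the true scaled size
        vals = []
        for _ in range(200):
            iv = coalescent_intervals(simulate_kingman_tree(10, 0.01, rng))
            vals.extend(classic_skyline(iv).values)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.01) < 3 * se


class TestGeneralizedSkyline:
    def test_epsilon_zero_equals_classic(self, rng):
        iv = coalescent_intervals(simulate_kingman_tree(9, 1.0, rng))
        gen = generalized_skyline(iv, 0.0)
        cls = classic_skyline(iv)
        np.testing.assert_allclose(gen.values, cls.values)

    def test_epsilon_beyond_depth_single_segment(self):
        iv = CoalescentIntervals(k=[4, 3, 2], durations=[0.1, 0.2, 0.3])
        est = generalized_skyline(iv, 10.0)
        assert est.K == 1
        expected = (6 * 0.1 + 3 * 0.2 + 1 * 0.3) / 3
        assert est.values[0] == pytest.approx(expected)

    def test_hand_pooling_example(self):
        iv = CoalescentIntervals(k=[3, 2], durations=[0.1, 0.4])
        est = generalized_skyline(iv, 0.6)
        assert est.K == 1
        assert est.values[0] == pytest.approx(0.35)

    def test_recovers_constant_size_with_full_pooling(self, rng):
        # parameter recovery: epsilon -> infinity MLE over 200 trees
        est = np.array([
            generalized_skyline(
                coalescent_intervals(simulate_kingman_tree(12, 0.5, rng)),
                np.inf,
            ).values[0]
            for _ in range(200)
        ])
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < 3 * se


class TestAICSelection:
    def test_two_tip_tree_smallest_epsilon_wins_ties(self):
        iv = CoalescentIntervals(k=[2], durations=[1.0])
        eps, est = aic_select_epsilon(iv, [0.0, 0.5, 2.0])
        assert eps == 0.0
        assert est.K == 1

    def test_grid_of_zero_returns_classic(self, rng):
        iv = coalescent_intervals(simulate_kingman_tree(6, 1.0, rng))
        eps, est = aic_select_epsilon(iv, [0.0])
        assert eps == 0.0
        np.testing.assert_allclose(est.values, classic_skyline(iv).values)

    def test_pooling_favored_for_constant_size(self, rng):
        # under constant N the AIC-selected skyline should usually have
        # fewer segments than the classic skyline
        pooled = 0
        for _ in range(100):
            iv = coalescent_intervals(simulate_kingman_tree(10, 1.0, rng))
            _, est = aic_select_epsilon(iv, default_epsilon_grid(iv))
            pooled += est.K < 9
        assert pooled > 90

    def test_aic_never_above_classic_when_zero_in_grid(self, rng):
        from demoskew.skyline import _log_likelihood

        for _ in range(20):
            iv = coalescent_intervals(simulate_kingman_tree(8, 1.0, rng))
            _, est = aic_select_epsilon(iv)
            cls = classic_skyline(iv)
            aic_sel = 2 * est.K - 2 * _log_likelihood(est)
            aic_cls = 2 * cls.K - 2 * _log_likelihood(cls)
            assert aic_sel <= aic_cls + 1e-9


class TestAmplitude:
    def test_constant_skyline_is_one(self):
        iv = CoalescentIntervals(k=[2], durations=[1.0])
        assert skyline_amplitude(classic_skyline(iv)) == 1.0

    def test_ratio_and_scale_invariance(self):
        from demoskew.skyline import SkylineEstimate

        est = SkylineEstimate(boundaries=[0, 1, 2], values=[2.0, 8.0],
                              epsilon=0.0)
        assert skyline_amplitude(est) == pytest.approx(4.0)
        scaled = SkylineEstimate(boundaries=[0, 1, 2], values=[14.0, 56.0],
                                 epsilon=0.0)
        assert skyline_amplitude(scaled) == pytest.approx(4.0)

    def test_zero_minimum_undefined(self):
        iv = CoalescentIntervals(k=[3, 2], durations=[0.0, 1.0])
        with pytest.raises(ValueError):
            skyline_amplitude(classic_skyline(iv))


class TestKingmanSimulator:
    def test_pair_depth_mean(self, rng):
        depths = [tree_depth(simulate_kingman_tree(2, 2.0, rng))
                  for _ in range(4000)]
        depths = np.array(depths)
        se = depths.std(ddof=1) / np.sqrt(len(depths))
        assert abs(depths.mean() - 2.0) < 3 * se

    def test_tmrca_mean(self, rng):
        n, N = 10, 1.0
        depths = np.array([
            tree_depth(simulate_kingman_tree(n, N, rng)) for _ in range(3000)
        ])
        expected = 2 * N * (1 - 1 / n)
        se = depths.std(ddof=1) / np.sqrt(len(depths))
        assert abs(depths.mean() - expected) < 3 * se

    def test_binary_and_ultrametric(self, rng):
        tree = simulate_kingman_tree(15, 1.0, rng)
        assert is_ultrametric(tree)
        iv = coalescent_intervals(tree)  # validates binary shape
        assert iv.n == 15

    def test_full_pooling_matches_msprime_genealogies(self):
        # independent coalescent oracle: the fully pooled skyline estimate
        # on msprime trees recovers the msprime population size
        est = []
        for seed in range(1, 121):
            ts = msprime.sim_ancestry(samples=15, ploidy=1,
                                      population_size=100.0, random_seed=seed)
            tree = read_newick(ts.first().as_newick())
            iv = coalescent_intervals(tree)
            est.append(generalized_skyline(iv, np.inf).values[0])
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 100.0) < 3 * se


class TestNewickIO:
    def test_simple_round_trip(self, tmp_path):
        path = tmp_path / "t.nwk"
        tree = read_newick("(A:1,B:1);")
        write_newick(tree, path)
        again = read_newick(path)
        assert tree_depth(again) == pytest.approx(1.0, abs=1e-12)

    def test_large_random_tree_round_trip(self, rng, tmp_path):
        tree = simulate_kingman_tree(100, 0.37, rng)
        iv = coalescent_intervals(tree)
        path = tmp_path / "big.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        iv2 = coalescent_intervals(again)
        np.testing.assert_allclose(iv2.durations, iv.durations, atol=1e-12)
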