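"""Disparity, net evolutionary rates, rate comparisons and the BM band."""

import numpy as np
import pytest

import morphomod as mm
from morphomod.phylo_comparative import Phylogeny
from morphomod.rates_disparity import (bm_prediction_band, compare_rates_groups,
                                       compare_rates_modules, landmark_evo_map,
                                       pairwise_disparity_tests,
                                       procrustes_variance, sigma2_mult)
from test_modularity import make_aligned


class TestProcrustesVariance:
    def test_identical_specimens_zero(self):
        coords = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        assert procrustes_variance(make_aligned(coords)) == 0.0

    def test_two_specimens_one_point(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0] = [3.0, 0, 0]   # squared distance 9
        pv = procrustes_variance(make_aligned(coords), per_landmark=True)
        # each specimen sits d/2 from the mean: sum = d^2/2, divisor n = 2
        assert pv == pytest.approx(9.0 / 4)

    def test_equals_trace_of_ml_covariance(self, rng):
        coords = rng.standard_normal((9, 6, 3))
        aligned = make_aligned(coords)
        pv = procrustes_variance(aligned, per_landmark=False)
        X = coords.reshape(9, -1)
        S_ml = np.cov(X, rowvar=False, ddof=0)
        assert pv == pytest.approx(float(np.trace(S_ml)), abs=1e-10)

    def test_empty_subset_errors(self, rng):
        aligned = make_aligned(rng.standard_normal((4, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            procrustes_variance(aligned, point_subset=[])


class TestSigma2Mult:
    def test_star_tree_reduces_to_identity_formula(self, rng):
        n, p = 12, 5
        tree = mm.star_tree(n)
        coords = rng.standard_normal((n, p, 3))
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        rate = sigma2_mult(tree, aligned)
        Y = coords.reshape(n, -1)
        R = Y - Y.mean(axis=0)
        oracle = float(np.sum(R ** 2)) / (n * p)
        assert rate == pytest.approx(oracle, abs=1e-12)

    def test_branch_doubling_halves_rate(self, rng):
        tree = mm.simulate_tree(10, seed=5)
        coords = rng.standard_normal((10, 4, 3))
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        r1 = sigma2_mult(tree, aligned)
        doubled = Phylogeny.from_newick(tree.as_newick())
        for e in doubled.tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2.0
        r2 = sigma2_mult(doubled, aligned)
        assert r2 == pytest.approx(r1 / 2, rel=1e-12)

    def test_additivity_over_point_subsets(self, rng):
        tree = mm.simulate_tree(9, seed=1)
        coords = rng.standard_normal((9, 7, 3))
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        A = [f"p{j}" for j in range(3)]
        B = [f"p{j}" for j in range(3, 7)]
        rA = sigma2_mult(tree, aligned, A)
        rB = sigma2_mult(tree, aligned, B)
        rAll = sigma2_mult(tree, aligned)
        assert rAll * 7 == pytest.approx(rA * 3 + rB * 4, rel=1e-12)


class TestRateComparisons:
    def test_identical_modules_ratio_one(self, rng):
        tree = mm.simulate_tree(8, seed=2)
        block = rng.standard_normal((8, 3, 3))
        coords = np.concatenate([block, block], axis=1)
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        res = compare_rates_modules(tree, aligned,
                                    {"a": ["p0", "p1", "p2"],
                                     "b": ["p3", "p4", "p5"]},
                                    n_sim=19, seed=0)
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_overlapping_groups_error(self, rng):
        tree = mm.simulate_tree(8, seed=3)
        aligned = make_aligned(rng.standard_normal((8, 3, 3)))
        aligned.specimen_ids = list(tree.tip_labels)
        tips = tree.tip_labels
        with pytest.raises(ValueError, match="overlap"):
            compare_rates_groups(tree, aligned,
                                 {"g1": tips[:4], "g2": tips[2:]}, n_sim=9)

    def test_tip_exclusion_supported(self, rng):
        tree = mm.simulate_tree(10, seed=4)
        tips = tree.tip_labels
        aligned = make_aligned(rng.standard_normal((10, 4, 3)))
        aligned.specimen_ids = list(tips)
        groups = {"g1": tips[:5], "g2": tips[5:]}
        full = compare_rates_groups(tree, aligned, groups, n_sim=19, seed=0)
        loo = compare_rates_groups(tree, aligned, groups, n_sim=19, seed=0,
                                   exclude_tips=[tips[0]])
        assert full.p_value != loo.p_value or full.ratio != loo.ratio

    def test_small_group_errors(self, rng):
        tree = mm.simulate_tree(6, seed=5)
        tips = tree.tip_labels
        aligned = make_aligned(rng.standard_normal((6, 3, 3)))
        aligned.specimen_ids = list(tips)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_rates_groups(tree, aligned, {"g1": tips[:1], "g2": tips[1:]},
                                 n_sim=9)


class TestPairwiseDisparity:
    def test_pair_count(self, rng):
        coords = rng.standard_normal((8, 20, 3))
        aligned = make_aligned(coords)
        modules = {f"m{k}": [f"p{j}" for j in range(2 * k, 2 * k + 2)]
                   for k in range(10)}
        res = pairwise_disparity_tests(aligned, modules, n_perm=9, seed=0)
        iu = np.triu_indices(10, 1)
        assert np.isfinite(res.p_values[iu]).sum() == 45

    def test_inflated_module_detected(self, rng):
        coords = rng.standard_normal((35, 18, 3)) * 0.01
        coords[:, :6, :] *= 20.0   # one module far more disparate
        aligned = make_aligned(coords)
        modules = {"hot": [f"p{j}" for j in range(6)],
                   "cold1": [f"p{j}" for j in range(6, 12)],
                   "cold2": [f"p{j}" for j in range(12, 18)]}
        res = pairwise_disparity_tests(aligned, modules, n_perm=199, seed=1)
        labels = res.modules
        hi = labels.index("hot")
        for j, m in enumerate(labels):
            if m != "hot":
                assert res.p_adjusted[hi, j] <= 0.05

    def test_difference_matrix_antisymmetric(self, rng):
        aligned = make_aligned(rng.standard_normal((6, 6, 3)))
        modules = {"a": ["p0", "p1", "p2"], "b": ["p3", "p4", "p5"]}
        res = pairwise_disparity_tests(aligned, modules, n_perm=9, seed=0)
        assert np.allclose(res.difference, -res.difference.T)

    def test_legacy_tukey_mode_runs(self, rng):
        aligned = make_aligned(rng.standard_normal((10, 9, 3)))
        modules = {"a": ["p0", "p1", "p2"], "b": ["p3", "p4", "p5"],
                   "c": ["p6", "p7", "p8"]}
        res = pairwise_disparity_tests(aligned, modules, method="tukey")
        assert res.method == "tukey"
        iu = np.triu_indices(3, 1)
        assert np.all((res.p_values[iu] >= 0) & (res.p_values[iu] <= 1))


class TestLandmarkEvoMap:
    def test_constant_point_zero_rate_and_variance(self, rng):
        tree = mm.simulate_tree(10, seed=6)
        coords = rng.standard_normal((10, 5, 3))
        coords[:, 2, :] = [1.0, 2.0, 3.0]
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        emap = landmark_evo_map(tree, aligned)
        assert emap.rate[2] == pytest.approx(0.0, abs=1e-12)
        assert emap.variance[2] == pytest.approx(0.0, abs=1e-12)

    def test_variance_decomposition_identity(self, rng):
        tree = mm.simulate_tree(12, seed=7)
        coords = rng.standard_normal((12, 8, 3))
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        emap = landmark_evo_map(tree, aligned)
        total = procrustes_variance(aligned, per_landmark=False)
        assert float(emap.variance.sum()) == pytest.approx(total, abs=1e-10)

    def test_band_flags_reproduce_under_seed(self, rng):
        tree = mm.simulate_tree(10, seed=8)
        coords = rng.standard_normal((10, 6, 3))
        aligned = make_aligned(coords)
        aligned.specimen_ids = list(tree.tip_labels)
        emap = landmark_evo_map(tree, aligned)
        b1 = bm_prediction_band(tree, emap, tree.tip_labels, n_sim=20, seed=9)
        b2 = bm_prediction_band(tree, emap, tree.tip_labels, n_sim=20, seed=9)
        assert np.array_equal(b1.outside, b2.outside)
        assert np.all(b1.upper >= b1.lower)
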