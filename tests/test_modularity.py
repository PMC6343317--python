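"""Congruence coefficients, EMMLi model selection, merging, jackknife, CR."""

import math

import numpy as np
import pytest

import morphomod as mm
from morphomod.datatypes import AlignedShapes
from morphomod.modularity import (CorrelationMatrix, ModularityModel,
                                  congruence_matrix, correct_allometry, cr_test,
                                  emmli_fit, jackknife_emmli, merge_regions)
from morphomod.datatypes import RegionMap


def make_aligned(coords, centroid_size=None):
    n, p, _ = coords.shape
    cs = centroid_size if centroid_size is not None else np.ones(n)
    return AlignedShapes(
        specimen_ids=[f"s{i}" for i in range(n)],
        point_ids=[f"p{j}" for j in range(p)],
        coords=coords, centroid_size=np.asarray(cs, dtype=float))


def grid_search_one_module_loglik(z_cells, n_eff, step=1e-4):
    """Independent oracle: 1-D grid search over rho for the one-module model."""
    sd = 1.0 / math.sqrt(n_eff - 3)
    best = -np.inf
    best_rho = None
    for rho in np.arange(0.0, 0.999, step):
        mu = math.atanh(rho)
        ll = (-len(z_cells) * (0.5 * math.log(2 * math.pi) + math.log(sd))
              - float(np.sum((z_cells - mu) ** 2)) / (2 * sd ** 2))
        if ll > best:
            best, best_rho = ll, rho
    return best, best_rho


class TestCongruence:
    def test_self_correlation_is_one(self, rng):
        corr = congruence_matrix(make_aligned(rng.standard_normal((8, 4, 3))))
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_affine_copies_fully_congruent(self, rng):
        coords = np.empty((10, 2, 3))
        coords[:, 0, :] = rng.standard_normal((10, 3))
        coords[:, 1, :] = 2.0 * coords[:, 0, :] + np.array([5.0, -1.0, 3.0])
        corr = congruence_matrix(make_aligned(coords))
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_blocks_zero(self):
        # centered blocks constructed with zero inner product
        coords = np.zeros((4, 2, 3))
        coords[:, 0, 0] = [1, -1, 0, 0]
        coords[:, 1, 0] = [0, 0, 1, -1]
        corr = congruence_matrix(make_aligned(coords + 0.0))
        assert abs(corr.values[0, 1]) < 1e-12

    def test_zero_variance_point_errors(self, rng):
        coords = rng.standard_normal((6, 3, 3))
        coords[:, 2, :] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            congruence_matrix(make_aligned(coords))

    def test_invariance_to_relabeling_and_rotation(self, rng):
        coords = rng.standard_normal((9, 5, 3))
        corr1 = congruence_matrix(make_aligned(coords))
        R = mm.synthetic_data.random_rotation(rng)
        corr2 = congruence_matrix(make_aligned(coords @ R))
        assert np.allclose(corr1.values, corr2.values, atol=1e-9)
        perm = rng.permutation(9)
        corr3 = congruence_matrix(make_aligned(coords[perm]))
        assert np.allclose(corr1.values, corr3.values, atol=1e-12)


class TestEMMLi:
    def test_one_module_matches_grid_search_oracle(self, rng):
        P = 5
        R = np.eye(P)
        iu = np.triu_indices(P, 1)
        vals = rng.uniform(0.1, 0.8, len(iu[0]))
        R[iu] = vals
        R.T[iu] = vals
        corr = CorrelationMatrix(values=R, point_ids=[f"p{i}" for i in range(P)],
                                 n_eff=30)
        model = ModularityModel("one", {f"p{i}": "all" for i in range(P)})
        fit = emmli_fit(corr, [model])
        z = np.arctanh(np.abs(vals))
        oracle_ll, oracle_rho = grid_search_one_module_loglik(z, 30)
        assert fit.log_likelihood["one"] >= oracle_ll - 1e-8
        assert abs(fit.log_likelihood["one"] - oracle_ll) < 1e-4
        assert fit.rho_within["all"] == pytest.approx(oracle_rho, abs=1e-4)
        assert fit.rho_within["all"] == pytest.approx(math.tanh(z.mean()), abs=1e-12)

    def test_no_signal_parsimony_wins(self):
        P = 6
        R = np.full((P, P), 0.5)
        np.fill_diagonal(R, 1.0)
        corr = CorrelationMatrix(values=R, point_ids=[f"p{i}" for i in range(P)],
                                 n_eff=25)
        one = ModularityModel("one", {f"p{i}": "all" for i in range(P)})
        two = ModularityModel("two", {f"p{i}": ("a" if i < 3 else "b")
                                      for i in range(P)})
        fit = emmli_fit(corr, [one, two])
        assert fit.log_likelihood["one"] == pytest.approx(
            fit.log_likelihood["two"], abs=1e-9)
        assert fit.best_model == "one"
        assert sum(fit.weight.values()) == pytest.approx(1.0)

    def test_two_block_structure_strongly_preferred(self, rng):
        cfg = mm.SimConfig(n_tips=40, regions=("A", "B"),
                           points_per_region=(3, 0, 3),
                           true_partition={"A": "m1", "B": "m2"},
                           rho_within_default=0.9, rho_between=0.1,
                           allometry_slope=0.0, missing_region_prob=0.0,
                           seed=17)
        sim = mm.simulate_modular_shapes(cfg, mm.star_tree(40))
        aligned = AlignedShapes(
            specimen_ids=sim.dataset.specimen_ids,
            point_ids=sim.dataset.point_ids,
            coords=sim.aligned_truth, centroid_size=np.ones(40))
        corr = congruence_matrix(aligned)
        pids = aligned.point_ids
        one = ModularityModel("one", {p: "all" for p in pids})
        two = ModularityModel("two", {p: sim.region_map.region_of_point[p]
                                      for p in pids})
        fit = emmli_fit(corr, [one, two])
        assert fit.best_model == "two"
        assert fit.aicc["one"] - fit.aicc["two"] > 10


class TestMergeRegions:
    def test_threshold_rule_arithmetic(self):
        part = merge_regions({"A": 0.7, "B": 0.6}, {("A", "B"): 0.45})
        assert part.n_modules == 1
        part2 = merge_regions({"A": 0.7, "B": 0.6}, {("A", "B"): 0.30})
        assert part2.n_modules == 2

    def test_transitive_components(self):
        rho_w = {"A": 0.8, "B": 0.8, "C": 0.8, "D": 0.8}
        rho_b = {("A", "B"): 0.75, ("B", "C"): 0.75, ("A", "C"): 0.1,
                 ("A", "D"): 0.1, ("B", "D"): 0.1, ("C", "D"): 0.1}
        part = merge_regions(rho_w, rho_b)
        mods = part.modules()
        assert part.module_of_region["A"] == part.module_of_region["C"]
        assert part.module_of_region["D"] not in (part.module_of_region["A"],)
        assert part.n_modules == 2

    def test_order_independence(self, rng):
        regions = [f"r{i}" for i in range(8)]
        rho_w = {r: rng.uniform(0.4, 0.9) for r in regions}
        rho_b = {}
        for i in range(8):
            for j in range(i + 1, 8):
                rho_b[(regions[i], regions[j])] = rng.uniform(0.0, 0.8)
        p1 = merge_regions(rho_w, rho_b)
        shuffled_w = dict(sorted(rho_w.items(), reverse=True))
        shuffled_b = dict(sorted(rho_b.items(), reverse=True))
        p2 = merge_regions(shuffled_w, shuffled_b)
        assert p1.module_of_region == p2.module_of_region


class TestJackknife:
    def test_full_fraction_equals_full_fit(self, rng):
        coords = rng.standard_normal((12, 10, 3))
        aligned = make_aligned(coords)
        rm = RegionMap(region_of_point={f"p{j}": ("A" if j < 5 else "B")
                                        for j in range(10)},
                       region_ids=["A", "B"])
        jk = jackknife_emmli(aligned, rm, fraction=1.0, iters=3, seed=0)
        corr = congruence_matrix(aligned)
        model = ModularityModel("regions", {f"p{j}": ("A" if j < 5 else "B")
                                            for j in range(10)})
        full = emmli_fit(corr, [model])
        assert jk.mean_within["A"] == pytest.approx(full.rho_within["A"], abs=1e-12)
        assert jk.mean_between[("A", "B")] == pytest.approx(
            full.rho_between[("A", "B")], abs=1e-12)
        assert jk.sd_within["A"] == 0.0

    def test_sample_size_matches_fraction(self, rng):
        aligned = make_aligned(rng.standard_normal((10, 40, 3)))
        rm = RegionMap(region_of_point={f"p{j}": f"r{j % 4}" for j in range(40)},
                       region_ids=[f"r{i}" for i in range(4)])
        jk = jackknife_emmli(aligned, rm, fraction=0.10, iters=2, seed=1)
        assert jk.n_points_per_iter == 4


class TestCR:
    def test_single_permutation_counting_rule(self, rng):
        coords = rng.standard_normal((10, 8, 3))
        aligned = make_aligned(coords)
        part = {f"p{j}": ("a" if j < 4 else "b") for j in range(8)}
        res = cr_test(aligned, part, n_perm=1, seed=3)
        assert res.p_value in (0.5, 1.0)

    def test_statistic_invariant_to_point_order_within_modules(self, rng):
        coords = rng.standard_normal((12, 10, 3))
        aligned = make_aligned(coords)
        part = {f"p{j}": ("a" if j < 5 else "b") for j in range(10)}
        r1 = cr_test(aligned, part, n_perm=1, seed=0).cr
        order = [3, 1, 4, 0, 2, 8, 6, 9, 5, 7]
        sub = aligned.subset_points([f"p{j}" for j in order])
        r2 = cr_test(sub, part, n_perm=1, seed=0).cr
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_single_point_module_errors(self, rng):
        aligned = make_aligned(rng.standard_normal((8, 5, 3)))
        part = {"p0": "a", "p1": "b", "p2": "b", "p3": "b", "p4": "b"}
        with pytest.raises(ValueError, match="fewer than 2"):
            cr_test(aligned, part, n_perm=1)


class TestCorrectAllometry:
    def test_size_independent_data_unchanged(self, rng):
        n = 10
        x = np.linspace(1.0, 3.0, n)
        coords = rng.standard_normal((n, 4, 3))
        # project every column to the orthogonal complement of centered log CS
        xc = np.log(x) - np.log(x).mean()
        flat = coords.reshape(n, -1)
        flat -= np.outer(xc, xc @ flat) / (xc @ xc)
        aligned = make_aligned(flat.reshape(n, 4, 3), centroid_size=x)
        resid = correct_allometry(aligned)
        centered = aligned.coords - aligned.coords.mean(axis=0)
        assert np.allclose(resid, centered, atol=1e-10)

    def test_pure_allometry_gives_zero_residuals(self):
        n = 8
        x = np.linspace(1.0, 5.0, n)
        base = np.arange(12, dtype=float).reshape(4, 3)
        coords = np.array([np.log(s) * base + 2.0 for s in x])
        aligned = make_aligned(coords, centroid_size=x)
        resid = correct_allometry(aligned)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_constant_size_errors(self, rng):
        aligned = make_aligned(rng.standard_normal((6, 3, 3)),
                               centroid_size=np.full(6, 2.0))
        with pytest.raises(ValueError, match="constant"):
            correct_allometry(aligned)

    def test_residuals_orthogonal_to_log_size(self, rng):
        n = 15
        cs = np.exp(rng.standard_normal(n))
        aligned = make_aligned(rng.standard_normal((n, 6, 3)), centroid_size=cs)
        resid = correct_allometry(aligned).reshape(n, -1)
        xc = np.log(cs) - np.log(cs).mean()
        corrs = xc @ resid / (np.linalg.norm(xc) * np.linalg.norm(resid, axis=0))
        assert np.all(np.abs(corrs) < 1e-10)


def test_boundary_landmarks_inflate_between_region_correlation(rng):
    """Under smooth spatial variation, landmarks at region boundaries recover
    higher between-region correlation than full surface sampling."""
    n = 40
    # 1-D positions: region A interior, boundary pair, region B interior
    pos_a = np.linspace(-2.0, -0.6, 6)
    pos_bound = np.array([-0.05, 0.05])
    pos_b = np.linspace(0.6, 2.0, 6)
    pos = np.concatenate([pos_a, pos_bound, pos_b])
    # smooth per-specimen deformation fields: GP with length scale 0.7
    K = np.exp(-0.5 * (pos[:, None] - pos[None, :]) ** 2 / 0.7 ** 2)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(len(pos)))
    coords = np.zeros((n, len(pos), 3))
    for d in range(3):
        coords[:, :, d] = (L @ rng.standard_normal((len(pos), n))).T
    aligned = make_aligned(coords)
    corr = congruence_matrix(aligned).values
    a_int, a_bnd = np.arange(6), np.array([6])
    b_bnd, b_int = np.array([7]), np.arange(8, 14)
    between_full = np.abs(corr[np.ix_(np.r_[a_int, a_bnd],
                                      np.r_[b_bnd, b_int])]).mean()
    between_landmarks_only = np.abs(corr[np.ix_(a_bnd, b_bnd)]).mean()
    assert between_landmarks_only > between_full
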