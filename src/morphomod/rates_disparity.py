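"""Morphological disparity and Brownian-motion evolutionary rates.

Disparity is the Procrustes variance: the mean squared (Euclidean,
post-Procrustes) distance of specimens from their mean shape, optionally
divided by the number of points so that modules of different sizes are
comparable.  The net evolutionary rate sigma^2_mult is the phylogenetically
corrected analogue: the GLS-centred, C^-1-weighted mean squared
displacement per unit branch length, again per landmark.  Rate differences
between modules (or between groups of tips) are tested against a null of a
single shared rate by simulating BM on the tree; per-point rates and
variances support landmark-level evolution maps and a simulation-based
prediction band for the rate-disparity relationship expected under BM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .datatypes import AlignedShapes
from .phylo_comparative import Phylogeny, _inv_sqrt, _sqrt_pd, gls_mean, bh_adjust


# ---------------------------------------------------------------------------
# Disparity
# ---------------------------------------------------------------------------

def procrustes_variance(aligned: AlignedShapes,
                        point_subset: Optional[Sequence[str]] = None,
                        per_landmark: bool = True) -> float:
    """Procrustes variance sum_i ||Y_i - Ybar||^2 / n over a point subset.

    Divisor n (not n - 1), matching the convention of the standard
    morphometric toolchain; per_landmark divides by the subset's point
    count.
    """
    sub = aligned if point_subset is None else aligned.subset_points(point_subset)
    if sub.n_points == 0:
        raise ValueError("empty point subset")
    X = sub.flat()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 specimens")
    dev = X - X.mean(axis=0)
    pv = float(np.sum(dev ** 2)) / n
    if per_landmark:
        pv /= sub.n_points
    return pv


@dataclass
class DisparityResult:
    modules: List[str]
    disparity: Dict[str, float]
    difference: np.ndarray          # antisymmetric pairwise differences
    p_values: np.ndarray            # raw, upper triangle mirrored
    p_adjusted: np.ndarray
    n_significant: int
    method: str
    n_perm: int = 0


def pairwise_disparity_tests(aligned: AlignedShapes,
                             module_points: Dict[str, List[str]],
                             n_perm: int = 999, seed: int = 0,
                             method: str = "permutation",
                             alpha: float = 0.05) -> DisparityResult:
    """All pairwise tests of per-landmark disparity differences between modules.

    Default method permutes whole points between each pair of modules
    (sizes fixed) and compares |disparity difference|; p-values are then
    BH-adjusted across pairs.  method="tukey" applies the legacy
    honest-significant-difference test to the per-specimen squared
    deviations (the historical recipe, statistically irregular for
    variances; flagged in the result).
    """
    modules = sorted(module_points)
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    X = aligned.coords
    n = aligned.n_specimens
    pidx = aligned.point_index
    idx = {m: np.array([pidx[p] for p in module_points[m]]) for m in modules}

    def pv_of(cols: np.ndarray) -> float:
        block = X[:, cols, :].reshape(n, -1)
        dev = block - block.mean(axis=0)
        return float(np.sum(dev ** 2)) / n / len(cols)

    disp = {m: pv_of(idx[m]) for m in modules}
    k = len(modules)
    diff = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            diff[a, b] = disp[modules[a]] - disp[modules[b]]

    raw = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    if method == "permutation":
        for a in range(k):
            for b in range(a + 1, k):
                ia, ib = idx[modules[a]], idx[modules[b]]
                pool = np.concatenate([ia, ib])
                obs = abs(disp[modules[a]] - disp[modules[b]])
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(pool)
                    d = abs(pv_of(perm[:len(ia)]) - pv_of(perm[len(ia):]))
                    count += d >= obs
                raw[a, b] = raw[b, a] = (count + 1) / (n_perm + 1)
    elif method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        vals, labs = [], []
        for m in modules:
            block = X[:, idx[m], :].reshape(n, -1)
            dev = block - block.mean(axis=0)
            per_spec = np.sum(dev ** 2, axis=1) / len(idx[m])
            vals.extend(per_spec)
            labs.extend([m] * n)
        res = pairwise_tukeyhsd(np.array(vals), np.array(labs), alpha=alpha)
        pi = 0
        for a in range(k):
            for b in range(a + 1, k):
                raw[a, b] = raw[b, a] = float(res.pvalues[pi])
                pi += 1
    else:
        raise ValueError(f"unknown method {method!r}")

    iu = np.triu_indices(k, 1)
    if method == "permutation":
        adj_flat, _ = bh_adjust(raw[iu], alpha=alpha)
    else:
        adj_flat = raw[iu]  # Tukey p-values are already family-wise
    adj = np.full((k, k), np.nan)
    adj[iu] = adj_flat
    adj.T[iu] = adj_flat
    n_sig = int(np.sum(adj_flat <= alpha))
    return DisparityResult(modules=modules, disparity=disp, difference=diff,
                           p_values=raw, p_adjusted=adj, n_significant=n_sig,
                           method=method, n_perm=n_perm if method == "permutation" else 0)


# ---------------------------------------------------------------------------
# Net evolutionary rates (sigma^2_mult)
# ---------------------------------------------------------------------------

def _subset_matrix(aligned: AlignedShapes,
                   point_subset: Optional[Sequence[str]]) -> Tuple[np.ndarray, int]:
    sub = aligned if point_subset is None else aligned.subset_points(point_subset)
    if sub.n_points == 0:
        raise ValueError("empty point subset")
    return sub.flat(), sub.n_points


def sigma2_mult(phylogeny: Phylogeny, aligned: AlignedShapes,
                point_subset: Optional[Sequence[str]] = None) -> float:
    """Net BM rate: tr[(Y - 1a')' C^-1 (Y - 1a')] / (n L), a the GLS mean."""
    Y, L = _subset_matrix(aligned, point_subset)
    C = phylogeny.covariance(order=aligned.specimen_ids)
    C_inv = np.linalg.inv(C)
    a = gls_mean(C_inv, Y)
    R = Y - a
    n = Y.shape[0]
    return float(np.einsum("ij,ik,kj->", R, C_inv, R)) / (n * L)


def _sigma2_from_matrix(Y: np.ndarray, C_inv: np.ndarray, L: int) -> float:
    a = gls_mean(C_inv, Y)
    R = Y - a
    return float(np.einsum("ij,ik,kj->", R, C_inv, R)) / (Y.shape[0] * L)


@dataclass
class RateResult:
    rates: Dict[str, float]
    ratio: float
    p_value: float
    n_sim: int
    statistic: str = "max/min"


def _simulate_bm_tips(C_half: np.ndarray, n_cols: int, rate_per_col: float,
                      rng: np.random.Generator) -> np.ndarray:
    Z = rng.standard_normal((C_half.shape[0], n_cols))
    return C_half @ Z * math.sqrt(rate_per_col)


def compare_rates_modules(phylogeny: Phylogeny, aligned: AlignedShapes,
                          module_points: Dict[str, List[str]],
                          n_sim: int = 999, seed: int = 0) -> RateResult:
    """Multi-module rate comparison with a max/min rate-ratio statistic.

    The null simulates tip data under single-rate BM with identity trait
    covariance (pooled rate) and recomputes the ratio;
    p = (#(ratio_sim >= ratio_obs) + 1) / (n_sim + 1).
    """
    modules = sorted(module_points)
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    C = phylogeny.covariance(order=aligned.specimen_ids)
    C_inv = np.linalg.inv(C)
    C_half = _sqrt_pd(C)
    pidx = aligned.point_index
    cols = {}
    for m in modules:
        pts = np.array([pidx[p] for p in module_points[m]])
        cols[m] = np.sort(np.concatenate([3 * pts + d for d in range(3)]))
    X = aligned.flat()
    rates = {m: _sigma2_from_matrix(X[:, cols[m]], C_inv, len(module_points[m]))
             for m in modules}
    vals = np.array([rates[m] for m in modules])
    obs_ratio = float(vals.max() / vals.min())
    pooled = _sigma2_from_matrix(X, C_inv, aligned.n_points) / 3.0  # per coordinate

    rng = np.random.default_rng(seed)
    count = 0
    sizes = {m: len(module_points[m]) for m in modules}
    total_cols = 3 * aligned.n_points
    for _ in range(n_sim):
        Ysim = _simulate_bm_tips(C_half, total_cols, pooled, rng)
        sim_rates = [
            _sigma2_from_matrix(Ysim[:, cols[m]], C_inv, sizes[m]) for m in modules
        ]
        ratio = max(sim_rates) / min(sim_rates)
        count += ratio >= obs_ratio
    p = (count + 1) / (n_sim + 1)
    return RateResult(rates=rates, ratio=obs_ratio, p_value=float(p), n_sim=n_sim)


def compare_rates_groups(phylogeny: Phylogeny, aligned: AlignedShapes,
                         tip_groups: Dict[str, List[str]],
                         focal: Optional[str] = None,
                         n_sim: int = 999, seed: int = 0,
                         exclude_tips: Sequence[str] = ()) -> RateResult:
    """Two-group (or k-group) rate comparison across tips.

    Per-group rates come from each group's rows of the phylogenetically
    transformed residuals U = C^(-1/2)(Y - 1a').  The reported ratio is
    focal/other when a focal group is named (two groups only), while the
    test statistic and null simulation use the max/min form.  Tips listed
    in exclude_tips are dropped (tree pruned) before analysis, supporting
    leave-one-out sensitivity checks.
    """
    groups = {g: [t for t in tips if t not in set(exclude_tips)]
              for g, tips in tip_groups.items()}
    names = sorted(groups)
    for g in names:
        if len(groups[g]) < 2:
            raise ValueError(f"group {g} has fewer than 2 tips")
    flat_tips = [t for g in names for t in groups[g]]
    if len(set(flat_tips)) != len(flat_tips):
        raise ValueError("groups overlap (identical membership?)")

    keep = [s for s in aligned.specimen_ids if s in set(flat_tips)]
    sub_idx = [aligned.specimen_ids.index(s) for s in keep]
    Y = aligned.flat()[sub_idx]
    tree = phylogeny.prune_to(keep) if set(keep) != set(phylogeny.tip_labels) else phylogeny
    C = tree.covariance(order=keep)
    C_inv = np.linalg.inv(C)
    P = _inv_sqrt(C)
    C_half = _sqrt_pd(C)
    L = aligned.n_points
    n = len(keep)
    member = {t: g for g in names for t in groups[g]}
    rows = {g: np.array([i for i, s in enumerate(keep) if member[s] == g])
            for g in names}

    def group_rates(Ymat: np.ndarray) -> Dict[str, float]:
        a = gls_mean(C_inv, Ymat)
        U = P @ (Ymat - a)
        return {g: float(np.sum(U[rows[g]] ** 2)) / (len(rows[g]) * L) for g in names}

    rates = group_rates(Y)
    vals = np.array([rates[g] for g in names])
    stat_obs = float(vals.max() / vals.min())
    if focal is not None:
        if len(names) != 2:
            raise ValueError("focal/other ratio requires exactly 2 groups")
        other = next(g for g in names if g != focal)
        ratio = rates[focal] / rates[other]
    else:
        ratio = stat_obs
    pooled = float(vals @ np.array([len(rows[g]) for g in names])) / n / 3.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        Ysim = _simulate_bm_tips(C_half, 3 * L, pooled, rng)
        r = group_rates(Ysim)
        v = np.array([r[g] for g in names])
        count += (v.max() / v.min()) >= stat_obs
    p = (count + 1) / (n_sim + 1)
    return RateResult(rates=rates, ratio=float(ratio), p_value=float(p), n_sim=n_sim,
                      statistic="max/min (ratio reported as focal/other)"
                      if focal else "max/min")


# ---------------------------------------------------------------------------
# Per-landmark evolution maps and the BM prediction band
# ---------------------------------------------------------------------------

@dataclass
class LandmarkEvoMap:
    point_ids: List[str]
    rate: np.ndarray
    variance: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def landmark_evo_map(phylogeny: Phylogeny, aligned: AlignedShapes) -> LandmarkEvoMap:
    """Per-point evolutionary rate and disparity, with their OLS relationship.

    rate is sigma^2_mult restricted to the point's three columns (L = 1);
    variance is the point's (uncorrected) Procrustes variance, so the
    per-point variances sum to the whole-configuration Procrustes variance.
    """
    C = phylogeny.covariance(order=aligned.specimen_ids)
    C_inv = np.linalg.inv(C)
    Y = aligned.flat()
    n = Y.shape[0]
    a = gls_mean(C_inv, Y)
    R = Y - a
    CR = C_inv @ R
    per_col_rate = np.einsum("ij,ij->j", R, CR) / n
    dev = Y - Y.mean(axis=0)
    per_col_var = np.sum(dev ** 2, axis=0) / n
    p = aligned.n_points
    rate = per_col_rate.reshape(p, 3).sum(axis=1)
    variance = per_col_var.reshape(p, 3).sum(axis=1)
    X = sm.add_constant(rate)
    fit = sm.OLS(variance, X).fit()
    return LandmarkEvoMap(point_ids=list(aligned.point_ids), rate=rate,
                          variance=variance, slope=float(fit.params[1]),
                          intercept=float(fit.params[0]),
                          r_squared=float(fit.rsquared))


@dataclass
class BMPredictionBand:
    slope: float
    intercept: float
    lower: np.ndarray
    upper: np.ndarray
    mean_sim_variance: np.ndarray
    outside: np.ndarray           # bool flag per point: observed variance outside band
    n_sim: int


def bm_prediction_band(phylogeny: Phylogeny, evo_map: LandmarkEvoMap,
                       tip_names: Sequence[str], n_sim: int = 100,
                       seed: int = 0, level: float = 0.95) -> BMPredictionBand:
    """Simulation-based BM expectation for the per-point rate-variance relation.

    Each point's rate is split equally over 3 independent coordinates (no
    trait covariation); BM tip data are simulated n_sim times.  The fitted
    line (mean simulated variance regressed on rate) summarises the BM
    expectation; the band bounds are the per-point empirical quantiles of
    the simulated variances at the requested level, so under exact BM about
    (1 - level) of points fall outside by construction.  Points whose
    observed variance falls outside the band are flagged.
    """
    C = phylogeny.covariance(order=tip_names)
    C_half = _sqrt_pd(C)
    n = C.shape[0]
    p = len(evo_map.point_ids)
    rate = np.asarray(evo_map.rate, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p))
    scale = np.sqrt(np.maximum(rate, 0.0) / 3.0)   # per-coordinate sd multiplier
    for b in range(n_sim):
        Z = rng.standard_normal((n, 3 * p))
        Y = C_half @ Z
        Y = Y.reshape(n, p, 3) * scale[None, :, None]
        dev = Y - Y.mean(axis=0)
        sims[b] = np.sum(dev ** 2, axis=(0, 2)) / n
    mean_var = sims.mean(axis=0)

    X = sm.add_constant(rate)
    fit = sm.OLS(mean_var, X).fit()
    alpha = 1 - level
    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    eps = 1e-12
    outside = (evo_map.variance < lower - eps) | (evo_map.variance > upper + eps)
    return BMPredictionBand(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                            lower=lower, upper=upper, mean_sim_variance=mean_var,
                            outside=outside, n_sim=n_sim)
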