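"""Likelihood-based modularity model selection and covariance-ratio tests.

Integration between two points is measured by the congruence coefficient of
their centered (specimen x 3) coordinate blocks.  Candidate partitions of
the points (or regions) into modules are compared by the likelihood of the
Fisher-z transformed |r| values under class-specific correlation
parameters, ranked by AICc (the EMMLi construction).  A post-hoc merging
rule combines regions whose between-region correlation comes within a
threshold of the weaker of their within-region correlations.  The
covariance ratio (CR) provides a complementary, likelihood-free test of
modular structure with significance by permutation of whole points across
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .datatypes import AlignedShapes, RegionMap
from .phylo_comparative import Phylogeny, pic


# ---------------------------------------------------------------------------
# Congruence coefficients
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Point x point congruence coefficients with the effective sample size."""

    values: np.ndarray
    point_ids: List[str]
    n_eff: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)


def congruence_matrix(data, point_ids: Optional[Sequence[str]] = None,
                      n_eff: Optional[int] = None) -> CorrelationMatrix:
    """Congruence coefficients between all point pairs.

    data: AlignedShapes, or an (observations x points x 3) array (e.g.
    independent contrasts reshaped per point).  Entry (p, q) is
    sum(A * B) / sqrt(sum(A^2) sum(B^2)) over observations and axes, where
    A and B are the two points' blocks with each coordinate column centered
    over observations.
    """
    if isinstance(data, AlignedShapes):
        X = data.coords
        point_ids = point_ids or list(data.point_ids)
        n_eff = n_eff if n_eff is not None else data.n_specimens
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 2:  # observations x (3p) flattened
            X = X.reshape(X.shape[0], -1, 3)
        point_ids = point_ids or [f"p{i}" for i in range(X.shape[1])]
        n_eff = n_eff if n_eff is not None else X.shape[0]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    Xc = X - X.mean(axis=0, keepdims=True)
    N = np.einsum("ipk,iqk->pq", Xc, Xc)
    d = np.sqrt(np.diag(N))
    zero = np.where(d <= 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance point(s): {[point_ids[i] for i in zero[:5]]}")
    R = N / np.outer(d, d)
    np.clip(R, -1.0, 1.0, out=R)
    return CorrelationMatrix(values=R, point_ids=list(point_ids), n_eff=int(n_eff))


# ---------------------------------------------------------------------------
# EMMLi-style maximum-likelihood model selection
# ---------------------------------------------------------------------------

@dataclass
class ModularityModel:
    name: str
    partition: Dict[str, str]     # point (or region) id -> module label
    between_mode: str = "per_pair"  # or "single"

    def modules(self) -> List[str]:
        return sorted(set(self.partition.values()))


@dataclass
class EMMLiFit:
    models: List[str]
    log_likelihood: Dict[str, float]
    k: Dict[str, int]
    aicc: Dict[str, float]
    weight: Dict[str, float]
    best_model: str
    rho_within: Dict[str, float]                  # module -> rho, for best model
    rho_between: Dict[Tuple[str, str], float]     # module pair -> rho, for best model
    n_eff: int
    n_cells: int


def _classes_for_model(model: ModularityModel, point_ids: Sequence[str]):
    """Index off-diagonal cells (p<q) by likelihood class."""
    labels = [model.partition[p] for p in point_ids]
    P = len(point_ids)
    iu, ju = np.triu_indices(P, k=1)
    keys = []
    for i, j in zip(iu, ju):
        a, b = labels[i], labels[j]
        if a == b:
            keys.append(("within", a))
        elif model.between_mode == "single":
            keys.append(("between", "*"))
        else:
            keys.append(("between", tuple(sorted((a, b)))))
    return iu, ju, keys


def _fit_classes(z: np.ndarray, keys: List, sd: float):
    """Closed-form ML: per class, atanh(rho_hat) = mean z; Normal logL."""
    groups: Dict = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)
    logL = 0.0
    rho: Dict = {}
    const = -0.5 * math.log(2 * math.pi) - math.log(sd)
    for key, idxs in groups.items():
        zc = z[idxs]
        mu = float(zc.mean())
        rho[key] = math.tanh(mu)
        logL += len(zc) * const - float(np.sum((zc - mu) ** 2)) / (2 * sd ** 2)
    return logL, rho, len(groups)


def emmli_fit(corr: CorrelationMatrix, models: Sequence[ModularityModel],
              count_variance_param: bool = False) -> EMMLiFit:
    """Fit and compare modularity models on a congruence matrix.

    For each model the off-diagonal |r| cells are classed as within-module
    (one class per module) or between-module (single or per-pair); each
    class gets one correlation parameter, estimated in closed form on the
    Fisher-z scale with sd 1/sqrt(n_eff - 3).  Models are ranked by AICc
    with sample size = number of cells.
    """
    if corr.n_eff <= 3:
        raise ValueError("n_eff must exceed 3 for the Fisher-z likelihood")
    sd = 1.0 / math.sqrt(corr.n_eff - 3)
    P = len(corr.point_ids)
    n_cells = P * (P - 1) // 2
    absr = np.abs(corr.values)
    iu0, ju0 = np.triu_indices(P, k=1)
    if np.any(absr[iu0, ju0] >= 1 - 1e-12):
        import warnings
        warnings.warn("|r| = 1 cells clipped to 1 - 1e-6 for the Fisher transform")
    z_full = np.arctanh(np.minimum(absr, 1 - 1e-6))

    logL: Dict[str, float] = {}
    kpar: Dict[str, int] = {}
    aicc: Dict[str, float] = {}
    rho_by_model: Dict[str, Dict] = {}
    for model in models:
        missing = [p for p in corr.point_ids if p not in model.partition]
        if missing:
            raise ValueError(f"model {model.name} does not cover points {missing[:5]}")
        iu, ju, keys = _classes_for_model(model, corr.point_ids)
        z = z_full[iu, ju]
        ll, rho, k = _fit_classes(z, keys, sd)
        if count_variance_param:
            k += 1
        if n_cells <= k + 1:
            raise ValueError(
                f"model {model.name}: AICc undefined ({n_cells} cells, {k} parameters)")
        logL[model.name] = ll
        kpar[model.name] = k
        aicc[model.name] = -2 * ll + 2 * k + 2 * k * (k + 1) / (n_cells - k - 1)
        rho_by_model[model.name] = rho

    best = min(aicc, key=aicc.get)
    delta = {m: aicc[m] - aicc[best] for m in aicc}
    raw_w = {m: math.exp(-0.5 * d) for m, d in delta.items()}
    tot = sum(raw_w.values())
    weight = {m: w / tot for m, w in raw_w.items()}

    best_model = next(m for m in models if m.name == best)
    rho = rho_by_model[best]
    rho_within = {key[1]: max(0.0, r) for key, r in rho.items() if key[0] == "within"}
    rho_between: Dict[Tuple[str, str], float] = {}
    for key, r in rho.items():
        if key[0] != "between":
            continue
        if key[1] == "*":
            for a in best_model.modules():
                for b in best_model.modules():
                    if a < b:
                        rho_between[(a, b)] = max(0.0, r)
        else:
            rho_between[key[1]] = max(0.0, r)
    return EMMLiFit(
        models=[m.name for m in models], log_likelihood=logL, k=kpar, aicc=aicc,
        weight=weight, best_model=best, rho_within=rho_within,
        rho_between=rho_between, n_eff=corr.n_eff, n_cells=n_cells,
    )


def region_model(region_map: RegionMap, point_ids: Sequence[str],
                 name: str = "all_regions") -> ModularityModel:
    """The finest model: each region its own module."""
    return ModularityModel(
        name=name,
        partition={p: region_map.region_of_point[p] for p in point_ids},
    )


def model_from_region_grouping(name: str, region_map: RegionMap,
                               point_ids: Sequence[str],
                               grouping: Dict[str, str]) -> ModularityModel:
    """Lift a region -> module grouping to a point-level model."""
    part = {p: grouping[region_map.region_of_point[p]] for p in point_ids}
    return ModularityModel(name=name, partition=part)


# ---------------------------------------------------------------------------
# Post-hoc merging of regions into modules
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    module_of_region: Dict[str, str]
    threshold: float

    def modules(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for region, module in self.module_of_region.items():
            out.setdefault(module, []).append(region)
        return {m: sorted(rs) for m, rs in out.items()}

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of_region.values()))


def merge_regions(rho_within: Dict[str, float],
                  rho_between: Dict[Tuple[str, str], float],
                  threshold: float = 0.2) -> ModulePartition:
    """Merge regions whose between-correlation approaches their within-correlations.

    Regions a and b are connected when
    min(rho_within[a], rho_within[b]) - rho_between[(a, b)] <= threshold;
    merged modules are the connected components of this graph.  Module
    labels join the member region names with '+'.
    """
    G = nx.Graph()
    G.add_nodes_from(rho_within)
    for (a, b), rb in rho_between.items():
        if a not in rho_within or b not in rho_within:
            continue
        if min(rho_within[a], rho_within[b]) - rb <= threshold:
            G.add_edge(a, b)
    module_of_region: Dict[str, str] = {}
    for comp in nx.connected_components(G):
        label = "+".join(sorted(comp))
        for region in comp:
            module_of_region[region] = label
    return ModulePartition(module_of_region=module_of_region, threshold=threshold)


# ---------------------------------------------------------------------------
# Jackknife robustness resampling
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    regions: List[str]
    mean_within: Dict[str, float]
    sd_within: Dict[str, float]
    mean_between: Dict[Tuple[str, str], float]
    sd_between: Dict[Tuple[str, str], float]
    n_points_per_iter: int
    iters: int


def jackknife_emmli(aligned_or_corr, region_map: RegionMap,
                    fraction: float = 0.10, iters: int = 100,
                    seed: int = 0) -> JackknifeResult:
    """Jackknife the point set down to a fraction and refit region correlations.

    Each iteration samples floor(fraction * P) points without replacement,
    recomputes congruence coefficients and the region-level rho estimates;
    returns element-wise mean and SD over iterations.  A region reduced to
    fewer than 2 points in an iteration contributes no within-rho for that
    iteration.
    """
    if isinstance(aligned_or_corr, AlignedShapes):
        full_ids = list(aligned_or_corr.point_ids)
        get_corr = lambda ids: congruence_matrix(aligned_or_corr.subset_points(ids))
    else:
        corr_full: CorrelationMatrix = aligned_or_corr
        full_ids = list(corr_full.point_ids)
        idx_of = {p: i for i, p in enumerate(full_ids)}

        def get_corr(ids):
            idx = [idx_of[p] for p in ids]
            return CorrelationMatrix(values=corr_full.values[np.ix_(idx, idx)],
                                     point_ids=list(ids), n_eff=corr_full.n_eff)

    P = len(full_ids)
    n_sample = max(2, int(math.floor(fraction * P)))
    rng = np.random.default_rng(seed)
    regions = list(region_map.region_ids)
    acc_w: Dict[str, List[float]] = {r: [] for r in regions}
    acc_b: Dict[Tuple[str, str], List[float]] = {}
    for _ in range(iters):
        if n_sample >= P:
            ids = full_ids
        else:
            ids = [full_ids[i] for i in sorted(rng.choice(P, n_sample, replace=False))]
        sub = get_corr(ids)
        present = [r for r in regions if len(region_map.points_in(r, ids)) >= 2]
        if len(present) < 1:
            continue
        model = ModularityModel(
            name="regions",
            partition={p: region_map.region_of_point[p] for p in ids},
        )
        fit = emmli_fit(sub, [model])
        for r, v in fit.rho_within.items():
            acc_w[r].append(v)
        for pair, v in fit.rho_between.items():
            acc_b.setdefault(pair, []).append(v)

    mean_w = {r: float(np.mean(v)) for r, v in acc_w.items() if v}
    sd_w = {r: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for r, v in acc_w.items() if v}
    mean_b = {k: float(np.mean(v)) for k, v in acc_b.items()}
    sd_b = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for k, v in acc_b.items()}
    return JackknifeResult(regions=regions, mean_within=mean_w, sd_within=sd_w,
                           mean_between=mean_b, sd_between=sd_b,
                           n_points_per_iter=n_sample, iters=iters)


# ---------------------------------------------------------------------------
# Covariance ratio
# ---------------------------------------------------------------------------

@dataclass
class CRResult:
    cr: float
    pairwise: np.ndarray
    modules: List[str]
    p_value: float
    n_perm: int


def _cr_statistic(S: np.ndarray, blocks: List[np.ndarray]) -> Tuple[float, np.ndarray]:
    k = len(blocks)
    within_tr = np.empty(k)
    for a in range(k):
        Sa = S[np.ix_(blocks[a], blocks[a])].copy()
        np.fill_diagonal(Sa, 0.0)
        within_tr[a] = np.sum(Sa * Sa)
    pairwise = np.full((k, k), np.nan)
    vals = []
    for a in range(k):
        for b in range(a + 1, k):
            Sab = S[np.ix_(blocks[a], blocks[b])]
            denom = math.sqrt(within_tr[a] * within_tr[b])
            if denom <= 0:
                raise ValueError("module with zero within-block covariance "
                                 "(single-point module?)")
            cr = math.sqrt(np.sum(Sab * Sab) / denom)
            pairwise[a, b] = pairwise[b, a] = cr
            vals.append(cr)
    return float(np.mean(vals)), pairwise


def cr_test(aligned: AlignedShapes, partition: Dict[str, str],
            n_perm: int = 999, seed: int = 0) -> CRResult:
    """Covariance-ratio test of modular structure.

    CR(a, b) compares cross-block to (diagonal-zeroed) within-block
    covariance; values well below 1 indicate modularity.  The null permutes
    whole points (x, y, z kept together) across modules with module sizes
    fixed; p = #(CR_perm <= CR_obs + 1) / (n_perm + 1).
    """
    if aligned.n_specimens < 3:
        raise ValueError("need at least 3 specimens")
    modules = sorted(set(partition.values()))
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    labels = np.array([partition[p] for p in aligned.point_ids])
    X = aligned.flat()
    S = np.cov(X, rowvar=False, ddof=1)
    P = aligned.n_points

    def col_blocks(lab):
        blocks = []
        for m in modules:
            pts = np.where(lab == m)[0]
            if pts.size < 2:
                raise ValueError(f"module {m} has fewer than 2 points")
            cols = np.concatenate([3 * pts + d for d in range(3)])
            blocks.append(np.sort(cols))
        return blocks

    obs, pairwise = _cr_statistic(S, col_blocks(labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_lab = labels[rng.permutation(P)]
        cr_p, _ = _cr_statistic(S, col_blocks(perm_lab))
        count += cr_p <= obs
    p = (count + 1) / (n_perm + 1)
    return CRResult(cr=obs, pairwise=pairwise, modules=modules,
                    p_value=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Corrected data variants
# ---------------------------------------------------------------------------

def correct_allometry(aligned: AlignedShapes) -> np.ndarray:
    """Residual shape after OLS of every coordinate column on log centroid size.

    Returns an (n x points x 3) residual array whose columns are orthogonal
    to log centroid size.
    """
    cs = aligned.centroid_size
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    x = np.log(cs)
    if np.ptp(x) <= 0:
        raise ValueError("constant centroid size: allometry not estimable")
    X = np.column_stack([np.ones_like(x), x])
    Y = aligned.flat()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.reshape(aligned.coords.shape)


def phylo_corrected_blocks(aligned: AlignedShapes, phylogeny: Phylogeny) -> np.ndarray:
    """Independent contrasts of the shape columns, reshaped to
    (n-1) x points x 3 for the congruence step (n_eff = n - 1)."""
    contrasts = pic(phylogeny, aligned.flat(), aligned.specimen_ids)
    return contrasts.reshape(contrasts.shape[0], aligned.n_points, 3)
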