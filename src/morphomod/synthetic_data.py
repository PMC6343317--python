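"""Synthetic phylogenies and modularly-evolving landmark configurations.

The generator emulates the statistical structure the analysis pipeline
assumes in a comparative study of skull shape:

* an ultrametric pure-birth phylogeny over the sampled species;
* tip configurations of 3-D landmarks, curve semilandmarks and surface
  semilandmarks grouped into named cranial regions, evolving under
  Brownian motion with a block-modular trait correlation matrix (a stated
  within-module and between-module correlation, the same correlation
  applied to each coordinate axis of a point pair, axes mutually
  independent);
* per-module rate multipliers, allometric shape-size covariation (a mean
  displacement along a fixed direction in shape space, proportional to log
  centroid size), and categorical ecological group effects;
* raw "specimens" produced by applying random similarity transforms
  (rotation with determinant +1, translation, scale) and occasional
  whole-region absences, so that superimposition, missing-region encoding
  and sliding are all exercised.

The defaults mirror the dimensions of the motivating study — 35 tips
sampled from 16 cranial regions with modest fractions of landmarks, curve
and surface semilandmarks per region — at a reduced point count per region
so the whole pipeline stays desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import CurveSpec, LandmarkDataset, RegionMap, TraitTable
from .phylo_comparative import Phylogeny

# Region ids follow the anatomical shorthand of the motivating system:
# frontal, parietal, dorsal/palatal nasopremaxilla, the three maxillopalatine
# surfaces, occipital region and condyle, quadrate lateral and jaw-joint
# surfaces, squamosal, ventral os basale, vomer, pterygoid, stapes.
DEFAULT_REGIONS: Tuple[str, ...] = (
    "Fr", "Pa", "NPM_d", "NPM_p", "Max_l", "Max_i", "Max_p", "Occ",
    "Co", "Qu", "JJ", "Sq", "BS", "Vo", "Pt", "St",
)

# A ten-module grouping of the sixteen regions (the cheek, occipital,
# maxillopalatine and palatal complexes each span several regions).
DEFAULT_TRUE_PARTITION: Dict[str, str] = {
    "Fr": "frontal", "Pa": "parietal",
    "NPM_d": "npm_dorsal", "NPM_p": "npm_palatal",
    "Max_l": "maxillopalatine", "Max_i": "maxillopalatine", "Max_p": "maxillopalatine",
    "Occ": "occipital", "Co": "occipital",
    "Qu": "cheek", "JJ": "cheek", "Sq": "cheek",
    "BS": "basale_vomer", "Vo": "basale_vomer",
    "Pt": "pterygoid", "St": "stapes",
}


@dataclass
class SimConfig:
    """Parameters of the generating model.

    points_per_region counts (landmarks, curve semilandmarks, surface
    semilandmarks) per region.  rho_within/rho_between are point-pair
    correlations; base_rate is BM variance per unit time per coordinate;
    rate_multipliers scale it per module.  allometry_slope is shape
    displacement (Procrustes units) per unit log centroid size;
    group_effect maps fossoriality level to a mean-offset magnitude.
    Noise magnitudes govern the random similarity transforms applied to
    raw specimens.
    """

    n_tips: int = 35
    regions: Tuple[str, ...] = DEFAULT_REGIONS
    points_per_region: Tuple[int, int, int] = (3, 5, 4)
    true_partition: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARTITION))
    rho_within: Dict[str, float] = field(default_factory=dict)   # module -> rho
    rho_within_default: float = 0.8
    rho_between: float = 0.1
    # per-coordinate BM variance per unit time: sd 0.1 at depth 1, i.e. ~10%
    # of the unit point scale, the relative variation scale of dense cranial
    # shape data
    base_rate: float = 1e-2
    rate_multipliers: Dict[str, float] = field(
        default_factory=lambda: {"cheek": 2.0})
    # shape displacement per unit log centroid size; with log-CS sd 0.4 this
    # puts allometry near 15% of total shape variance
    allometry_slope: float = 2.5
    # fossoriality-category mean offset: a small (~4% of variance) effect
    group_effect: float = 0.5
    log_cs_mean: float = math.log(20.0)   # ~20 mm skulls
    log_cs_sd: float = 0.4
    rotation_noise: bool = True
    translation_noise: float = 10.0
    # multiplicative size jitter (log-sd); small, as tomographic specimens
    # carry calibrated absolute scale
    scale_noise: float = 0.02
    # region absence probabilities: only the variably present elements
    # (stapes, pterygoid) go missing, at study-like frequencies (~3/35 and
    # ~2/35 specimens); a scalar applies one probability to every region
    missing_region_prob: object = field(
        default_factory=lambda: {"St": 0.09, "Pt": 0.06})
    seed: int = 0
    nearest_pd_fallback: bool = False

    def missing_prob(self, region: str) -> float:
        if isinstance(self.missing_region_prob, dict):
            return float(self.missing_region_prob.get(region, 0.0))
        return float(self.missing_region_prob)

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        probs = (list(self.missing_region_prob.values())
                 if isinstance(self.missing_region_prob, dict)
                 else [self.missing_region_prob])
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("missing_region_prob must be in [0, 1]")
        mods = set(self.true_partition.values())
        rw = {m: self.rho_within.get(m, self.rho_within_default) for m in mods}
        if any(not (0 <= v < 1) for v in rw.values()):
            raise ValueError("rho_within values must lie in [0, 1)")
        if not (0 <= self.rho_between < 1):
            raise ValueError("rho_between must lie in [0, 1)")
        self.rho_within = rw

    def module_of_region(self, region: str) -> str:
        return self.true_partition[region]


@dataclass
class GroundTruth:
    partition: Dict[str, str]
    rho_within: Dict[str, float]
    rho_between: float
    rate_per_module: Dict[str, float]
    allometry_slope: float
    allometry_direction: np.ndarray
    log_centroid_size: Dict[str, float]


@dataclass
class SimulatedDataset:
    dataset: LandmarkDataset          # raw, unaligned specimens
    aligned_truth: np.ndarray         # tip configurations before noise (n, p, 3)
    phylogeny: Phylogeny
    region_map: RegionMap
    traits: TraitTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, depth scaled to 1, tips t1..tn."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)

    # each active lineage: (parent_record, birth_time); records become nodes
    class Node:
        __slots__ = ("time", "children")

        def __init__(self, time):
            self.time = time
            self.children: List[Tuple[Node, float]] = []  # (child, branch)

    root = Node(0.0)
    active: List[Tuple[Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent, birth = active.pop(i)
        node = Node(t)
        parent.children.append((node, t - birth))
        active.append((node, t))
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / n_tips)

    labels = iter(f"t{i + 1}" for i in range(n_tips))
    tip_branches: List[Tuple[Node, float, str]] = []
    for parent, birth in active:
        tip_branches.append((parent, t_end - birth, next(labels)))
    for parent, length, label in tip_branches:
        parent.children.append((label, length))

    scale = 1.0 / t_end if t_end > 0 else 1.0

    def newick(node) -> str:
        parts = []
        for child, length in node.children:
            bl = length * scale
            if isinstance(child, str):
                parts.append(f"{child}:{bl:.12f}")
            else:
                parts.append(f"{newick(child)}:{bl:.12f}")
        return "(" + ",".join(parts) + ")"

    return Phylogeny.from_newick(newick(root) + ";")


def star_tree(n_tips: int, depth: float = 1.0) -> Phylogeny:
    """Star phylogeny: all tips attach directly to the root at equal depth."""
    parts = ",".join(f"t{i + 1}:{depth}" for i in range(n_tips))
    return Phylogeny.from_newick(f"({parts});")


# ---------------------------------------------------------------------------
# Region layout and mean shape
# ---------------------------------------------------------------------------

def _region_points(config: SimConfig) -> Tuple[List[str], List[str], List[str],
                                               List[CurveSpec], Dict[str, str],
                                               Dict[str, str]]:
    """Point ids, roles, sides, curve specs, region map, anchors."""
    n_lm, n_cv, n_sf = config.points_per_region
    point_ids: List[str] = []
    roles: List[str] = []
    sides: List[str] = []
    curves: List[CurveSpec] = []
    region_of: Dict[str, str] = {}
    regions = list(config.regions)
    for region in regions:
        lm_ids = [f"{region}_lm{i}" for i in range(n_lm)]
        cv_ids = [f"{region}_cv{i}" for i in range(n_cv)]
        sf_ids = [f"{region}_sf{i}" for i in range(n_sf)]
        point_ids += lm_ids + cv_ids + sf_ids
        roles += (["landmark"] * n_lm + ["curve_semilandmark"] * n_cv
                  + ["surface_semilandmark"] * n_sf)
        # midline regions carry midline landmarks so a mirror plane exists
        is_mid = region in {"Fr", "Pa", "BS"}
        sides += (["midline" if is_mid else "right"] * n_lm
                  + ["right"] * (n_cv + n_sf))
        for pid in lm_ids + cv_ids + sf_ids:
            region_of[pid] = region
        if n_cv >= 1 and n_lm >= 2:
            curves.append(CurveSpec(curve_id=f"curve_{region}", point_ids=cv_ids,
                                    anchor_start=lm_ids[0], anchor_end=lm_ids[1]))
    return point_ids, roles, sides, curves, region_of


def _mean_shape(config: SimConfig, roles: List[str], sides: List[str],
                region_of: Dict[str, str], point_ids: List[str],
                rng: np.random.Generator) -> np.ndarray:
    """A smooth-ish reference configuration: region clusters on a hemisphere,
    curve semilandmarks along arcs between their anchors."""
    regions = list(config.regions)
    n_reg = len(regions)
    centers = {}
    for i, region in enumerate(regions):
        theta = 2 * math.pi * i / n_reg
        phi = math.pi * (0.25 + 0.5 * ((i * 7) % n_reg) / n_reg)
        centers[region] = np.array([
            abs(math.sin(phi) * math.cos(theta)) + 0.3,   # keep x > 0 (right side)
            math.sin(phi) * math.sin(theta),
            math.cos(phi),
        ])
    p = len(point_ids)
    mean = np.empty((p, 3))
    by_region: Dict[str, List[int]] = {}
    for j, pid in enumerate(point_ids):
        by_region.setdefault(region_of[pid], []).append(j)
    for region, idxs in by_region.items():
        c = centers[region]
        lm = [j for j in idxs if roles[j] == "landmark"]
        cv = [j for j in idxs if roles[j] == "curve_semilandmark"]
        sf = [j for j in idxs if roles[j] == "surface_semilandmark"]
        for j in lm + sf:
            mean[j] = c + 0.15 * rng.standard_normal(3)
        if cv and len(lm) >= 2:
            a, b = mean[lm[0]], mean[lm[1]]
            bow = 0.1 * rng.standard_normal(3)
            ts = np.linspace(0, 1, len(cv) + 2)[1:-1]
            for t, j in zip(ts, cv):
                mean[j] = (1 - t) * a + t * b + math.sin(math.pi * t) * bow
        elif cv:
            for j in cv:
                mean[j] = c + 0.15 * rng.standard_normal(3)
    for j, s in enumerate(sides):
        if s == "midline":
            mean[j, 0] = 0.0
    return mean


def _nearest_pd(A: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    w = np.clip(w, 1e-10, None)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    return B / np.outer(d, d)


def point_covariance(config: SimConfig, point_ids: List[str],
                     region_of: Dict[str, str]) -> np.ndarray:
    """Point-level (per-axis) covariance K = D * Rho * D.

    Rho has rho_within[m] for point pairs sharing module m and rho_between
    otherwise; D scales each point by sqrt(base_rate * module multiplier).
    """
    modules = [config.module_of_region(region_of[p]) for p in point_ids]
    P = len(point_ids)
    rho = np.full((P, P), config.rho_between)
    for i in range(P):
        for j in range(P):
            if modules[i] == modules[j]:
                rho[i, j] = config.rho_within[modules[i]]
    np.fill_diagonal(rho, 1.0)
    try:
        np.linalg.cholesky(rho)
    except np.linalg.LinAlgError:
        if config.nearest_pd_fallback:
            rho = _nearest_pd(rho)
        else:
            raise ValueError(
                f"block correlation matrix not positive definite "
                f"(rho_within={config.rho_within}, rho_between={config.rho_between}); "
                "set nearest_pd_fallback=True to project to the nearest "
                "positive-definite correlation matrix") from None
    var = np.array([config.base_rate
                    * config.rate_multipliers.get(m, 1.0) for m in modules])
    d = np.sqrt(var)
    return rho * np.outer(d, d)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def _bm_tip_values(phylogeny: Phylogeny, tips: List[str],
                   rng: np.random.Generator, n_cols: int = 1) -> np.ndarray:
    C = phylogeny.covariance(order=tips)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tips)))
    return L @ rng.standard_normal((len(tips), n_cols))


def _simulate_traits(phylogeny: Phylogeny, tips: List[str],
                     rng: np.random.Generator) -> TraitTable:
    """Ecological covariates with realistic phylogenetic structure.

    Fossoriality comes from binning a BM liability into five equal-frequency
    categories; obligate aquatic habit is a single small clade; reproduction
    and life history are BM liabilities thresholded at the study-like
    frequencies, with occasional missing values.
    """
    n = len(tips)
    liab = _bm_tip_values(phylogeny, tips, rng, 3)
    foss_bins = np.searchsorted(np.quantile(liab[:, 0], [0.2, 0.4, 0.6, 0.8]),
                                liab[:, 0])
    foss = {t: int(b) for t, b in zip(tips, foss_bins)}

    # obligate aquatic: the clade whose size is closest to ~9% of tips (>= 2)
    target = max(2, int(round(0.09 * n)))
    best, best_gap = None, None
    for node in phylogeny.tree.preorder_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(leaves) <= max(2, n // 3):
            gap = abs(len(leaves) - target)
            if best_gap is None or gap < best_gap:
                best, best_gap = leaves, gap
    aquatic_tips = set(best or tips[:2])
    aquatic = {t: ("obligate" if t in aquatic_tips else "non-obligate")
               for t in tips}

    repro_thresh = np.quantile(liab[:, 1], 0.65)
    repro: Dict[str, Optional[str]] = {
        t: ("viviparous" if liab[i, 1] > repro_thresh else "oviparous")
        for i, t in enumerate(tips)}
    life_thresh = np.quantile(liab[:, 2], 0.6)
    life: Dict[str, Optional[str]] = {
        t: ("direct" if liab[i, 2] > life_thresh else "larval")
        for i, t in enumerate(tips)}
    # occasional unknown states, as in real trait compilations
    if n >= 10:
        for t in rng.choice(tips, 2, replace=False):
            repro[t] = None
        life[str(rng.choice(tips))] = None

    # guarantee both levels occur at least twice among scored tips
    def ensure_two(d: Dict[str, Optional[str]], a: str, b: str) -> None:
        for lv in (a, b):
            have = [t for t in tips if d[t] == lv]
            if len(have) < 2:
                pool = [t for t in tips if d[t] is not None and d[t] != lv]
                for t in pool[:2 - len(have)]:
                    d[t] = lv
    ensure_two(repro, "oviparous", "viviparous")
    ensure_two(life, "direct", "larval")
    return TraitTable(specimen_ids=list(tips), fossoriality=foss, aquatic=aquatic,
                      reproduction=repro, life_history=life)


# ---------------------------------------------------------------------------
# Main simulation
# ---------------------------------------------------------------------------

def simulate_modular_shapes(config: SimConfig,
                            phylogeny: Optional[Phylogeny] = None) -> SimulatedDataset:
    """Simulate tip shape configurations under block-modular Brownian motion.

    Tip coordinate vectors follow a matrix normal with row covariance C
    (the tree) and per-axis column covariance K (see
    :func:`point_covariance`); the three axes of a point are mutually
    independent.  Allometry and ecological group effects enter as mean
    shifts.  The returned dataset holds the noise-free aligned truth; call
    :func:`make_raw_specimens` (or use the raw dataset included here) for
    the unaligned specimens.
    """
    rng = np.random.default_rng(config.seed)
    if phylogeny is None:
        phylogeny = simulate_tree(config.n_tips, seed=int(rng.integers(2 ** 31)))
    tips = list(phylogeny.tip_labels)
    n = len(tips)

    point_ids, roles, sides, curves, region_of = _region_points(config)
    p = len(point_ids)
    mean = _mean_shape(config, roles, sides, region_of, point_ids, rng)
    # anchor for a missing region: the landmark of another region closest to
    # the region's centroid in the mean configuration (the landmark whose
    # position best represents the missing region's location)
    anchors: Dict[str, str] = {}
    for region in config.regions:
        idx = [j for j, pid in enumerate(point_ids) if region_of[pid] == region]
        centroid = mean[idx].mean(axis=0)
        cands = [(float(np.linalg.norm(mean[j] - centroid)), point_ids[j])
                 for j, pid in enumerate(point_ids)
                 if roles[j] == "landmark" and region_of[pid] != region]
        anchors[region] = min(cands)[1]

    K = point_covariance(config, point_ids, region_of)
    C = phylogeny.covariance(order=tips)
    C_half = np.linalg.cholesky(C)
    w, V = np.linalg.eigh(K)
    K_half = (V * np.sqrt(np.clip(w, 0, None))) @ V.T

    dev = np.empty((n, p, 3))
    for d in range(3):
        Z = rng.standard_normal((n, p))
        dev[:, :, d] = C_half @ Z @ K_half

    # log centroid size evolves by BM on the same tree (size is itself
    # phylogenetically structured in real comparative data)
    log_cs = (config.log_cs_mean
              + config.log_cs_sd * _bm_tip_values(phylogeny, tips, rng)[:, 0])
    u = rng.standard_normal((p, 3))
    u /= np.linalg.norm(u)
    traits = _simulate_traits(phylogeny, tips, rng)
    g = rng.standard_normal((5, p, 3))
    g /= np.linalg.norm(g, axis=(1, 2), keepdims=True)

    coords = np.empty((n, p, 3))
    for i, t in enumerate(tips):
        shape = mean + dev[i]
        shape = shape + config.allometry_slope * (log_cs[i] - config.log_cs_mean) * u
        if config.group_effect:
            shape = shape + config.group_effect * g[traits.fossoriality[t]]
        coords[i] = shape

    region_map = RegionMap(
        region_of_point=dict(region_of), region_ids=list(config.regions),
        anchor_of_region=anchors)
    aligned_truth = coords.copy()

    dataset = LandmarkDataset(
        specimen_ids=list(tips), point_ids=list(point_ids), coords=coords,
        point_role=list(roles), side=list(sides), curves=curves, missing={},
    )
    truth = GroundTruth(
        partition=dict(config.true_partition),
        rho_within=dict(config.rho_within), rho_between=config.rho_between,
        rate_per_module={m: config.base_rate * config.rate_multipliers.get(m, 1.0)
                         for m in set(config.true_partition.values())},
        allometry_slope=config.allometry_slope, allometry_direction=u,
        log_centroid_size={t: float(lc) for t, lc in zip(tips, log_cs)},
    )
    return SimulatedDataset(dataset=dataset, aligned_truth=aligned_truth,
                            phylogeny=phylogeny, region_map=region_map,
                            traits=traits, truth=truth)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation with determinant +1 (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return Q


def make_raw_specimens(sim: SimulatedDataset,
                       config: Optional[SimConfig] = None,
                       seed: Optional[int] = None) -> LandmarkDataset:
    """Turn true tip shapes into raw specimens: similarity-transform noise
    plus optional whole-region absences.

    Each specimen is scaled to its drawn centroid size, rotated by a
    uniform random rotation (det +1), and translated.  Region absences
    follow a Brownian liability on the tree thresholded at the configured
    probability, so element loss is phylogenetically clustered (as real
    element absences are); absent regions get NaN coordinates and are
    recorded in the dataset's missing table.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ds = sim.dataset.copy()
    n, p, _ = ds.coords.shape
    region_map = sim.region_map
    tips = list(ds.specimen_ids)
    absent: Dict[str, set] = {}
    for region in region_map.region_ids:
        prob = config.missing_prob(region)
        if prob <= 0:
            absent[region] = set()
            continue
        liab = _bm_tip_values(sim.phylogeny, tips, rng)[:, 0]
        thresh = np.quantile(liab, prob)
        absent[region] = {t for t, v in zip(tips, liab) if v <= thresh}
    for i, specimen in enumerate(ds.specimen_ids):
        X = sim.aligned_truth[i].copy()
        X -= X.mean(axis=0)
        cs = np.sqrt(np.sum(X ** 2))
        target_cs = math.exp(sim.truth.log_centroid_size[specimen])
        X *= target_cs / cs
        if config.scale_noise > 0:
            X *= math.exp(config.scale_noise * rng.standard_normal())
        if config.rotation_noise:
            X = X @ random_rotation(rng)
        if config.translation_noise > 0:
            X = X + config.translation_noise * rng.standard_normal(3)
        ds.coords[i] = X
        for region in region_map.region_ids:
            if specimen in absent[region]:
                pts = region_map.points_in(region, ds.point_ids)
                idx = [ds.point_index[pid] for pid in pts]
                ds.coords[i, idx, :] = np.nan
                ds.missing.setdefault(specimen, []).append(region)
    return ds


def simulate_study(config: Optional[SimConfig] = None) -> SimulatedDataset:
    """One-call generator: tree, modular shapes, traits and raw specimens."""
    config = config or SimConfig()
    sim = simulate_modular_shapes(config)
    sim.dataset = make_raw_specimens(sim, config)
    return sim
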