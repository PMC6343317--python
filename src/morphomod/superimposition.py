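"""Procrustes superimposition of landmark/semilandmark configurations.

The stage sequence mirrors the standard high-density workflow for bilateral
structures digitised on one side only:

1. resample digitised curves to equidistant semilandmarks;
2. mirror right-side points through the midline plane so the alignment sees
   a bilaterally symmetric configuration;
3. encode regions absent in a specimen as an "infinitesimal surface" (all
   points of the region collapsed onto a designated anchor landmark);
4. generalised Procrustes analysis (GPA): remove translation, scale and
   rotation (reflections never allowed);
5. slide curve semilandmarks along their tangent and surface semilandmarks
   within their tangent plane to minimise thin-plate-spline bending energy
   against the Procrustes mean, re-running GPA after each pass;
6. drop the mirrored points, keeping midline + right side for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import AlignedShapes, CurveSpec, LandmarkDataset, RegionMap, centroid_size


@dataclass
class SlidingSpec:
    """Which points slide, and along what local geometry.

    curves: ordered chains whose interior points slide along the chord
    through their neighbours; surface_points slide in a tangent plane
    estimated from the ``tangent_k`` nearest reference points.
    """

    curves: List[CurveSpec] = field(default_factory=list)
    surface_points: List[str] = field(default_factory=list)
    slide_iterations: int = 3
    tolerance: float = 1e-6
    tangent_k: int = 8

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for c in self.curves:
            for pid in c.point_ids:
                if pid in seen:
                    raise ValueError(f"point {pid} appears in curves {seen[pid]} and {c.curve_id}")
                seen[pid] = c.curve_id

    @classmethod
    def from_dataset(cls, dataset: LandmarkDataset, slide_iterations: int = 3,
                     tolerance: float = 1e-6) -> "SlidingSpec":
        surf = [pid for pid, role in zip(dataset.point_ids, dataset.point_role)
                if role == "surface_semilandmark"]
        return cls(curves=list(dataset.curves), surface_points=surf,
                   slide_iterations=slide_iterations, tolerance=tolerance)


# ---------------------------------------------------------------------------
# Curve resampling
# ---------------------------------------------------------------------------

def resample_curve(points: np.ndarray, k: int) -> np.ndarray:
    """Resample an ordered polyline to k points equidistant in arc length.

    Endpoints are preserved exactly; interior points lie on the
    piecewise-linear input curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 ordered input points")
    if k < 2:
        raise ValueError("k must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length curve cannot be resampled")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, pts.shape[1]))
    out[0], out[-1] = pts[0], pts[-1]
    for i, t in enumerate(targets[1:-1], start=1):
        j = int(np.searchsorted(cum, t, side="right")) - 1
        j = min(j, len(seg) - 1)
        frac = (t - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        out[i] = pts[j] + frac * (pts[j + 1] - pts[j])
    return out


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def fit_plane(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (point_on_plane, unit normal)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    center = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - center)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("midline points are collinear: plane is degenerate")
    return center, Vt[2]


def reflect_through_plane(points: np.ndarray, origin: np.ndarray,
                          normal: np.ndarray) -> np.ndarray:
    d = (np.asarray(points) - origin) @ normal
    return points - 2.0 * d[:, None] * normal[None, :]


def mirror_fill(dataset: LandmarkDataset,
                midline_ids: Optional[Sequence[str]] = None) -> LandmarkDataset:
    """Add left-side points as reflections of right-side points.

    The reflection plane is fit per specimen, by least squares through the
    midline points.  Mirrored points carry side="mirrored_left" and point
    ids suffixed "__L".
    """
    if midline_ids is None:
        midline_ids = [pid for pid, s in zip(dataset.point_ids, dataset.side)
                       if s == "midline"]
    mid_idx = [dataset.point_index[p] for p in midline_ids]
    if len(mid_idx) < 3:
        raise ValueError("need at least 3 midline points to define the plane")
    right_idx = [i for i, s in enumerate(dataset.side) if s == "right"]
    if not right_idx:
        return dataset.copy()

    n = dataset.n_specimens
    mirrored = np.empty((n, len(right_idx), 3))
    for i in range(n):
        spec = dataset.coords[i]
        finite_mid = [j for j in mid_idx if np.all(np.isfinite(spec[j]))]
        if len(finite_mid) < 3:
            raise ValueError(
                f"specimen {dataset.specimen_ids[i]}: fewer than 3 finite midline points")
        origin, normal = fit_plane(spec[finite_mid])
        mirrored[i] = reflect_through_plane(spec[right_idx], origin, normal)

    new_ids = dataset.point_ids + [dataset.point_ids[j] + "__L" for j in right_idx]
    coords = np.concatenate([dataset.coords, mirrored], axis=1)
    roles = dataset.point_role + [dataset.point_role[j] for j in right_idx]
    sides = dataset.side + ["mirrored_left"] * len(right_idx)
    return LandmarkDataset(
        specimen_ids=list(dataset.specimen_ids), point_ids=new_ids, coords=coords,
        point_role=roles, side=sides,
        curves=[CurveSpec(c.curve_id, list(c.point_ids), c.anchor_start, c.anchor_end)
                for c in dataset.curves],
        missing={k: list(v) for k, v in dataset.missing.items()},
    )


# ---------------------------------------------------------------------------
# Missing-region encoding
# ---------------------------------------------------------------------------

def encode_missing_region(dataset: LandmarkDataset, specimen: str, region: str,
                          region_map: RegionMap,
                          anchor_point: Optional[str] = None) -> LandmarkDataset:
    """Collapse an absent region onto its anchor landmark for one specimen.

    Every point of the region is set to the anchor's coordinates before
    GPA, so the missing region is carried as an infinitesimal surface of
    the right dimensionality rather than dropped.
    """
    out = dataset.copy()
    si = out.specimen_index[specimen]
    anchor = anchor_point or region_map.anchor_of_region.get(region)
    if anchor is None:
        raise ValueError(f"no anchor landmark declared for region {region}")
    ai = out.point_index[anchor]
    if not np.all(np.isfinite(out.coords[si, ai])):
        raise ValueError(f"anchor {anchor} itself missing in specimen {specimen}")
    pts = region_map.points_in(region, out.point_ids)
    idx = [out.point_index[p] for p in pts]
    out.coords[si, idx, :] = out.coords[si, ai]
    out.missing.setdefault(specimen, [])
    if region not in out.missing[specimen]:
        out.missing[specimen].append(region)
    return out


def encode_all_missing(dataset: LandmarkDataset, region_map: RegionMap) -> LandmarkDataset:
    """Encode every flagged missing region of every specimen.

    If a region's declared anchor is itself missing in a specimen (its own
    region also absent), the first finite fixed landmark of the specimen is
    used instead.
    """
    out = dataset.copy()
    for specimen, regions in dataset.missing.items():
        si = out.specimen_index[specimen]
        for region in regions:
            anchor = region_map.anchor_of_region.get(region)
            if anchor is not None:
                ai = out.point_index[anchor]
                if not np.all(np.isfinite(out.coords[si, ai])):
                    anchor = next(
                        (pid for pid, role in zip(out.point_ids, out.point_role)
                         if role == "landmark"
                         and np.all(np.isfinite(out.coords[si, out.point_index[pid]]))),
                        None)
                    if anchor is None:
                        raise ValueError(
                            f"specimen {specimen}: no finite landmark available "
                            f"to anchor missing region {region}")
            out = encode_missing_region(out, specimen, region, region_map,
                                        anchor_point=anchor)
    return out


# ---------------------------------------------------------------------------
# Generalised Procrustes analysis
# ---------------------------------------------------------------------------

def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation of source onto target, det forced +1."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (translation,
    scale and rotation removed)."""
    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)
    a, b = norm(np.asarray(a, float)), norm(np.asarray(b, float))
    R = optimal_rotation(a, b)
    return float(np.linalg.norm(a @ R - b))


def gpa(dataset: LandmarkDataset, tol: float = 1e-9, max_iter: int = 200,
        record_objective: bool = False) -> AlignedShapes:
    """Iterative generalised Procrustes alignment.

    Each specimen is centred, scaled to unit centroid size and rotated to
    the current mean shape; the mean is recomputed until it changes by less
    than tol.  Centroid sizes are recorded before scaling.
    """
    X = np.array(dataset.coords, dtype=float)
    n, p, _ = X.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    if not np.all(np.isfinite(X)):
        bad = [dataset.specimen_ids[i] for i in range(n)
               if not np.all(np.isfinite(X[i]))]
        raise ValueError(
            f"non-finite coordinates (encode missing regions first): {bad[:5]}")

    sizes = np.empty(n)
    for i in range(n):
        X[i] -= X[i].mean(axis=0)
        sizes[i] = np.sqrt(np.sum(X[i] ** 2))
        if sizes[i] <= 0:
            raise ValueError(f"specimen {dataset.specimen_ids[i]} has zero size")
        X[i] /= sizes[i]

    mean = X[0].copy()
    mean /= np.linalg.norm(mean)
    objective: List[float] = []
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        nm = np.linalg.norm(new_mean)
        if nm <= 0:
            raise ValueError("degenerate mean shape")
        new_mean /= nm
        if record_objective:
            objective.append(float(np.sum((X - new_mean) ** 2)))
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge: last mean change {change:.3g}")

    prov = {"gpa_iterations": len(objective) if record_objective else None}
    if record_objective:
        prov["objective"] = objective
    return AlignedShapes(
        specimen_ids=list(dataset.specimen_ids), point_ids=list(dataset.point_ids),
        coords=X, centroid_size=sizes,
        point_role=list(dataset.point_role), side=list(dataset.side),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Sliding semilandmarks (bending-energy minimisation)
# ---------------------------------------------------------------------------

def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of a 3-D reference configuration.

    With the 3-D kernel U(r) = -r (the sign that makes the quadratic form
    positive semi-definite, vanishing exactly on affine deformations) the
    matrix is the top-left p x p block of the inverse of
    L = [[K, Q], [Q', 0]], Q = [1 | reference].  The TPS bending energy of
    a deformation with target coordinates y (one column per output
    dimension) is sum_d y_d' B y_d.
    """
    ref = np.asarray(reference, dtype=float)
    p = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r = np.sqrt(np.sum(diff ** 2, axis=2))
    off = r + np.eye(p)
    if np.any(off == 0):
        i, j = np.argwhere(off == 0)[0]
        raise ValueError(f"coincident reference points {i} and {j}: "
                         "bending-energy matrix singular")
    Q = np.hstack([np.ones((p, 1)), ref])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = -r
    L[:p, p:] = Q
    L[p:, :p] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("bending-energy matrix singular (degenerate reference)") from exc
    B = Linv[:p, :p]
    return (B + B.T) / 2.0


def tps_bending_energy(B: np.ndarray, config: np.ndarray) -> float:
    """Total bending energy sum_d y_d' B y_d of a configuration vs the
    reference that produced B."""
    y = np.asarray(config, dtype=float)
    return float(np.einsum("pd,pq,qd->", y, B, y))


def _curve_tangents(mean: np.ndarray, spec: SlidingSpec,
                    point_index: Dict[str, int]) -> Dict[int, np.ndarray]:
    """Unit tangent per sliding curve point: chord through its neighbours."""
    tangents: Dict[int, np.ndarray] = {}
    for curve in spec.curves:
        chain = list(curve.point_ids)
        if curve.anchor_start is not None:
            chain = [curve.anchor_start] + chain
        if curve.anchor_end is not None:
            chain = chain + [curve.anchor_end]
        idx = [point_index[pid] for pid in chain]
        slide_set = {point_index[pid] for pid in curve.point_ids}
        for k, i in enumerate(idx):
            if i not in slide_set:
                continue
            lo = idx[max(k - 1, 0)]
            hi = idx[min(k + 1, len(idx) - 1)]
            t = mean[hi] - mean[lo]
            nrm = np.linalg.norm(t)
            tangents[i] = t / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    return tangents


def _surface_tangent_planes(mean: np.ndarray, spec: SlidingSpec,
                            point_index: Dict[str, int]) -> Dict[int, np.ndarray]:
    """Two orthonormal tangent vectors per surface point, from local PCA of
    the k nearest reference points."""
    planes: Dict[int, np.ndarray] = {}
    p = mean.shape[0]
    k = min(spec.tangent_k, p - 1)
    d2 = np.sum((mean[:, None, :] - mean[None, :, :]) ** 2, axis=2)
    for pid in spec.surface_points:
        i = point_index[pid]
        nbr = np.argsort(d2[i])[1:k + 1]
        local = mean[nbr] - mean[nbr].mean(axis=0)
        _, _, Vt = np.linalg.svd(local, full_matrices=False)
        planes[i] = Vt[:2]
    return planes


def slide_pass(aligned: AlignedShapes, spec: SlidingSpec) -> AlignedShapes:
    """One bending-energy-minimising slide of all semilandmarks, against the
    current Procrustes mean, followed by re-centering (no GPA here)."""
    mean = aligned.mean_shape
    B = bending_energy_matrix(mean)
    pidx = aligned.point_index
    tangents = _curve_tangents(mean, spec, pidx)
    planes = _surface_tangent_planes(mean, spec, pidx)

    # free sliding directions: list of (point index, direction vector)
    directions: List[Tuple[int, np.ndarray]] = []
    for i, t in tangents.items():
        directions.append((i, t))
    for i, UV in planes.items():
        directions.append((i, UV[0]))
        directions.append((i, UV[1]))
    if not directions:
        return aligned

    m = len(directions)
    p = aligned.n_points
    # A_d[p, j]: effect of slide parameter j on coordinate d of point p
    A = np.zeros((3, p, m))
    for j, (i, v) in enumerate(directions):
        for d in range(3):
            A[d, i, j] = v[d]

    # normal equations of the quadratic energy in the slide parameters t:
    # (sum_d A_d' B A_d) t = -sum_d A_d' B y_d, solved per specimen
    G = sum(A[d].T @ B @ A[d] for d in range(3))
    coords = aligned.coords.copy()
    for s in range(aligned.n_specimens):
        y = coords[s]
        rhs = -sum(A[d].T @ (B @ y[:, d]) for d in range(3))
        t, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        disp = np.stack([A[d] @ t for d in range(3)], axis=1)
        before = tps_bending_energy(B, y)
        after = tps_bending_energy(B, y + disp)
        if after <= before + 1e-12:   # guard: exact minimiser can tie numerically
            coords[s] = y + disp
        coords[s] -= coords[s].mean(axis=0)
        nrm = np.sqrt(np.sum(coords[s] ** 2))
        coords[s] /= nrm
    out = AlignedShapes(
        specimen_ids=list(aligned.specimen_ids), point_ids=list(aligned.point_ids),
        coords=coords, centroid_size=aligned.centroid_size.copy(),
        point_role=list(aligned.point_role), side=list(aligned.side),
        provenance=dict(aligned.provenance),
    )
    return out


def _regpa(aligned: AlignedShapes) -> AlignedShapes:
    ds = LandmarkDataset(
        specimen_ids=list(aligned.specimen_ids), point_ids=list(aligned.point_ids),
        coords=aligned.coords, point_role=list(aligned.point_role),
        side=list(aligned.side),
    )
    out = gpa(ds)
    out.centroid_size = aligned.centroid_size.copy()  # keep original sizes
    out.provenance.update(aligned.provenance)
    return out


def slide(aligned: AlignedShapes, spec: SlidingSpec) -> AlignedShapes:
    """Iteratively slide semilandmarks and re-run GPA.

    Stops after spec.slide_iterations passes or when the maximum point
    displacement in a pass falls below spec.tolerance.
    """
    current = aligned
    for it in range(spec.slide_iterations):
        before = current.coords
        slid = slide_pass(current, spec)
        moved = float(np.max(np.linalg.norm(slid.coords - before, axis=2)))
        current = _regpa(slid)
        if moved < spec.tolerance:
            break
    current.provenance["slide_passes"] = it + 1
    return current


def superimpose(dataset: LandmarkDataset, region_map: Optional[RegionMap] = None,
                sliding: Optional[SlidingSpec] = None,
                midline_ids: Optional[Sequence[str]] = None,
                mirror: bool = True) -> AlignedShapes:
    """Full superimposition: encode missing, mirror, GPA, slide, drop mirrored."""
    ds = dataset
    if region_map is not None:
        # infer unflagged whole-region absences from all-NaN blocks (absences
        # survive a plain coordinate round trip only as NaNs)
        ds = ds.copy()
        for i, specimen in enumerate(ds.specimen_ids):
            flagged = set(ds.missing.get(specimen, []))
            for region in region_map.region_ids:
                idx = [ds.point_index[pid]
                       for pid in region_map.points_in(region, ds.point_ids)]
                if idx and region not in flagged and \
                        np.all(np.isnan(ds.coords[i, idx, :])):
                    ds.missing.setdefault(specimen, []).append(region)
        if ds.missing:
            ds = encode_all_missing(ds, region_map)
    if mirror:
        ds = mirror_fill(ds, midline_ids)
    aligned = gpa(ds)
    if sliding is None:
        sliding = SlidingSpec.from_dataset(dataset)
    if sliding.curves or sliding.surface_points:
        aligned = slide(aligned, sliding)
    if mirror:
        aligned = drop_mirrored(aligned)
    return aligned


def drop_mirrored(aligned: AlignedShapes) -> AlignedShapes:
    """Remove mirrored points after alignment; coordinates are untouched."""
    keep = [i for i, s in enumerate(aligned.side) if s != "mirrored_left"]
    return AlignedShapes(
        specimen_ids=list(aligned.specimen_ids),
        point_ids=[aligned.point_ids[i] for i in keep],
        coords=aligned.coords[:, keep, :].copy(),
        centroid_size=aligned.centroid_size.copy(),
        point_role=[aligned.point_role[i] for i in keep],
        side=[aligned.side[i] for i in keep],
        provenance=dict(aligned.provenance),
    )
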