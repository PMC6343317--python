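"""Core data containers shared across the analysis stages.

The containers are deliberately thin: a :class:`LandmarkDataset` is little
more than a labelled ``(specimen, point, 3)`` coordinate array with point
roles (fixed landmark, curve semilandmark, surface semilandmark), side
labels for bilateral structures, and a per-specimen record of which cranial
regions are absent.  All downstream statistics operate on
:class:`AlignedShapes`, the Procrustes-superimposed version of the same
array plus centroid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

POINT_ROLES = ("landmark", "curve_semilandmark", "surface_semilandmark")
SIDES = ("midline", "right", "mirrored_left")


@dataclass
class CurveSpec:
    """An ordered chain of curve semilandmarks anchored by fixed landmarks."""

    curve_id: str
    point_ids: List[str]          # in sliding order, rank 0..k-1
    anchor_start: Optional[str] = None
    anchor_end: Optional[str] = None


@dataclass
class LandmarkDataset:
    """Raw (unaligned) landmark/semilandmark coordinates for a set of specimens.

    coords has shape ``(n_specimens, n_points, 3)`` in an arbitrary but
    consistent length unit.  Coordinates of points that belong to a region
    flagged missing for a specimen may be NaN until the missing region is
    encoded (see :func:`morphomod.superimposition.encode_missing_region`).
    """

    specimen_ids: List[str]
    point_ids: List[str]
    coords: np.ndarray
    point_role: List[str] = field(default_factory=list)
    side: List[str] = field(default_factory=list)
    curves: List[CurveSpec] = field(default_factory=list)
    missing: Dict[str, List[str]] = field(default_factory=dict)  # specimen -> missing regions

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = len(self.specimen_ids), len(self.point_ids)
        if self.coords.shape != (n, p, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} specimens x {p} points x 3"
            )
        if not self.point_role:
            self.point_role = ["landmark"] * p
        if not self.side:
            self.side = ["right"] * p
        for role in self.point_role:
            if role not in POINT_ROLES:
                raise ValueError(f"unknown point role {role!r}")
        for s in self.side:
            if s not in SIDES:
                raise ValueError(f"unknown side label {s!r}")
        for curve in self.curves:
            missing = [pid for pid in curve.point_ids if pid not in self.point_index]
            if missing:
                raise ValueError(f"curve {curve.curve_id} references unknown points {missing}")

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def specimen_index(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.specimen_ids)}

    @property
    def point_index(self) -> Dict[str, int]:
        return {p: i for i, p in enumerate(self.point_ids)}

    def subset_points(self, point_ids: Sequence[str]) -> "LandmarkDataset":
        idx = [self.point_index[p] for p in point_ids]
        keep = set(point_ids)
        curves = [
            CurveSpec(c.curve_id, list(c.point_ids), c.anchor_start, c.anchor_end)
            for c in self.curves
            if all(pid in keep for pid in c.point_ids)
        ]
        return LandmarkDataset(
            specimen_ids=list(self.specimen_ids),
            point_ids=list(point_ids),
            coords=self.coords[:, idx, :].copy(),
            point_role=[self.point_role[i] for i in idx],
            side=[self.side[i] for i in idx],
            curves=curves,
            missing={k: list(v) for k, v in self.missing.items()},
        )

    def copy(self) -> "LandmarkDataset":
        return replace(
            self,
            specimen_ids=list(self.specimen_ids),
            point_ids=list(self.point_ids),
            coords=self.coords.copy(),
            point_role=list(self.point_role),
            side=list(self.side),
            curves=[CurveSpec(c.curve_id, list(c.point_ids), c.anchor_start, c.anchor_end)
                    for c in self.curves],
            missing={k: list(v) for k, v in self.missing.items()},
        )


@dataclass
class RegionMap:
    """Total mapping of analysed points to named regions.

    ``anchor_of_region`` optionally names, per region, the fixed landmark
    whose position stands in for the whole region when the region is absent
    in a specimen.
    """

    region_of_point: Dict[str, str]
    region_ids: List[str]
    anchor_of_region: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set(self.region_of_point.values())
        empties = [r for r in self.region_ids if r not in seen]
        if empties:
            raise ValueError(f"regions with no points: {empties}")
        unknown = seen - set(self.region_ids)
        if unknown:
            raise ValueError(f"points mapped to undeclared regions: {sorted(unknown)}")

    def points_in(self, region: str, point_ids: Sequence[str]) -> List[str]:
        """Points of `region`, in the order they appear in `point_ids`."""
        return [p for p in point_ids if self.region_of_point.get(p) == region]

    def validate_total(self, point_ids: Sequence[str]) -> None:
        missing = [p for p in point_ids if p not in self.region_of_point]
        if missing:
            raise ValueError(f"points without a region assignment: {missing[:10]}")


@dataclass
class TraitTable:
    """Per-specimen ecological covariates.

    fossoriality: five unordered categories 0-4 of presumed increasing
    degree of burrowing; aquatic: obligate vs non-obligate adults;
    reproduction: oviparous/viviparous (may be missing); life_history:
    direct/larval development (may be missing).
    """

    specimen_ids: List[str]
    fossoriality: Dict[str, int]
    aquatic: Dict[str, str]
    reproduction: Dict[str, Optional[str]]
    life_history: Dict[str, Optional[str]]

    def __post_init__(self) -> None:
        for s in self.specimen_ids:
            f = self.fossoriality.get(s)
            if f not in {0, 1, 2, 3, 4}:
                raise ValueError(f"fossoriality for {s} must be 0-4, got {f}")
            if self.aquatic.get(s) not in {"obligate", "non-obligate"}:
                raise ValueError(f"aquatic for {s} must be obligate/non-obligate")
            r = self.reproduction.get(s)
            if r is not None and r not in {"oviparous", "viviparous"}:
                raise ValueError(f"bad reproduction value {r!r} for {s}")
            lh = self.life_history.get(s)
            if lh is not None and lh not in {"direct", "larval"}:
                raise ValueError(f"bad life_history value {lh!r} for {s}")


@dataclass
class AnalysisConfig:
    """Run configuration for the full pipeline."""

    n_permutations: int = 1000
    n_sim_rates: int = 999
    n_sim_band: int = 100
    seed: int = 0
    jackknife_fraction: float = 0.10
    jackknife_iters: int = 100
    merge_threshold: float = 0.2
    slide_iterations: int = 3
    tolerance: float = 1e-6
    bh_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_permutations", "n_sim_rates", "n_sim_band", "jackknife_iters",
                     "slide_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.jackknife_fraction <= 1):
            raise ValueError("jackknife_fraction must be in (0, 1]")
        if self.merge_threshold < 0:
            raise ValueError("merge_threshold must be >= 0")


@dataclass
class AlignedShapes:
    """Procrustes-superimposed coordinates plus centroid sizes.

    coords are dimensionless shape variables; centroid_size keeps the
    pre-scaling size of each specimen in the input length unit.
    """

    specimen_ids: List[str]
    point_ids: List[str]
    coords: np.ndarray                      # (n, p, 3)
    centroid_size: np.ndarray               # (n,)
    point_role: List[str] = field(default_factory=list)
    side: List[str] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.centroid_size = np.asarray(self.centroid_size, dtype=float)
        n, p = len(self.specimen_ids), len(self.point_ids)
        if self.coords.shape != (n, p, 3):
            raise ValueError("coords shape mismatch")
        if self.centroid_size.shape != (n,):
            raise ValueError("centroid_size shape mismatch")
        if not self.point_role:
            self.point_role = ["landmark"] * p
        if not self.side:
            self.side = ["right"] * p

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def mean_shape(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def point_index(self) -> Dict[str, int]:
        return {p: i for i, p in enumerate(self.point_ids)}

    def flat(self) -> np.ndarray:
        """Specimens x (3 * points) matrix of flattened coordinates."""
        return self.coords.reshape(self.n_specimens, -1)

    def subset_points(self, point_ids: Sequence[str]) -> "AlignedShapes":
        """Restrict to a point subset without re-aligning (global alignment kept)."""
        idx = [self.point_index[p] for p in point_ids]
        return AlignedShapes(
            specimen_ids=list(self.specimen_ids),
            point_ids=list(point_ids),
            coords=self.coords[:, idx, :].copy(),
            centroid_size=self.centroid_size.copy(),
            point_role=[self.point_role[i] for i in idx],
            side=[self.side[i] for i in idx],
            provenance=dict(self.provenance),
        )


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered ** 2)))
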