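"""Superimposition: resampling, mirroring, GPA, sliding, missing regions."""

import numpy as np
import pytest

import morphomod as mm
from morphomod.datatypes import CurveSpec, LandmarkDataset, RegionMap, centroid_size
from morphomod.superimposition import (bending_energy_matrix, encode_all_missing,
                                       fit_plane, gpa, mirror_fill,
                                       resample_curve, slide_pass,
                                       tps_bending_energy)
from conftest import random_dataset


class TestResampleCurve:
    def test_straight_segment_equal_spacing(self):
        pts = np.array([[0, 0, 0], [10, 0, 0.0]])
        out = resample_curve(pts, 3)
        assert np.allclose(out[:, 0], [0, 5, 10])
        assert np.allclose(out[:, 1:], 0)

    def test_quarter_circle_arc_length_gaps(self):
        # oracle: equal arc-length spacing along a unit quarter circle
        theta = np.linspace(0, np.pi / 2, 100)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        out = resample_curve(pts, 5)
        angles = np.arctan2(out[:, 1], out[:, 0])
        gaps = np.diff(angles)
        assert np.allclose(gaps, (np.pi / 2) / 4, atol=2e-3)

    def test_endpoints_exact_and_on_curve(self, rng):
        pts = rng.standard_normal((20, 3)).cumsum(axis=0)
        out = resample_curve(pts, 7)
        assert np.array_equal(out[0], pts[0])
        assert np.array_equal(out[-1], pts[-1])
        # equal chord spacing in arc length along the input polyline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = seg.sum()
        # each output point lies on some input segment
        for q in out:
            d = np.linalg.norm(np.cross(np.diff(pts, axis=0),
                                        q[None, :] - pts[:-1]), axis=1) / seg
            t = np.einsum("ij,ij->i", np.diff(pts, axis=0), q[None, :] - pts[:-1]) / seg**2
            on = (d < 1e-9) & (t > -1e-9) & (t < 1 + 1e-9)
            assert on.any()

    def test_zero_length_curve_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_curve(np.zeros((3, 3)), 4)


class TestMirrorFill:
    def _dataset(self, right_coords):
        mid = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        coords = np.concatenate([mid, right_coords])[None, :, :]
        return LandmarkDataset(
            specimen_ids=["a"],
            point_ids=[f"m{i}" for i in range(3)] + [f"r{i}" for i in
                       range(len(right_coords))],
            coords=coords,
            side=["midline"] * 3 + ["right"] * len(right_coords),
        )

    def test_reflection_through_x_plane(self):
        ds = self._dataset(np.array([[1, 2, 3.0]]))
        out = mirror_fill(ds)
        assert out.side[-1] == "mirrored_left"
        assert np.allclose(out.coords[0, -1], [-1, 2, 3])

    def test_reflection_is_isometry(self, rng):
        right = rng.standard_normal((6, 3)) + [2, 0, 0]
        ds = self._dataset(right)
        out = mirror_fill(ds)
        refl = out.coords[0, -6:]
        orig_d = np.linalg.norm(right[:, None] - right[None, :], axis=2)
        refl_d = np.linalg.norm(refl[:, None] - refl[None, :], axis=2)
        assert np.allclose(orig_d, refl_d, atol=1e-12)

    def test_midline_points_are_fixed(self, rng):
        right = rng.standard_normal((4, 3)) + [1.5, 0, 0]
        ds = self._dataset(right)
        origin, normal = fit_plane(ds.coords[0, :3])
        from morphomod.superimposition import reflect_through_plane
        refl_mid = reflect_through_plane(ds.coords[0, :3], origin, normal)
        assert np.allclose(refl_mid, ds.coords[0, :3], atol=1e-10)

    def test_collinear_midline_errors(self):
        coords = np.array([[[0, 0, 0], [0, 0, 1], [0, 0, 2], [1, 0, 0.0]]])
        ds = LandmarkDataset(specimen_ids=["a"], point_ids=list("abcd"),
                             coords=coords,
                             side=["midline"] * 3 + ["right"])
        with pytest.raises(ValueError, match="collinear"):
            mirror_fill(ds)


class TestGPA:
    def test_similarity_invariance(self, rng):
        base = rng.standard_normal((6, 3))
        ds = random_dataset(rng, n=2, p=6)
        R = mm.synthetic_data.random_rotation(rng)
        ds.coords[0] = base
        ds.coords[1] = 2.5 * base @ R + np.array([4, -1, 7])
        aligned = gpa(ds)
        d = np.linalg.norm(aligned.coords[0] - aligned.coords[1])
        assert d < 1e-10

    def test_unit_square_centroid_size(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_alignment_invariants(self, rng):
        ds = random_dataset(rng, n=8, p=10)
        aligned = gpa(ds)
        for i in range(8):
            cfg = aligned.coords[i]
            assert np.linalg.norm(cfg.mean(axis=0)) < 1e-9
            assert abs(np.sqrt(np.sum(cfg ** 2)) - 1) < 1e-9

    def test_objective_monotone_nonincreasing(self, rng):
        ds = random_dataset(rng, n=10, p=12)
        aligned = gpa(ds, record_objective=True)
        obj = aligned.provenance["objective"]
        assert len(obj) >= 1
        assert all(b <= a + 1e-12 for a, b in zip(obj, obj[1:]))

    def test_invariant_to_specimen_order_and_rigid_pretransform(self, rng):
        ds = random_dataset(rng, n=6, p=9)
        a1 = gpa(ds)
        ds2 = ds.copy()
        perm = [3, 1, 5, 0, 4, 2]
        ds2.coords = ds2.coords[perm]
        ds2.specimen_ids = [ds.specimen_ids[i] for i in perm]
        R = mm.synthetic_data.random_rotation(rng)
        ds2.coords[2] = ds2.coords[2] @ R + 5.0
        a2 = gpa(ds2)
        # mean shapes agree up to a global rotation
        assert mm.procrustes_distance(a1.mean_shape, a2.mean_shape) < 1e-7


class TestSlide:
    def _curve_dataset(self, rng, n=6, jitter=0.0):
        """Fixed 3-D landmarks plus one sliding curve along a parabola."""
        anchors = np.array([[0, 0, 0], [10, 0, 0], [5, 5, 3], [2, -4, 1],
                            [8, 3, -2.0]])
        k = 7
        curve_ids = [f"c{i}" for i in range(k)]
        specs = []
        coords = np.empty((n, 5 + k, 3))
        for i in range(n):
            t = np.sort(rng.uniform(0.05, 0.95, k)) if jitter else \
                np.linspace(0.1, 0.9, k)
            curve = np.column_stack([10 * t, 2 * np.sin(np.pi * t),
                                     np.zeros_like(t)])
            coords[i, :5] = anchors + (jitter * 0.01) * rng.standard_normal((5, 3))
            coords[i, 5:] = curve
        ds = LandmarkDataset(
            specimen_ids=[f"s{i}" for i in range(n)],
            point_ids=[f"a{i}" for i in range(5)] + curve_ids,
            coords=coords,
            point_role=["landmark"] * 5 + ["curve_semilandmark"] * k,
            curves=[CurveSpec("curve0", curve_ids, "a0", "a1")],
        )
        return ds

    def test_identical_specimens_are_a_fixed_point(self, rng):
        ds = self._curve_dataset(rng, jitter=0.0)
        aligned = gpa(ds)
        spec = mm.SlidingSpec(curves=ds.curves)
        out = slide_pass(aligned, spec)
        assert np.allclose(out.coords, aligned.coords, atol=1e-9)

    def test_bending_energy_nonincreasing(self, rng):
        ds = self._curve_dataset(rng, jitter=1.0)
        aligned = gpa(ds)
        spec = mm.SlidingSpec(curves=ds.curves)
        B = bending_energy_matrix(aligned.mean_shape)
        before = [tps_bending_energy(B, aligned.coords[i]) for i in range(6)]
        out = slide_pass(aligned, spec)
        after = [tps_bending_energy(B, out.coords[i]) for i in range(6)]
        assert sum(after) <= sum(before) + 1e-12
        assert all(a <= b * 1.001 + 1e-12 for a, b in zip(after, before))

    def test_fixed_landmarks_never_move(self, rng):
        ds = self._curve_dataset(rng, jitter=1.0)
        aligned = gpa(ds)
        spec = mm.SlidingSpec(curves=ds.curves)
        out = slide_pass(aligned, spec)
        # landmarks never slide: their geometry changes only by the global
        # re-centering/rescaling of the whole configuration after the pass
        for i in range(6):
            a, b = aligned.coords[i, :5, :], out.coords[i, :5, :]
            da = np.linalg.norm(a[:, None] - a[None, :], axis=2)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=2)
            np.testing.assert_allclose(da / da.mean(), db / db.mean(), atol=1e-9)

    def test_coincident_reference_points_error(self):
        ref = np.zeros((4, 3))
        ref[2] = [1, 1, 1]
        ref[3] = [2, 0, 1]
        with pytest.raises(ValueError, match="[cC]oincident"):
            bending_energy_matrix(ref)


class TestMissingRegions:
    def test_encode_sets_anchor_coordinates(self, rng):
        ds = random_dataset(rng, n=3, p=8)
        rm = RegionMap(
            region_of_point={f"p{j}": ("A" if j < 5 else "B") for j in range(8)},
            region_ids=["A", "B"], anchor_of_region={"A": "p7"})
        out = mm.encode_missing_region(ds, "s1", "A", rm)
        block = out.coords[1, :5, :]
        assert np.allclose(block, out.coords[1, 7])
        assert centroid_size(block) == 0.0

    def test_missing_anchor_errors(self, rng):
        ds = random_dataset(rng, n=3, p=8)
        ds.coords[1, 7] = np.nan
        rm = RegionMap(
            region_of_point={f"p{j}": ("A" if j < 5 else "B") for j in range(8)},
            region_ids=["A", "B"], anchor_of_region={"A": "p7"})
        with pytest.raises(ValueError, match="anchor"):
            mm.encode_missing_region(ds, "s1", "A", rm)

    def test_encoded_region_negligible_after_gpa(self, rng):
        ds = random_dataset(rng, n=4, p=10)
        rm = RegionMap(
            region_of_point={f"p{j}": ("A" if j < 4 else "B") for j in range(10)},
            region_ids=["A", "B"], anchor_of_region={"A": "p9"})
        ds.coords[2, :4] = np.nan
        ds.missing = {"s2": ["A"]}
        enc = encode_all_missing(ds, rm)
        aligned = gpa(enc)
        extent = centroid_size(aligned.coords[2, :4, :])
        assert extent == 0.0  # pre-GPA coincident stays coincident under similarity
        full = centroid_size(aligned.coords[2])
        assert full > 0.5  # the rest of the configuration keeps its size


class TestDropMirrored:
    def test_counts_and_identity(self, rng):
        mid = 3; right = 10
        n_pts = mid + right
        ds = random_dataset(rng, n=4, p=n_pts)
        ds.side = ["midline"] * mid + ["right"] * right
        filled = mirror_fill(ds)
        aligned = gpa(filled)
        dropped = mm.drop_mirrored(aligned)
        assert dropped.n_points == mid + right
        keep = [i for i, s in enumerate(aligned.side) if s != "mirrored_left"]
        assert np.array_equal(dropped.coords, aligned.coords[:, keep, :])

    def test_study_scheme_point_count(self):
        # 53 landmarks + 687 curve + 729 surface on midline/right = 1469 kept
        sides = (["midline"] * 3 + ["right"] * 50
                 + ["right"] * 687 + ["right"] * 729
                 + ["mirrored_left"] * (50 + 687 + 729))
        kept = [s for s in sides if s != "mirrored_left"]
        assert len(kept) == 1469


def test_noise_free_specimens_recover_true_shapes(rng):
    cfg = mm.SimConfig(n_tips=8, regions=("A", "B"), points_per_region=(3, 4, 3),
                       true_partition={"A": "m1", "B": "m2"},
                       missing_region_prob=0.0, seed=5)
    sim = mm.simulate_modular_shapes(cfg)
    raw = mm.make_raw_specimens(sim, cfg)
    aligned = gpa(raw)
    for i in range(8):
        d = mm.procrustes_distance(aligned.coords[i], sim.aligned_truth[i])
        assert d < 1e-8
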