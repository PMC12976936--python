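"""Rigid registration, anatomical-frame decomposition, volumes and
surface distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tevgsim.anatomy import Centerline, GeometryError, VesselModel, loft_surface
from tevgsim.graft import DeviationSpec, apply_deviation, deviation_rotation
from tevgsim.metrics import (AnatomicalFrame, RigidTransform, build_frame,
                             decompose_deviation, enclosed_volume,
                             register_rigid, surface_distance)

from helpers import brute_force_hausdorff


def random_rigid(rng):
    r = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    return RigidTransform(r, rng.uniform(-20, 20, 3))


class TestRegisterRigid:
    def test_identity_for_identical_clouds(self, rng):
        pts = rng.normal(size=(50, 3))
        t = register_rigid(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-10)

    def test_known_transform_recovered(self, rng):
        pts = rng.normal(size=(200, 3)) * 10
        r = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        target = pts @ r.T + np.array([1.0, 2.0, 3.0])
        t = register_rigid(pts, target)
        angle_err = np.degrees(np.arccos(np.clip(
            (np.trace(t.rotation.T @ r) - 1) / 2, -1, 1)))
        assert angle_err < 0.01
        assert np.linalg.norm(t.translation - [1, 2, 3]) < 1e-6

    def test_three_point_case_beats_brute_force_search(self, rng):
        """Kabsch residual must not exceed the best residual found by a
        dense search over Euler-angle space."""
        src = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 3.0, 1.0]])
        true = random_rigid(rng)
        dst = true.apply(src) + rng.normal(scale=0.05, size=src.shape)
        t = register_rigid(src, dst)
        res_kabsch = np.sum((t.apply(src) - dst) ** 2)
        best = np.inf
        grid = np.linspace(-180, 180, 25)
        for a in grid:
            for b in np.linspace(-90, 90, 13):
                for c in grid:
                    r = Rotation.from_euler("XYZ", [a, b, c],
                                            degrees=True).as_matrix()
                    # optimal translation given r: match centroids
                    tr = dst.mean(0) - r @ src.mean(0)
                    best = min(best, np.sum((src @ r.T + tr - dst) ** 2))
        assert res_kabsch <= best + 1e-9

    def test_collinear_cloud_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(GeometryError):
            register_rigid(pts, pts + 1.0)

    def test_icp_refines_from_close_initial(self, rng):
        pts = rng.normal(size=(300, 3)) * 10
        r = Rotation.from_euler("y", 5, degrees=True).as_matrix()
        target = pts @ r.T + np.array([0.5, -0.3, 0.2])
        perm = rng.permutation(len(pts))
        t = register_rigid(pts, target[perm], correspondence="unknown")
        moved = t.apply(pts)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(target).query(moved)
        assert d.mean() < 1e-6

    def test_residual_invariant_under_common_rigid_motion(self, rng):
        src = rng.normal(size=(80, 3)) * 5
        dst = src + rng.normal(scale=0.1, size=src.shape)
        t0 = register_rigid(src, dst)
        res0 = np.sum((t0.apply(src) - dst) ** 2)
        g = random_rigid(rng)
        t1 = register_rigid(g.apply(src), g.apply(dst))
        res1 = np.sum((t1.apply(g.apply(src)) - g.apply(dst)) ** 2)
        assert res1 == pytest.approx(res0, rel=1e-9, abs=1e-12)


class TestAnatomicalFrame:
    def test_axes_orthonormal_right_handed(self):
        frame = build_frame(loop_points=np.random.default_rng(0).normal(size=(8, 3)))
        np.testing.assert_allclose(frame.axes.T @ frame.axes, np.eye(3),
                                   atol=1e-12)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-12)

    def test_origin_is_loop_centroid(self, rng):
        loop = rng.normal(size=(12, 3))
        frame = build_frame(loop_points=loop)
        np.testing.assert_allclose(frame.origin, loop.mean(axis=0), atol=1e-12)

    def test_invariant_to_loop_reordering(self, rng):
        loop = rng.normal(size=(12, 3))
        f1 = build_frame(loop_points=loop)
        f2 = build_frame(loop_points=loop[rng.permutation(12)])
        np.testing.assert_allclose(f1.origin, f2.origin, atol=1e-12)
        np.testing.assert_allclose(f1.axes, f2.axes)


class TestDecomposeDeviation:
    frame = AnatomicalFrame(origin=np.array([5.0, -2.0, 30.0]),
                            axes=np.eye(3))

    def test_pure_is_translation_of_largest_observed_magnitude(self):
        t = RigidTransform(np.eye(3), [0.0, 0.0, 6.9])
        report = decompose_deviation(t, self.frame, 100.0, 100.0)
        np.testing.assert_allclose(report.translation_mm, [0, 0, 6.9],
                                   atol=1e-12)
        np.testing.assert_allclose(report.rotation_deg, 0.0, atol=1e-12)

    def test_pure_lr_rotation_of_38_degrees(self):
        r = Rotation.from_euler("x", 38, degrees=True).as_matrix()
        # rotation about the frame origin: no origin displacement
        t = RigidTransform(r, self.frame.origin - r @ self.frame.origin)
        report = decompose_deviation(t, self.frame, 100.0, 100.0)
        np.testing.assert_allclose(report.rotation_deg, [38.0, 0, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(report.translation_mm, 0.0, atol=1e-9)

    def test_identity_reports_zero_and_unit_ratio(self):
        report = decompose_deviation(RigidTransform.identity(), self.frame,
                                     123.0, 123.0)
        np.testing.assert_allclose(report.translation_mm, 0.0)
        np.testing.assert_allclose(report.rotation_deg, 0.0)
        assert report.volume_ratio == 1.0

    def test_gimbal_degenerate_flagged(self):
        r = Rotation.from_euler("XYZ", [10.0, 90.0, 20.0],
                                degrees=True).as_matrix()
        t = RigidTransform(r, np.zeros(3))
        report = decompose_deviation(t, AnatomicalFrame(np.zeros(3), np.eye(3)),
                                     1.0, 1.0)
        assert report.gimbal_degenerate

    def test_round_trip_with_apply_deviation(self, study_case, rng):
        """Decomposing an applied deviation recovers it away from gimbal
        lock."""
        graft, plane = study_case.graft, study_case.plane
        origin = graft.surface.nodes[
            graft.surface.boundary_loops[graft.proximal_loop]].mean(axis=0)
        frame = AnatomicalFrame(origin, np.eye(3))
        for _ in range(20):
            spec = DeviationSpec(
                translation_mm=rng.uniform(-6, 6, 3),
                rotation_deg=rng.uniform(-60, 60, 3))
            out, _ = apply_deviation(graft, plane, spec)
            transform = RigidTransform.from_matrix(out.design_pose)
            report = decompose_deviation(transform, frame, 1.0, 1.0)
            np.testing.assert_allclose(report.rotation_deg, spec.rotation_deg,
                                       atol=1e-4)
            np.testing.assert_allclose(report.translation_mm,
                                       spec.translation_mm, atol=1e-6)


class TestEnclosedVolume:
    def test_cylinder_volume(self, cylinder):
        assert enclosed_volume(cylinder) == pytest.approx(np.pi * 1e4,
                                                          rel=0.02)

    def test_scaling_is_cubic(self, cylinder, rng):
        from tevgsim.anatomy import scale_uniform
        s = rng.uniform(0.7, 1.3)
        assert enclosed_volume(scale_uniform(cylinder, s)) == pytest.approx(
            s ** 3 * enclosed_volume(cylinder), rel=1e-9)

    def test_rigid_invariance(self, cylinder, rng):
        v0 = enclosed_volume(cylinder)
        g = random_rigid(rng)
        moved = cylinder.copy()
        moved.nodes = g.apply(cylinder.nodes)
        assert enclosed_volume(moved) == pytest.approx(v0, rel=1e-9)


def flat_patch(offset_z=0.0, n=6, size=10.0):
    """Square flat quad patch in a z = const plane."""
    xs = np.linspace(0, size, n + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(),
                             np.full(xx.size, offset_z)])
    idx = np.arange((n + 1) ** 2).reshape(n + 1, n + 1)
    quads = np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                             idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()])
    return VesselModel(nodes=nodes, quads=quads,
                       region_tags=np.array(["patch"] * len(quads)),
                       boundary_loops={})


class TestSurfaceDistance:
    def test_identical_surfaces_have_zero_distance(self, cylinder):
        report = surface_distance(cylinder, cylinder, n_samples=500, seed=3)
        assert report.hausdorff_mm == pytest.approx(0.0, abs=1e-9)
        assert report.mean_surface_distance_mm == pytest.approx(0.0, abs=1e-9)

    def test_parallel_patches_report_their_offset(self):
        a, b = flat_patch(0.0), flat_patch(2.5)
        report = surface_distance(a, b, n_samples=2000, seed=0)
        assert report.hausdorff_mm == pytest.approx(2.5, abs=1e-9)
        assert report.mean_surface_distance_mm == pytest.approx(2.5, abs=1e-9)

    def test_vertex_mode_matches_brute_force(self, rng):
        for _ in range(10):
            na, nb = rng.integers(20, 120, size=2)
            a = flat_patch(0.0, n=3)
            b = flat_patch(1.0, n=3)
            a.nodes = rng.normal(size=(len(a.nodes), 3)) * 5
            b.nodes = rng.normal(size=(len(b.nodes), 3)) * 5 + 1.0
            report = surface_distance(a, b, mode="vertex")
            oracle = brute_force_hausdorff(a.nodes, b.nodes)
            assert report.hausdorff_mm == oracle["hausdorff"]
            assert report.mean_surface_distance_mm == pytest.approx(
                oracle["mean"], rel=1e-12)

    def test_monotone_in_rigid_offset(self, cylinder):
        prev = 0.0
        for dz in (1.0, 2.0, 4.0):
            moved = cylinder.copy()
            moved.nodes = cylinder.nodes + np.array([0, 0, dz])
            rep = surface_distance(cylinder, moved, n_samples=1000, seed=0)
            assert rep.mean_surface_distance_mm > prev
            prev = rep.mean_surface_distance_mm

    def test_hausdorff_is_max_of_directed(self, cylinder, rng):
        moved = cylinder.copy()
        moved.nodes = cylinder.nodes * 1.1
        rep = surface_distance(cylinder, moved, n_samples=800, seed=1)
        assert rep.hausdorff_mm == max(rep.directed_max_ab,
                                       rep.directed_max_ba)
        assert rep.hausdorff_mm >= rep.mean_surface_distance_mm >= 0
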