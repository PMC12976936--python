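"""Resection-plane placement, graft construction and placement deviations."""

import numpy as np
import pytest

from tevgsim.anatomy import GeometryError
from tevgsim.graft import (DeviationSpec, apply_deviation, design_graft,
                           deviation_rotation, place_resection_planes, resect,
                           sample_deviation_thresholds)
from tevgsim.metrics import enclosed_volume, surface_distance

from helpers import fit_circle_radius


def element_area(model, mask=None):
    tris = model.nodes[model.triangles()]
    a = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
    return a.sum()


class TestResectionPlanes:
    def test_parallel_planes_on_cylinder(self, cylinder):
        p1, p2 = place_resection_planes(cylinder, 30.0, 70.0)
        assert np.dot(p1.normal, p2.normal) == pytest.approx(1.0, abs=1e-9)
        gap = abs(np.dot(p2.origin - p1.origin, p1.normal))
        assert gap == pytest.approx(40.0, abs=1e-9)

    def test_normal_aligned_with_tangent(self, one_branch_aorta):
        cl = one_branch_aorta.centerline
        for s in (40.0, 80.0):
            (plane,) = place_resection_planes(one_branch_aorta, s,
                                              s + 20.0)[:1]
            assert np.dot(plane.normal, cl.tangent_at(s)) == pytest.approx(
                1.0, abs=1e-9)

    def test_plane_between_branches_separates_them(self, branched_aorta):
        """Signed-distance classification: with the proximal plane between
        the two ostia, branch 1 lies on the negative side and branch 2 on
        the positive side."""
        s1 = branched_aorta.structure["branch_1"].attach_arclength
        s2 = branched_aorta.structure["branch_2"].attach_arclength
        s_mid = 0.5 * (s1 + s2)
        p1, _ = place_resection_planes(branched_aorta, s_mid, s2 + 15.0)
        cents = branched_aorta.element_centroids()
        d = p1.signed_distance(cents)
        b1 = branched_aorta.region_tags == "branch_1"
        b2 = branched_aorta.region_tags == "branch_2"
        assert np.all(d[b1] < 0) and np.all(d[b2] > 0)

    def test_out_of_range_station_rejected(self, cylinder):
        with pytest.raises(GeometryError):
            place_resection_planes(cylinder, -5.0, 50.0)
        with pytest.raises(GeometryError):
            place_resection_planes(cylinder, 70.0, 30.0)

    def test_plane_through_ostium_rejected(self, one_branch_aorta):
        s_b = one_branch_aorta.structure["branch_1"].attach_arclength
        with pytest.raises(GeometryError, match="ostium"):
            place_resection_planes(one_branch_aorta, s_b, s_b + 30.0)


class TestResect:
    def test_element_count_and_area_conserved(self, cylinder):
        planes = place_resection_planes(cylinder, 30.0, 70.0)
        remnant, resected = resect(cylinder, planes)
        assert remnant.n_elements + resected.n_elements == cylinder.n_elements
        total = element_area(remnant) + element_area(resected)
        assert total == pytest.approx(element_area(cylinder), rel=0.01)

    def test_resected_lateral_area(self, cylinder):
        planes = place_resection_planes(cylinder, 30.0, 70.0)
        _, resected = resect(cylinder, planes)
        assert element_area(resected) == pytest.approx(
            2 * np.pi * 10.0 * 40.0, rel=0.02)

    def test_mating_loops_have_equal_node_counts(self, one_branch_aorta):
        planes = place_resection_planes(one_branch_aorta, 40.0, 75.0)
        remnant, resected = resect(one_branch_aorta, planes)
        assert len(remnant.boundary_loops["cut_prox"]) == \
            len(resected.boundary_loops["prox"])
        assert len(remnant.boundary_loops["cut_dist"]) == \
            len(resected.boundary_loops["dist"])

    def test_branch_inside_interval_is_cut(self, one_branch_aorta):
        planes = place_resection_planes(one_branch_aorta, 40.0, 75.0)
        remnant, resected = resect(one_branch_aorta, planes)
        assert "cut_branch_1" in remnant.boundary_loops
        assert "branch_1_cut" in resected.boundary_loops
        assert "outlet_branch_1" in remnant.boundary_loops

    def test_planes_outside_mesh_rejected(self, cylinder):
        from tevgsim.graft import CutPlane
        p_out = CutPlane.from_origin_normal((0, 0, -20.0), (0, 0, 1.0),
                                            station_arclength=-20.0)
        p_in = CutPlane.from_origin_normal((0, 0, 50.0), (0, 0, 1.0),
                                           station_arclength=50.0)
        with pytest.raises(GeometryError):
            resect(cylinder, (p_out, p_in))


@pytest.fixture(scope="module")
def cut(one_branch_aorta):
    planes = place_resection_planes(one_branch_aorta, 40.0, 75.0)
    return resect(one_branch_aorta, planes)


@pytest.fixture(scope="module")
def graft_and_plane(one_branch_aorta):
    planes = place_resection_planes(one_branch_aorta, 40.0, 75.0)
    remnant, resected = resect(one_branch_aorta, planes)
    return design_graft(resected, branched=True), planes[0]


class TestDesignGraft:
    def test_identity_design_matches_native_loops(self, cut):
        remnant, resected = cut
        graft = design_graft(resected, 1.0, branched=True,
                             native_remnant=remnant)
        for loop in ("prox", "dist"):
            g = graft.surface.nodes[graft.surface.boundary_loops[loop]]
            n = resected.nodes[resected.boundary_loops[loop]]
            np.testing.assert_allclose(g, n, atol=1e-6)

    def test_branched_flag_controls_loop_count(self, cut):
        _, resected = cut
        assert len(design_graft(resected, branched=True).loop_names()) == 3
        assert len(design_graft(resected, branched=False).loop_names()) == 2

    def test_diameter_scale_recovered_by_circle_fit(self, cut):
        _, resected = cut
        graft = design_graft(resected, 1.1)
        rings = graft.surface.structure["main"].rings
        mid = graft.surface.nodes[rings[len(rings) // 2]]
        native_mid = resected.nodes[
            resected.structure["main"].rings[len(rings) // 2]]
        c = mid.mean(axis=0)
        r_g = np.linalg.norm(mid - c, axis=1).mean()
        r_n = np.linalg.norm(native_mid - native_mid.mean(axis=0),
                             axis=1).mean()
        assert r_g / r_n == pytest.approx(1.1, rel=0.01)

    def test_branched_without_stub_rejected(self, cylinder):
        planes = place_resection_planes(cylinder, 30.0, 70.0)
        _, resected = resect(cylinder, planes)
        with pytest.raises(GeometryError):
            design_graft(resected, branched=True)


class TestApplyDeviation:
    def test_zero_deviation_is_bitwise_identity(self, graft_and_plane):
        graft, plane = graft_and_plane
        out, out_plane = apply_deviation(graft, plane, DeviationSpec())
        assert out is graft and out_plane is plane

    def test_full_turn_recovers_coordinates(self, graft_and_plane):
        graft, plane = graft_and_plane
        for axis in range(3):
            rot = np.zeros(3)
            rot[axis] = 360.0
            out, _ = apply_deviation(graft, plane,
                                     DeviationSpec(rotation_deg=rot))
            np.testing.assert_allclose(out.surface.nodes, graft.surface.nodes,
                                       atol=1e-9)

    def test_is_translation_moves_graft_not_plane(self, graft_and_plane):
        """The largest displacement observed in vivo, 6.9 mm, applied
        inferior-superior: the plane must not move."""
        graft, plane = graft_and_plane
        dev = DeviationSpec(translation_mm=(0.0, 0.0, 6.9))
        out, out_plane = apply_deviation(graft, plane, dev)
        np.testing.assert_allclose(
            out.surface.nodes - graft.surface.nodes,
            np.broadcast_to([0.0, 0.0, 6.9], graft.surface.nodes.shape),
            atol=1e-12)
        np.testing.assert_allclose(out_plane.origin, plane.origin, atol=1e-12)
        np.testing.assert_allclose(out_plane.normal, plane.normal, atol=1e-12)

    def test_lr_translation_moves_plane(self, graft_and_plane):
        graft, plane = graft_and_plane
        dev = DeviationSpec(translation_mm=(3.0, 0.0, 0.0))
        _, out_plane = apply_deviation(graft, plane, dev)
        np.testing.assert_allclose(out_plane.origin - plane.origin,
                                   [3.0, 0.0, 0.0], atol=1e-12)

    def test_rigid_composition_is_a_group_action(self, graft_and_plane):
        graft, plane = graft_and_plane
        dev_a = DeviationSpec(translation_mm=(1.0, -2.0, 3.0),
                              rotation_deg=(10.0, 0.0, -5.0))
        dev_b = DeviationSpec(translation_mm=(-0.5, 1.5, 0.0),
                              rotation_deg=(0.0, 15.0, 5.0))
        g1, p1 = apply_deviation(graft, plane, dev_a)
        g2, _ = apply_deviation(g1, p1, dev_b)
        # composite affine map applied to the original nodes
        m = g2.design_pose
        expect = graft.surface.nodes @ m[:3, :3].T + m[:3, 3]
        np.testing.assert_allclose(g2.surface.nodes, expect, atol=1e-9)

    def test_scaled_volume_is_cubic(self, graft_and_plane):
        graft, plane = graft_and_plane
        v0 = enclosed_volume(graft.surface)
        out, _ = apply_deviation(graft, plane, DeviationSpec(scale=1.15))
        assert enclosed_volume(out.surface) / v0 == pytest.approx(
            1.15 ** 3, rel=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(GeometryError):
            DeviationSpec(scale=0.0)


class TestRoundTripShape:
    def test_resect_and_identity_design_reproduce_the_aorta(
            self, one_branch_aorta):
        from tevgsim.pipeline import _merged_surface
        planes = place_resection_planes(one_branch_aorta, 40.0, 75.0)
        remnant, resected = resect(one_branch_aorta, planes)
        graft = design_graft(resected, 1.0, branched=True,
                             native_remnant=remnant)
        rebuilt = _merged_surface(remnant, graft)
        report = surface_distance(rebuilt, one_branch_aorta,
                                  n_samples=2000, seed=0)
        assert report.mean_surface_distance_mm < 0.5


class TestDeviationThresholds:
    def test_two_observations_hand_arithmetic(self):
        obs = [DeviationSpec(translation_mm=(1.0, 0, 0)),
               DeviationSpec(translation_mm=(3.0, 0, 0))]
        rng = sample_deviation_thresholds(obs)
        lo, hi = rng["translation_mm"]["L-R"]
        assert lo == pytest.approx(2 - 2 * np.sqrt(2))
        assert hi == pytest.approx(2 + 2 * np.sqrt(2))

    def test_identical_observations_are_degenerate(self):
        obs = [DeviationSpec(rotation_deg=(2.0, 0, 0))] * 3
        rng = sample_deviation_thresholds(obs)
        assert rng["rotation_deg"]["L-R"] == pytest.approx((2.0, 2.0))

    def test_symmetric_observations_give_symmetric_range(self):
        obs = [DeviationSpec(translation_mm=(0, v, 0))
               for v in (-3.0, -1.0, 1.0, 3.0)]
        lo, hi = sample_deviation_thresholds(obs)["translation_mm"]["A-P"]
        assert lo == pytest.approx(-hi)

    def test_single_observation_rejected(self):
        with pytest.raises(GeometryError):
            sample_deviation_thresholds([DeviationSpec()])
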