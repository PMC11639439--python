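"""Personalized coordinate frame: head sphere, axes, plane, landmark, crop."""

import numpy as np
import pytest
import trimesh

from femuratlas.core import Axis
from femuratlas.frame import (UnreliableFitError, crop_distal,
                              detect_lesser_trochanter, estimate_frame,
                              estimate_neck_axis, estimate_shaft_axis,
                              fit_head_sphere, mirror_left,
                              place_cutting_plane, refine_axes,
                              volume_above_lt)


def _angle_deg(u, v):
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return np.degrees(np.arccos(min(1.0, c)))


class TestHeadSphere:
    def test_exact_sphere_recovered_to_tenth_millimetre(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=24.0)
        mesh.apply_translation([10.0, -5.0, 30.0])
        c, r, rms = fit_head_sphere(mesh)
        assert np.linalg.norm(c - [10.0, -5.0, 30.0]) < 0.1
        assert abs(r - 24.0) < 0.1
        assert rms < 0.05

    def test_noisy_hemisphere_radius_within_two_percent(self):
        rng = np.random.default_rng(4)
        full = trimesh.creation.icosphere(subdivisions=4, radius=24.0)
        keep = full.vertices[:, 2] > 1.0
        faces = full.faces[np.all(keep[full.faces], axis=1)]
        hemi = trimesh.Trimesh(vertices=full.vertices.copy(), faces=faces,
                               process=True)
        hemi.vertices += rng.normal(0.0, 0.2, size=hemi.vertices.shape)
        seed = hemi.vertices[np.argmax(hemi.vertices[:, 2])]
        c, r, _ = fit_head_sphere(hemi, seed_point=seed)
        assert abs(r - 24.0) / 24.0 < 0.02

    def test_planar_mesh_is_an_unreliable_fit(self):
        grid = trimesh.creation.box(extents=[50.0, 50.0, 0.01])
        with pytest.raises(UnreliableFitError):
            fit_head_sphere(grid, seed_point=grid.vertices[0])

    def test_phantom_head_center_within_one_millimetre(self, ref_case,
                                                       ref_frame):
        _, _, truth = ref_case
        assert np.linalg.norm(ref_frame.head_center - truth.head_center) < 1.0
        assert abs(ref_frame.head_radius - truth.head_radius) < 1.0


class TestShaftAxis:
    def test_ideal_cylinder_direction_within_one_degree(self):
        cyl = trimesh.creation.cylinder(radius=14.0, height=120.0,
                                        sections=64)
        axis = estimate_shaft_axis(cyl)
        assert _angle_deg(axis.direction, [0, 0, 1]) < 1.0

    def test_tilted_cylinder_same_accuracy(self):
        cyl = trimesh.creation.cylinder(radius=14.0, height=120.0,
                                        sections=64)
        T = trimesh.transformations.rotation_matrix(np.deg2rad(30.0),
                                                    [1.0, 0.3, 0.0])
        cyl.apply_transform(T)
        truth_dir = T[:3, :3] @ np.array([0.0, 0.0, 1.0])
        axis = estimate_shaft_axis(cyl)
        assert _angle_deg(axis.direction, truth_dir) < 1.0

    def test_phantom_axis_within_three_degrees(self, ref_case, ref_frame):
        _, _, truth = ref_case
        assert _angle_deg(ref_frame.shaft_axis.direction,
                          truth.shaft_axis.direction) < 3.0

    def test_too_small_mesh_raises(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]], process=False)
        with pytest.raises(UnreliableFitError):
            estimate_shaft_axis(tri)


class TestNeckAxis:
    def test_phantom_axis_within_three_degrees(self, ref_case, ref_frame):
        _, _, truth = ref_case
        assert _angle_deg(ref_frame.neck_axis.direction,
                          truth.neck_axis.direction) < 3.0

    def test_stable_under_head_center_perturbation(self, ref_case, ref_frame):
        _, _, truth = ref_case
        shaft = estimate_shaft_axis(truth.outer_mesh)
        a1 = estimate_neck_axis(truth.outer_mesh, ref_frame.head_center,
                                ref_frame.head_radius, shaft)
        a2 = estimate_neck_axis(truth.outer_mesh, truth.head_center,
                                truth.head_radius, shaft)
        assert _angle_deg(a1.direction, a2.direction) < 1.0

    def test_degenerate_sphere_mesh_raises(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=24.0)
        with pytest.raises(UnreliableFitError):
            estimate_neck_axis(sphere, np.zeros(3), 24.0, None)

    def test_refined_axes_intersect_exactly(self, ref_frame):
        from femuratlas.frame import _closest_approach
        _, _, gap = _closest_approach(ref_frame.neck_axis,
                                      ref_frame.shaft_axis)
        assert gap < 1e-6


class TestCuttingPlane:
    def _stepped_cylinder(self, r1=10.0, r2=16.0):
        a = trimesh.creation.cylinder(radius=r1, height=40.0, sections=48)
        a.apply_translation([0, 0, 20.0])
        b = trimesh.creation.cylinder(radius=r2, height=30.0, sections=48)
        b.apply_translation([0, 0, 55.0])
        return trimesh.util.concatenate([a, b])

    def test_plane_lands_before_the_area_jump(self):
        mesh = self._stepped_cylinder()
        axis = Axis([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        plane, fallback = place_cutting_plane(mesh, axis, threshold=0.15,
                                              step_mm=3.0)
        assert not fallback
        t = axis.project(plane.point)
        assert t <= 40.0 + 3.0  # at or before the step, never after

    def test_flat_profile_raises_fallback_flag(self):
        cyl = trimesh.creation.cylinder(radius=12.0, height=80.0, sections=48)
        cyl.apply_translation([0, 0, 40.0])
        axis = Axis([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        plane, fallback = place_cutting_plane(cyl, axis)
        assert fallback

    def test_phantom_plane_between_head_and_trochanter(self, ref_case,
                                                       ref_frame):
        _, _, truth = ref_case
        t = ref_frame.neck_axis.project(ref_frame.cutting_plane.point)
        t_junction = ref_frame.neck_axis.project(truth.shaft_axis.point)
        assert truth.head_radius < t < t_junction
        # plane normal parallel to neck axis by construction
        assert abs(ref_frame.cutting_plane.normal
                   @ ref_frame.neck_axis.direction) > 0.999


class TestLesserTrochanterAndCrop:
    def test_phantom_landmark_within_two_millimetres(self, ref_case,
                                                     ref_frame):
        _, _, truth = ref_case
        assert np.linalg.norm(ref_frame.lesser_trochanter
                              - truth.lesser_trochanter) < 2.0

    def test_crop_offset_scales_with_cube_root_of_volume(self, ref_case,
                                                         ref_frame):
        _, _, truth = ref_case
        lt = ref_frame.lesser_trochanter
        shaft = ref_frame.shaft_axis
        c1, f1 = crop_distal(truth.outer_mesh, shaft, lt, 1000.0, scale=0.1)
        c8, f8 = crop_distal(truth.outer_mesh, shaft, lt, 8000.0, scale=0.1)
        t_lt = shaft.project(lt)
        assert (c8 - t_lt) == pytest.approx(2.0 * (c1 - t_lt))
        assert not f1 and not f8

    def test_crop_beyond_mesh_is_clamped_and_flagged(self, ref_case,
                                                     ref_frame):
        _, _, truth = ref_case
        crop, flagged = crop_distal(truth.outer_mesh, ref_frame.shaft_axis,
                                    ref_frame.lesser_trochanter, 1e9)
        assert flagged
        t_max = ref_frame.shaft_axis.project(
            np.asarray(truth.outer_mesh.vertices)).max()
        assert crop == pytest.approx(t_max)

    def test_non_positive_volume_rejected(self, ref_case, ref_frame):
        _, _, truth = ref_case
        with pytest.raises(ValueError):
            crop_distal(truth.outer_mesh, ref_frame.shaft_axis,
                        ref_frame.lesser_trochanter, 0.0)


class TestMirror:
    def test_mirror_twice_is_identity(self, ref_case):
        _, mask, truth = ref_case
        m2 = mirror_left(mirror_left(truth.outer_mesh))
        np.testing.assert_allclose(m2.vertices, truth.outer_mesh.vertices)
        np.testing.assert_array_equal(m2.faces, truth.outer_mesh.faces)
        v2 = mirror_left(mirror_left(mask))
        np.testing.assert_array_equal(v2.data, mask.data)
        np.testing.assert_allclose(v2.origin, mask.origin)

    def test_normals_stay_outward(self, ref_case):
        _, _, truth = ref_case
        assert mirror_left(truth.outer_mesh).volume > 0

    def test_unknown_side_rejected(self, ref_case):
        _, _, truth = ref_case
        with pytest.raises(ValueError):
            mirror_left(truth.outer_mesh, side="both")

    def test_mirrored_left_frame_matches_right_template(self, ref_params,
                                                        ref_geometry,
                                                        ref_maps, ref_frame):
        from femuratlas.synthetic import SubjectRecord, build_femur
        subjL = SubjectRecord("L", 50.0, 25.0, "female", "left")
        _, maskL, truthL = build_femur(ref_params, subjL, ref_maps, 0,
                                       geometry=ref_geometry)
        frameL = estimate_frame(mirror_left(truthL.outer_mesh),
                                mirror_left(maskL))
        assert np.linalg.norm(frameL.head_center - ref_frame.head_center) < 1e-6
        assert _angle_deg(frameL.neck_axis.direction,
                          ref_frame.neck_axis.direction) < 1e-6


class TestRigidEquivariance:
    def test_frame_transforms_with_the_mesh(self, ref_case, ref_frame):
        _, _, truth = ref_case
        T = trimesh.transformations.rotation_matrix(
            0.6, [0.2, 1.0, 0.5], point=[15.0, -10.0, 40.0])
        R, t = T[:3, :3], T[:3, 3]
        moved = truth.outer_mesh.copy()
        moved.apply_transform(T)
        f2 = estimate_frame(moved)
        assert np.linalg.norm(f2.head_center
                              - (R @ ref_frame.head_center + t)) < 0.2
        for ax in ("neck_axis", "shaft_axis"):
            assert _angle_deg(getattr(f2, ax).direction,
                              R @ getattr(ref_frame, ax).direction) < 0.5
        assert np.linalg.norm(
            f2.lesser_trochanter
            - (R @ ref_frame.lesser_trochanter + t)) < 0.2


class TestVolumeAboveLT:
    def test_counts_only_proximal_mask(self, ref_case, ref_frame):
        _, mask, _ = ref_case
        v_all = mask.data.sum() * mask.voxel_volume
        v_above = volume_above_lt(mask, ref_frame.shaft_axis,
                                  ref_frame.lesser_trochanter)
        assert 0 < v_above < v_all
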