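"""Sphere-averaged BMD sampling with dismissal and removal rules."""

import numpy as np
import pandas as pd
import pytest

from femuratlas.calibration import CalibratedVolume
from femuratlas.core import Volume
from femuratlas.sampling import (MIN_VOXELS_PER_SPHERE, filter_points,
                                 sample_case, sphere_average,
                                 sphere_overlap_fraction, sphere_radius)


def _brute_force_mean(cal: CalibratedVolume, center, radius):
    """Exhaustive oracle: enumerate every voxel of the whole grid."""
    vol = cal.bmd
    axes = vol.axes_world()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    d2 = ((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    inside = (d2 <= radius ** 2) & (np.asarray(cal.femur_mask.data) > 0)
    n = int(inside.sum())
    return (float(vol.data[inside].mean()) if n else float("nan")), n


def _random_calibrated(shape=(24, 20, 16), spacing=(1.0, 1.2, 0.8), seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(300.0, 60.0, size=shape)
    mask = (rng.random(shape) > 0.3).astype(np.uint8)
    return CalibratedVolume(Volume(data, spacing, (0.0, 0.0, 0.0)),
                            Volume(mask, spacing, (0.0, 0.0, 0.0)))


class TestSphereRadius:
    def test_reference_volume_gives_reference_radius(self):
        assert sphere_radius(12345.0, 12345.0) == pytest.approx(1.5)

    def test_cube_root_scaling(self):
        assert sphere_radius(8.0 * 999.0, 999.0) == pytest.approx(3.0)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            sphere_radius(0.0, 100.0)
        with pytest.raises(ValueError):
            sphere_radius(100.0, -1.0)


class TestSphereAverage:
    def test_constant_field_mean_is_the_constant(self):
        cal = CalibratedVolume(
            Volume(np.full((10, 10, 10), 7.5), (1, 1, 1), (0, 0, 0)),
            Volume(np.ones((10, 10, 10)), (1, 1, 1), (0, 0, 0)))
        res = sphere_average(cal, [5.0, 5.0, 5.0], 2.5)
        assert not res.dismissed
        assert res.mean_bmd == 7.5

    def test_constant_field_mean_survives_mask_clipping(self):
        data = np.full((10, 10, 10), 7.5)
        mask = np.zeros((10, 10, 10))
        mask[:5] = 1.0
        cal = CalibratedVolume(Volume(data, (1, 1, 1), (0, 0, 0)),
                               Volume(mask, (1, 1, 1), (0, 0, 0)))
        res = sphere_average(cal, [4.6, 5.0, 5.0], 3.0)
        assert not res.dismissed
        assert res.mean_bmd == 7.5

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        cal = _random_calibrated(seed=seed)
        for _ in range(20):
            center = rng.uniform([0, 0, 0], [23.0, 22.8, 12.0])
            radius = rng.uniform(0.8, 5.0)
            res = sphere_average(cal, center, radius)
            expected, n = _brute_force_mean(cal, center, radius)
            assert res.voxel_count == n
            if n >= MIN_VOXELS_PER_SPHERE:
                assert not res.dismissed
                assert res.mean_bmd == expected
            else:
                assert res.dismissed

    def test_five_voxel_rule_is_a_strict_threshold(self):
        data = np.zeros((9, 9, 9))
        for n_keep, dismissed in [(4, True), (5, False)]:
            mask = np.zeros((9, 9, 9))
            mask[4, 4, 4] = 1
            mask[3, 4, 4] = 1
            mask[5, 4, 4] = 1
            mask[4, 3, 4] = 1
            if n_keep == 5:
                mask[4, 5, 4] = 1
            cal = CalibratedVolume(Volume(data, (1, 1, 1), (0, 0, 0)),
                                   Volume(mask, (1, 1, 1), (0, 0, 0)))
            res = sphere_average(cal, [4.0, 4.0, 4.0], 1.5)
            assert res.voxel_count == n_keep
            assert res.dismissed is dismissed

    def test_center_outside_bounds_dismissed_with_flag(self):
        cal = _random_calibrated()
        res = sphere_average(cal, [-50.0, 0.0, 0.0], 2.0)
        assert res.dismissed and res.out_of_bounds

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_average(_random_calibrated(), [5, 5, 5], 0.0)

    def test_shrinking_the_mask_never_undismisses(self):
        rng = np.random.default_rng(3)
        cal = _random_calibrated(seed=3)
        shrunk_mask = cal.femur_mask.data * (rng.random(
            cal.femur_mask.shape) > 0.5)
        cal2 = CalibratedVolume(cal.bmd, Volume(shrunk_mask,
                                                cal.bmd.spacing,
                                                cal.bmd.origin))
        for _ in range(30):
            center = rng.uniform([0, 0, 0], [23.0, 22.8, 12.0])
            r = rng.uniform(0.8, 4.0)
            before = sphere_average(cal, center, r).dismissed
            after = sphere_average(cal2, center, r).dismissed
            assert after or not before


class TestSampleCase:
    def test_noise_free_means_match_truth_field_on_smooth_maps(
            self, ref_params, ref_geometry, ref_frame, ref_cloud):
        # smooth fields only (no cortical step) so the sphere average is
        # a faithful point value
        from femuratlas.synthetic import (EffectMaps, SubjectRecord,
                                          build_femur)
        maps = EffectMaps(
            q_field=lambda p: -1.0 + 0.01 * p[:, 2],
            s_field=lambda p: 0.5 + 0.005 * p[:, 0],
            b_field=lambda p: 400.0 + 0.2 * p[:, 1],
            residual_sd=0.0)
        subj = SubjectRecord("s", 60.0, 30.0, "female", "right")
        hu, mask, truth = build_femur(ref_params, subj, maps, 0,
                                      geometry=ref_geometry)
        bmd = (hu.data - ref_params.hu_intercept) / ref_params.hu_slope
        cal = CalibratedVolume(Volume(bmd, hu.spacing, hu.origin), mask)
        df = sample_case(ref_cloud, cal, 1.5, "s")
        ok = ~df.dismissed.to_numpy()
        pos = ref_cloud.points[["x", "y", "z"]].to_numpy()[ok]
        expected = (60.0 * maps.q_field(pos) + 30.0 * maps.s_field(pos)
                    + maps.b_field(pos))
        assert np.abs(df.mean_bmd.to_numpy()[ok] - expected).max() < 1.0

    def test_outside_points_are_dismissed(self, ref_cloud, ref_calibrated):
        df = sample_case(ref_cloud, ref_calibrated, 1.5, "REF")
        outside = ~ref_cloud.points.inside_bone.to_numpy()
        assert df.dismissed.to_numpy()[outside].all()

    def test_neighbor_sphere_overlap_is_small_on_reference_config(
            self, ref_cloud):
        # diagnostic: worst-case neighbor overlap stays below the
        # published maximum of 5.6 % of the sphere volume
        spacing = ref_cloud.config.radial_spacing_mm
        overlap = sphere_overlap_fraction(spacing, 1.5)
        print(f"neighbor sphere overlap at {spacing} mm spacing: "
              f"{100 * overlap:.2f} %")
        assert overlap <= 0.056

    def test_overlap_fraction_against_monte_carlo(self):
        # MC oracle for the lens-volume formula
        rng = np.random.default_rng(0)
        r, d = 1.5, 1.8
        pts = rng.uniform(-r, r, size=(200_000, 3))
        in_a = (pts ** 2).sum(axis=1) < r * r
        shifted = pts.copy()
        shifted[:, 0] -= d
        in_b = (shifted ** 2).sum(axis=1) < r * r
        mc = (in_a & in_b).sum() / in_a.sum()
        assert sphere_overlap_fraction(d, r) == pytest.approx(mc, abs=0.005)


class TestFilterPoints:
    def _matrix(self, dismissal_counts, n_cases=100):
        rows = []
        for pid, k in dismissal_counts.items():
            for c in range(n_cases):
                rows.append((*pid, 300.0 if c >= k else np.nan,
                             10, c < k, f"case{c}"))
        return pd.DataFrame(rows, columns=[
            "z_index", "phi_index", "radial_ordinal", "mean_bmd",
            "voxel_count", "dismissed", "case_id"])

    def test_strictly_greater_than_twenty_percent_removed(self):
        mat = self._matrix({(0, 0, 1): 20, (0, 0, 2): 21})
        retained, removed = filter_points(mat, threshold=0.20)
        assert (0, 0, 1) in retained
        assert (0, 0, 2) in removed

    def test_no_dismissals_keeps_everything(self):
        mat = self._matrix({(0, 0, 1): 0, (5, 3, 2): 0})
        retained, removed = filter_points(mat)
        assert removed == []
        assert len(retained) == 2

    def test_single_dismissed_case_removes_the_point(self):
        mat = self._matrix({(0, 0, 1): 1}, n_cases=1)
        retained, removed = filter_points(mat)
        assert removed == [(0, 0, 1)]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_points(pd.DataFrame())


class TestCoverageScaleInvariance:
    def test_covered_bone_fraction_invariant_under_scaling(
            self, ref_params, ref_maps, ref_case, ref_cloud, ref_frame,
            ref_volume_above_lt):
        from scipy.spatial import cKDTree

        from femuratlas.frame import estimate_frame, volume_above_lt
        from femuratlas.synthetic import (SubjectRecord, build_femur,
                                          build_geometry, make_effect_maps)

        def coverage(cloud, mask, radius):
            pts = cloud.points[cloud.points.inside_bone][
                ["x", "y", "z"]].to_numpy()
            tree = cKDTree(pts)
            vox = np.argwhere(np.asarray(mask.data) > 0)
            centers = mask.index_to_world(vox)
            d, _ = tree.query(centers, k=1)
            return np.mean(d <= radius)

        _, mask1, _ = ref_case
        cov1 = coverage(ref_cloud, mask1, 1.5)

        params = ref_params.scaled(1.15)
        geo = build_geometry(params)
        maps = make_effect_maps(params)
        subj = SubjectRecord("big", 50.0, 25.0, "male", "right")
        _, mask2, truth2 = build_femur(params, subj, maps, 0, geometry=geo)
        frame2 = estimate_frame(truth2.outer_mesh, mask2)
        cloud2 = build_cloud_with_config(frame2, truth2, mask2,
                                         ref_cloud.config)
        v2 = volume_above_lt(mask2, frame2.shaft_axis,
                             frame2.lesser_trochanter)
        r2 = sphere_radius(v2, ref_volume_above_lt)
        cov2 = coverage(cloud2, mask2, r2)
        assert abs(cov1 - cov2) < 0.01


def build_cloud_with_config(frame, truth, mask, config):
    from femuratlas.cloud import build_cloud
    return build_cloud(frame, truth.outer_mesh, mask, config=config)
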