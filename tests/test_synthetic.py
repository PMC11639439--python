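"""Phantom generator: populations, exclusions, voxelization, phantom slab."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femuratlas.synthetic import (ChamberLayout, FemurPhantomParams,
                                  SubjectRecord, apply_exclusion_criteria,
                                  build_femur, build_phantom_slab,
                                  make_effect_maps, sample_population)


# --------------------------------------------------------------------------
# population

class TestPopulation:
    def test_records_within_requested_ranges(self):
        pop = sample_population(4, (20, 94), (16, 40), 0.34, seed=1)
        assert len(pop) == 4
        for r in pop:
            assert 20 <= r.age <= 94
            assert 16 <= r.bmi <= 40
            assert r.sex in ("female", "male")
            assert r.side in ("left", "right")

    def test_deterministic_for_fixed_seed(self):
        a = sample_population(10, seed=1)
        b = sample_population(10, seed=1)
        assert a == b
        assert a != sample_population(10, seed=2)

    def test_female_fraction_matches_binomial_expectation(self):
        # binomial oracle: sd of the observed fraction at n=1000, p=0.34
        # is sqrt(p(1-p)/n) ~ 0.015, so +-0.05 is a > 3 sigma band
        pop = sample_population(1000, female_fraction=0.34, seed=3)
        frac = np.mean([r.sex == "female" for r in pop])
        assert abs(frac - 0.34) <= 0.05

    def test_paired_mode_emits_both_sides_per_donor(self):
        pop = sample_population(5, seed=0, paired=True)
        assert len(pop) == 10
        sides = {(r.id[:-1], r.side) for r in pop}
        assert len(sides) == 10  # every donor once per side

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_population(5, age_range=(90, 20))
        with pytest.raises(ValueError):
            sample_population(0)


class TestExclusionCriteria:
    @pytest.mark.parametrize("age,bmi,kept", [
        (19.0, 25.0, False),   # under 20
        (20.0, 25.0, True),    # exactly 20 retained
        (50.0, 16.0, True),    # bounds exclusive: BMI 16 retained
        (50.0, 40.0, True),
        (50.0, 15.9, False),
        (50.0, 40.1, False),
        (float("nan"), 25.0, False),   # unknown age
    ])
    def test_boundary_cases(self, age, bmi, kept):
        rec = SubjectRecord("x", age, bmi, "female", "left")
        assert (apply_exclusion_criteria([rec]) == [rec]) is kept

    def test_empty_input(self):
        assert apply_exclusion_criteria([]) == []

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 120), st.floats(5, 60)),
                    max_size=20))
    def test_filter_is_order_preserving_subset(self, rows):
        recs = [SubjectRecord(f"r{i}", a, b, "male", "right")
                for i, (a, b) in enumerate(rows)]
        kept = apply_exclusion_criteria(recs)
        ids = [r.id for r in recs]
        assert [ids.index(r.id) for r in kept] == sorted(
            ids.index(r.id) for r in kept)
        for r in kept:
            assert r.age >= 20 and 16 <= r.bmi <= 40


# --------------------------------------------------------------------------
# femur voxelization

SMALL = FemurPhantomParams(voxel_spacing=(2.0, 2.0, 2.0))


class TestBuildFemur:
    def test_interior_voxels_carry_the_exact_density_field(self, ref_geometry,
                                                           ref_maps):
        params_ident = FemurPhantomParams(hu_slope=1.0, hu_intercept=0.0,
                                          noise_sd=0.0)
        subj = SubjectRecord("a", 60.0, 28.0, "male", "right")
        hu, mask, truth = build_femur(params_ident, subj, ref_maps, seed=0,
                                      geometry=ref_geometry)
        pts = ref_geometry.points
        expected = (60.0 * ref_maps.q_field(pts) + 28.0 * ref_maps.s_field(pts)
                    + ref_maps.b_field(pts)).reshape(mask.shape)
        inside = mask.data > 0
        np.testing.assert_allclose(hu.data[inside], expected[inside],
                                   rtol=1e-12)

    def test_age_difference_is_linear_in_q_field(self, ref_geometry, ref_maps,
                                                 ref_params):
        s1 = SubjectRecord("a", 40.0, 25.0, "female", "right")
        s2 = SubjectRecord("b", 50.0, 25.0, "female", "right")
        hu1, mask, _ = build_femur(ref_params, s1, ref_maps, 0, ref_geometry)
        hu2, _, _ = build_femur(ref_params, s2, ref_maps, 0, ref_geometry)
        q = ref_geometry.field_cache[id(ref_maps)][0]
        diff = (hu2.data - hu1.data) / ref_params.hu_slope
        inside = mask.data > 0
        np.testing.assert_allclose(diff[inside], 10.0 * q[inside], atol=1e-9)

    def test_deterministic_volumes_with_noise(self):
        params = FemurPhantomParams(voxel_spacing=(2.5, 2.5, 2.5),
                                    noise_sd=8.0)
        maps = make_effect_maps(params)
        subj = SubjectRecord("a", 70.0, 22.0, "female", "right")
        hu1, m1, _ = build_femur(params, subj, maps, seed=11)
        hu2, m2, _ = build_femur(params, subj, maps, seed=11)
        assert np.array_equal(hu1.data, hu2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_left_is_exact_sagittal_mirror_of_right(self, ref_geometry,
                                                    ref_maps, ref_params):
        sR = SubjectRecord("a", 55.0, 24.0, "male", "right")
        sL = SubjectRecord("a", 55.0, 24.0, "male", "left")
        huR, mR, tR = build_femur(ref_params, sR, ref_maps, 5, ref_geometry)
        huL, mL, tL = build_femur(ref_params, sL, ref_maps, 5, ref_geometry)
        mirrored = huR.mirrored_sagittal()
        assert np.array_equal(huL.data, mirrored.data)
        np.testing.assert_allclose(huL.origin, mirrored.origin)
        np.testing.assert_allclose(tL.head_center,
                                   tR.head_center * [-1, 1, 1])

    def test_mask_volume_matches_monte_carlo_shape_volume(self, ref_geometry):
        # grid-free oracle: MC integration of the signed-distance field
        rng = np.random.default_rng(123)
        grid = ref_geometry.volume_grid
        lo = grid.origin
        hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1)
        n = 200_000
        pts = rng.uniform(lo, hi, size=(n, 3))
        inside = ref_geometry.template.sdf(pts) < 0
        box = np.prod(hi - lo)
        mc_vol = box * inside.mean()
        mask_vol = ref_geometry.mask.sum() * grid.voxel_volume
        assert abs(mask_vol - mc_vol) / mc_vol < 0.02

    def test_mask_surface_voxels_lie_on_the_truth_mesh(self, ref_geometry):
        from scipy import ndimage

        from femuratlas.raycast import surface_distance
        mask = ref_geometry.mask
        interior = ndimage.binary_erosion(mask)
        surf_idx = np.argwhere(mask & ~interior)
        rng = np.random.default_rng(0)
        surf_idx = surf_idx[rng.choice(len(surf_idx), 400, replace=False)]
        grid = ref_geometry.volume_grid
        pts = grid.index_to_world(surf_idx)
        d = surface_distance(ref_geometry.outer_mesh, pts)
        diag = float(np.linalg.norm(grid.spacing))
        assert np.mean(d <= diag) >= 0.99

    def test_thin_shell_raises_warning_flag(self):
        params = FemurPhantomParams(voxel_spacing=(3.0, 3.0, 3.0))
        maps = make_effect_maps(params)
        subj = SubjectRecord("a", 50.0, 25.0, "female", "right")
        _, _, truth = build_femur(params, subj, maps, 0)
        assert any("shell" in w for w in truth.warnings)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FemurPhantomParams(neck_shaft_angle=85.0)
        with pytest.raises(ValueError):
            FemurPhantomParams(head_radius=-1.0)
        with pytest.raises(ValueError):
            FemurPhantomParams(voxel_spacing=(1.0, 0.0, 1.0))


# --------------------------------------------------------------------------
# calibration phantom slab

class TestPhantomSlab:
    CONC = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)

    def _chamber_means(self, vol, layout, k):
        """Brute-force chamber means from the known construction layout."""
        r = layout.chamber_radius_mm
        pad = r + layout.body_margin_mm
        centers = layout.centers_mm((pad + 4.0, pad + 4.0))
        xs, ys, _ = vol.axes_world()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        out = []
        for cx, cy in centers:
            inside = (X - cx) ** 2 + (Y - cy) ** 2 <= (0.8 * r) ** 2
            out.append(vol.data[:, :, k][inside].mean())
        return np.array(out)

    def test_noise_free_chamber_means_equal_concentrations(self):
        params = FemurPhantomParams(hu_slope=1.0, hu_intercept=0.0)
        lay = ChamberLayout()
        vol = build_phantom_slab(self.CONC, params, lay, n_slices=3)
        np.testing.assert_allclose(self._chamber_means(vol, lay, 1),
                                   self.CONC, atol=1e-12)

    def test_per_slice_intercept_drift_shifts_means(self):
        params = FemurPhantomParams(hu_slope=1.0, hu_intercept=0.0)
        lay = ChamberLayout()
        drift = lambda k: 7.0 * k
        vol = build_phantom_slab(self.CONC, params, lay, n_slices=4,
                                 intercept_drift=drift)
        for k in range(4):
            np.testing.assert_allclose(
                self._chamber_means(vol, lay, k),
                np.asarray(self.CONC) + drift(k), atol=1e-12)

    def test_noisy_chamber_means_within_clt_bound(self):
        # CLT oracle: mean of N iid N(c, 5) values deviates by less than
        # 3 * 5 / sqrt(N) in ~99.7 % of draws
        params = FemurPhantomParams(hu_slope=1.0, hu_intercept=0.0,
                                    noise_sd=5.0)
        lay = ChamberLayout()
        vol = build_phantom_slab(self.CONC, params, lay, n_slices=2, seed=5)
        r = lay.chamber_radius_mm
        n_vox = np.pi * (0.8 * r) ** 2  # ~pixel count at 1 mm spacing
        bound = 3.0 * 5.0 / np.sqrt(n_vox)
        means = self._chamber_means(vol, lay, 0)
        assert np.all(np.abs(means - self.CONC) < bound)

    def test_overlapping_chambers_rejected(self):
        lay = ChamberLayout(chamber_radius_mm=13.0, pitch_mm=24.0)
        with pytest.raises(ValueError, match="overlap"):
            build_phantom_slab(self.CONC, FemurPhantomParams(), lay)

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValueError):
            build_phantom_slab((100.0, 0.0, 200.0, 400.0, 600.0, 800.0))
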