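import math

import numpy as np
import pytest

from mibgdose import (
    EnergyWindowSet,
    ValidationError,
    VoxelImage,
    activity_from_voi,
    adaptive_threshold_mask,
    average_projection_rate,
    block27_extrema,
    chang_attenuation_correct,
    chang_correction_factors,
    i131_windows,
    tew_correct,
    voi_count_rate,
)


class TestEnergyWindows:
    def test_standard_i131_windows(self):
        w = i131_windows()
        assert w.peak == (364.0, pytest.approx(72.8))
        assert w.lower[1] == pytest.approx(21.84)
        assert w.upper[1] == pytest.approx(21.84)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError):
            EnergyWindowSet(peak=(364.0, 72.8), lower=(340.0, 21.84),
                            upper=(420.0, 21.84))

    def test_misordered_windows_rejected(self):
        with pytest.raises(ValidationError):
            EnergyWindowSet(peak=(364.0, 72.8), lower=(420.0, 21.84),
                            upper=(300.0, 21.84))


class TestTewCorrect:
    def test_scatter_free_passthrough(self):
        assert tew_correct(1234.0, 0.0, 0.0, i131_windows()) == 1234.0

    def test_hand_computed_example(self):
        # 1000 - 36.4*(120/21.84 + 60/21.84) = 700.0
        assert tew_correct(1000.0, 120.0, 60.0, i131_windows()) == \
            pytest.approx(700.0)

    def test_clamped_at_zero(self):
        assert tew_correct(10.0, 500.0, 500.0, i131_windows()) == 0.0

    def test_elementwise_on_projection_arrays(self):
        w = i131_windows()
        cp = np.array([[1000.0, 10.0], [500.0, 0.0]])
        c1 = np.array([[120.0, 500.0], [0.0, 0.0]])
        c2 = np.array([[60.0, 500.0], [0.0, 0.0]])
        out = tew_correct(cp, c1, c2, w)
        assert out == pytest.approx(np.array([[700.0, 0.0], [500.0, 0.0]]))

    def test_linear_above_clamp(self):
        w = i131_windows()
        a = tew_correct(1000.0, 100.0, 50.0, w)
        b = tew_correct(2000.0, 200.0, 100.0, w)
        assert b == pytest.approx(2 * a)


class TestChang:
    def test_mu_zero_is_identity(self, cylinder_mask):
        mask, vox, _, _ = cylinder_mask
        img = VoxelImage(np.random.default_rng(0).random(mask.shape),
                         voxel_mm=vox)
        out = chang_attenuation_correct(img, mask, mu_per_cm=0.0)
        assert np.array_equal(out.data, img.data)

    def test_centre_of_cylinder_closed_form(self, cylinder_mask):
        """All rays from the centre travel exactly R, so the factor is
        exp(mu*R) = exp(1.1) for R = 10 cm at mu = 0.11/cm."""
        mask, vox, center, r_cm = cylinder_mask
        f = chang_correction_factors(mask, vox, 0.11, n_angles=64,
                                     points=[center])[0]
        assert f == pytest.approx(math.exp(0.11 * r_cm), rel=0.01)

    def test_off_centre_voxel_against_dense_ray_oracle(self, cylinder_mask):
        mask, vox, (z, cy, cx), _ = cylinder_mask
        pt = [[z, cy + 10, cx + 4]]
        f64 = chang_correction_factors(mask, vox, 0.11, 64, points=pt)[0]
        f_dense = chang_correction_factors(mask, vox, 0.11, 4096,
                                           points=pt)[0]
        assert f64 == pytest.approx(f_dense, rel=0.02)

    def test_factor_at_least_one_inside_mask(self, cylinder_mask):
        mask, vox, _, _ = cylinder_mask
        factors = chang_correction_factors(mask, vox, 0.11, n_angles=16)
        assert np.all(factors[mask] >= 1.0)
        assert np.all(factors[~mask] == 1.0)

    def test_outside_mask_untouched(self, cylinder_mask):
        mask, vox, _, _ = cylinder_mask
        img = VoxelImage(np.ones(mask.shape), voxel_mm=vox)
        out = chang_attenuation_correct(img, mask, 0.11, n_angles=16)
        assert np.array_equal(out.data[~mask], img.data[~mask])
        assert np.all(out.data[mask] > img.data[mask])
        assert "attenuation" in out.corrections_applied

    def test_double_correction_rejected(self, cylinder_mask):
        mask, vox, _, _ = cylinder_mask
        img = VoxelImage(np.ones(mask.shape), voxel_mm=vox)
        once = chang_attenuation_correct(img, mask, 0.11, n_angles=8)
        with pytest.raises(ValidationError):
            chang_attenuation_correct(once, mask, 0.11, n_angles=8)


class TestVoiCountRate:
    def test_uniform_rate_sums(self):
        img = VoxelImage(np.ones((10, 10, 10)), voxel_mm=(1.0, 1.0, 1.0))
        mask = np.zeros((10, 10, 10), bool)
        mask[:10, :10, :10] = True
        rate, vol = voi_count_rate(img, mask)
        assert rate == 1000.0
        assert vol == pytest.approx(1.0)  # 1000 mm3 = 1 ml

    def test_single_voxel_mask(self):
        data = np.zeros((4, 4, 4))
        data[2, 2, 2] = 7.5
        img = VoxelImage(data, voxel_mm=(2.0, 2.0, 2.0))
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 2, 2] = True
        rate, vol = voi_count_rate(img, mask)
        assert rate == 7.5
        assert vol == pytest.approx(0.008)

    def test_sphere_fixture_enclosed_rate(self, sphere_phantom):
        image, mask, truth = sphere_phantom
        rate, _ = voi_count_rate(image, mask)
        assert rate == pytest.approx(
            truth.params["spheres"][0]["enclosed_rate_cps"], rel=1e-6)

    def test_empty_mask_rejected(self, sphere_phantom):
        image, _, _ = sphere_phantom
        with pytest.raises(ValidationError):
            voi_count_rate(image, np.zeros(image.data.shape, bool))


class TestAdaptiveThreshold:
    def test_hard_edged_sphere_recovered_within_one_voxel(self):
        """A 42.8-ml hard sphere is segmented to its own volume."""
        from mibgdose import synth
        vox = 4.67
        shape = (48, 48, 48)
        # centre off the grid symmetry point, as for any real lesion
        center = tuple(0.5 * n * vox + off
                       for n, off in zip(shape, (0.3, 1.1, 2.7)))
        image, masks, truth = synth.gen_sphere_phantom(
            shape, (vox,) * 3,
            [{"center_mm": center, "diameter_mm": 43.4,
              "conc_cps_per_ml": 50.0}],
            psf_fwhm_mm=0.0, seed=1)
        seed_vox = tuple(int(c / vox) for c in center)
        target = truth.params["spheres"][0]["raster_volume_ml"]
        mask = adaptive_threshold_mask(image, target, seed_vox)
        vol = mask.sum() * image.voxel_volume_ml
        assert abs(vol - target) <= image.voxel_volume_ml

    def test_target_equal_full_support_returns_whole_object(self):
        data = np.zeros((12, 12, 12))
        data[4:8, 4:8, 4:8] = 3.0
        img = VoxelImage(data, voxel_mm=(2.0, 2.0, 2.0))
        target = 64 * img.voxel_volume_ml
        mask = adaptive_threshold_mask(img, target, (5, 5, 5))
        assert mask.sum() == 64

    def test_seed_in_background_rejected(self):
        data = np.zeros((12, 12, 12))
        data[4:8, 4:8, 4:8] = 3.0
        img = VoxelImage(data, voxel_mm=(2.0, 2.0, 2.0))
        with pytest.raises(ValidationError):
            adaptive_threshold_mask(img, 0.1, (0, 0, 0))

    def test_unreachable_target_reports_achievable_range(self):
        data = np.zeros((12, 12, 12))
        data[4:8, 4:8, 4:8] = 3.0
        img = VoxelImage(data, voxel_mm=(2.0, 2.0, 2.0))
        with pytest.raises(ValidationError, match="unreachable"):
            adaptive_threshold_mask(img, 5000.0, (5, 5, 5))


class TestBlock27:
    def test_uniform_image_extrema_equal_constant(self):
        img = VoxelImage(np.full((9, 9, 9), 4.2), voxel_mm=(1.0,) * 3)
        res = block27_extrema(img, np.ones((9, 9, 9), bool))
        assert res["max_block_mean"] == pytest.approx(4.2)
        assert res["min_block_mean"] == pytest.approx(4.2)

    def test_interior_spike_contributes_h_over_27(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 27.0
        img = VoxelImage(data, voxel_mm=(1.0,) * 3)
        res = block27_extrema(img, np.ones((9, 9, 9), bool))
        assert res["max_block_mean"] == pytest.approx(1.0)
        assert res["min_block_mean"] == 0.0

    def test_matches_brute_force_on_random_images(self):
        """Exhaustive 3x3x3 scan oracle on 20 seeded random images."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.random((7, 8, 9))
            mask = rng.random((7, 8, 9)) > 0.2
            img = VoxelImage(data, voxel_mm=(1.0,) * 3)
            best_max, best_min = -np.inf, np.inf
            for z in range(1, 6):
                for y in range(1, 7):
                    for x in range(1, 8):
                        block = np.s_[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2]
                        if mask[block].all():
                            mval = data[block].mean()
                            best_max = max(best_max, mval)
                            best_min = min(best_min, mval)
            if not np.isfinite(best_max):
                with pytest.raises(ValidationError):
                    block27_extrema(img, mask)
                continue
            res = block27_extrema(img, mask)
            assert res["max_block_mean"] == pytest.approx(best_max)
            assert res["min_block_mean"] == pytest.approx(best_min)

    def test_no_interior_block_rejected(self):
        img = VoxelImage(np.ones((4, 4, 4)), voxel_mm=(1.0,) * 3)
        mask = np.zeros((4, 4, 4), bool)
        mask[0:2, 0:2, 0:2] = True
        with pytest.raises(ValidationError):
            block27_extrema(img, mask)


class TestProjectionsAndActivity:
    def test_uniform_projection_rate(self):
        counts = np.full(64, 1000.0)
        assert average_projection_rate(counts, 10.0) == pytest.approx(100.0)

    def test_single_view(self):
        assert average_projection_rate([500.0], 5.0) == pytest.approx(100.0)

    def test_mixed_durations_hand_sum(self):
        counts = np.array([100.0, 400.0, 900.0])
        durations = np.array([10.0, 20.0, 30.0])
        expected = (10.0 + 20.0 + 30.0) / 3
        assert average_projection_rate(counts, durations) == \
            pytest.approx(expected)

    def test_activity_from_voi_identity_and_arithmetic(self):
        assert activity_from_voi(29.2, 29.2, 1.0, 1.0) == pytest.approx(1.0)
        assert activity_from_voi(29.2, 29.2, 0.5, 1.2) == pytest.approx(2.4)

    def test_activity_from_voi_exact_inversion(self):
        Q, R, dtf = 29.2, 0.8, 1.05
        for A in (0.1, 3.0, 57.0):
            rate = A * Q * R / dtf
            assert activity_from_voi(rate, Q, R, dtf) == pytest.approx(A)

    def test_zero_recovery_rejected(self):
        with pytest.raises(ValidationError):
            activity_from_voi(10.0, 29.2, 0.0, 1.0)

    def test_full_chain_on_blurred_sphere(self, sphere_phantom):
        """Blur -> recovery from truth -> activity recovers the generator's
        activity within 5 %."""
        image, mask, truth = sphere_phantom
        sph = truth.params["spheres"][0]
        Q = 29.2
        true_activity = sph["total_rate_cps"] / Q
        rate, vol = voi_count_rate(image, mask)
        R = sph["enclosed_fraction"]
        est = activity_from_voi(rate, Q, R, 1.0)
        assert est == pytest.approx(true_activity, rel=0.05)
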