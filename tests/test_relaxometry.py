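import numpy as np
import pytest

from geldose import (
    FitOptions,
    GridGeometry,
    MultiEchoImage,
    cylinder_roi,
    fit_r2_map,
    fit_r2_voxel,
    roi_mean_r2,
    simulate_multiecho_mri,
)
from geldose.grid_model import R2Map
from geldose.synthetic import DEFAULT_ECHO_TIMES_S as TE

METHODS = ["loglinear_weighted", "nonlinear_ls"]


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return np.hypot(signal + rng.normal(0, sigma, signal.shape), rng.normal(0, sigma, signal.shape))


class TestVoxelFit:
    @pytest.mark.parametrize("method", METHODS)
    def test_noiseless_monoexponential_is_exact(self, method):
        signal = 1000.0 * np.exp(-TE * 3.0)
        r2, s0, q = fit_r2_voxel(signal, TE, FitOptions(method=method))
        assert r2 == pytest.approx(3.0, abs=1e-6)
        assert s0 == pytest.approx(1000.0, rel=1e-6)
        assert q == pytest.approx(1.0)

    @pytest.mark.parametrize("method", METHODS)
    def test_constant_signal_gives_zero_r2(self, method):
        r2, s0, _ = fit_r2_voxel(np.full(8, 500.0), TE, FitOptions(method=method))
        assert r2 == pytest.approx(0.0, abs=1e-9)
        assert s0 == pytest.approx(500.0, rel=1e-9)

    def test_too_few_usable_echoes_flags_invalid(self):
        signal = np.array([100.0, 0.0, 0.0, 0.0])
        r2, s0, q = fit_r2_voxel(signal, TE[:4], FitOptions(min_echoes=2))
        assert np.isnan(r2) and np.isnan(s0) and q == 0.0

    @pytest.mark.parametrize("method", METHODS)
    def test_rician_noise_estimate_within_monte_carlo_se(self, method):
        """Fixed-seed estimate lies within 3 SE of truth; the SE comes from a
        200-replicate brute-force simulation at the same noise level."""
        r2_true, s0, sigma = 3.71, 1000.0, 10.0
        clean = s0 * np.exp(-TE * r2_true)
        opts = FitOptions(method=method)
        reps = np.array(
            [
                fit_r2_voxel(_rician(clean, sigma, np.random.default_rng(1000 + i)), TE, opts)[0]
                for i in range(200)
            ]
        )
        se = reps.std(ddof=1)
        est = fit_r2_voxel(_rician(clean, sigma, np.random.default_rng(5)), TE, opts)[0]
        assert abs(est - r2_true) < 3 * se

    def test_nonlinear_median_bias_small_at_snr_20(self):
        # no Rician bias correction is applied; at SNR >= 20 the nonlinear
        # estimator's median bias stays below 2% of the true R2
        r2_true, s0, sigma = 3.71, 1000.0, 50.0
        clean = s0 * np.exp(-TE * r2_true)
        opts = FitOptions(method="nonlinear_ls")
        reps = np.array(
            [
                fit_r2_voxel(_rician(clean, sigma, np.random.default_rng(2000 + i)), TE, opts)[0]
                for i in range(200)
            ]
        )
        assert abs(np.median(reps) - r2_true) < 0.02 * r2_true


class TestMapFit:
    def test_noiseless_map_recovers_truth_everywhere(self, box_dose, gel_curve):
        img = simulate_multiecho_mri(box_dose, gel_curve)
        r2map = fit_r2_map(img)
        truth = gel_curve.intercept + gel_curve.slope * box_dose.values
        assert r2map.valid_mask.all()
        np.testing.assert_allclose(r2map.r2, truth, atol=1e-6)

    def test_all_zero_image_is_all_invalid(self):
        geom = GridGeometry((3, 3, 2), (1, 1, 1))
        img = MultiEchoImage(geom, TE, np.zeros((3, 3, 2, 8)))
        assert not fit_r2_map(img).valid_mask.any()

    @pytest.mark.parametrize("method", METHODS)
    def test_map_matches_looped_voxel_fit(self, method):
        rng = np.random.default_rng(11)
        geom = GridGeometry((5, 5, 3), (1, 1, 1))
        r2_field = 1.0 + 3.0 * rng.random((5, 5, 3))
        clean = 800.0 * np.exp(-TE[None, None, None, :] * r2_field[..., None])
        signal = _rician(clean, 5.0, rng)
        img = MultiEchoImage(geom, TE, signal)
        opts = FitOptions(method=method)
        r2map = fit_r2_map(img, opts)
        for idx in np.ndindex((5, 5, 3)):
            r2, s0, q = fit_r2_voxel(signal[idx], TE, opts)
            assert r2map.r2[idx] == pytest.approx(r2, rel=1e-9)
            assert r2map.fit_quality[idx] == pytest.approx(q, rel=1e-9, abs=1e-12)

    def test_map_is_deterministic(self, box_dose, gel_curve):
        from geldose import NoiseModel

        img = simulate_multiecho_mri(box_dose, gel_curve, noise=NoiseModel("rician", 20, 3))
        a, b = fit_r2_map(img), fit_r2_map(img)
        np.testing.assert_array_equal(a.r2[a.valid_mask], b.r2[b.valid_mask])
        np.testing.assert_array_equal(a.valid_mask, b.valid_mask)


class TestRoi:
    def _uniform_map(self, value=2.21, shape=(4, 4, 2)):
        geom = GridGeometry(shape, (1, 1, 1))
        ones = np.ones(shape)
        return R2Map(geom, value * ones, 1000 * ones, ones, ones.astype(bool))

    def test_uniform_roi_mean(self):
        mean, sd, n = roi_mean_r2(self._uniform_map(), np.ones((4, 4, 2), bool))
        assert mean == pytest.approx(2.21)
        assert sd == 0.0
        assert n == 32

    def test_two_voxel_mask_arithmetic(self):
        r2map = self._uniform_map()
        r2map.r2[0, 0, 0], r2map.r2[1, 0, 0] = 2.0, 4.0
        mask = np.zeros((4, 4, 2), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        mean, sd, n = roi_mean_r2(r2map, mask)
        assert (mean, n) == (3.0, 2)
        assert sd == pytest.approx(np.sqrt(2))

    def test_random_mask_matches_direct_computation(self):
        rng = np.random.default_rng(4)
        r2map = self._uniform_map()
        r2map.r2[:] = rng.random((4, 4, 2))
        mask = rng.random((4, 4, 2)) > 0.5
        mean, sd, n = roi_mean_r2(r2map, mask)
        assert mean == pytest.approx(r2map.r2[mask].mean())
        assert sd == pytest.approx(np.std(r2map.r2[mask], ddof=1))

    def test_empty_intersection_rejected(self):
        r2map = self._uniform_map()
        r2map.valid_mask[:] = False
        with pytest.raises(ValueError, match="ROI"):
            roi_mean_r2(r2map, np.ones((4, 4, 2), bool))


class TestCylinderRoi:
    def test_strong_erosion_keeps_only_near_axis_voxels(self):
        geom = GridGeometry((21, 21, 5), (1, 1, 1), (-10, -10, -2))
        mask = cylinder_roi(geom, (0, 0, 0), radius=8.0, erode_mm=7.5)
        X, Y, _ = geom.voxel_centers()
        assert mask.any()
        assert np.all(np.hypot(X[mask], Y[mask]) <= 0.5)

    def test_mask_volume_close_to_analytic_cylinder(self):
        geom = GridGeometry((40, 40, 40), (1, 1, 1), (-19.5, -19.5, -19.5))
        r, L, e = 12.0, 30.0, 2.0
        mask = cylinder_roi(geom, (0, 0, 0), radius=r, length=L, erode_mm=e)
        vol = mask.sum() * 1.0
        analytic = np.pi * (r - e) ** 2 * (L - 2 * e)
        # surface voxels bound the discretization error
        surface = 2 * np.pi * (r - e) * (L - 2 * e) + 2 * np.pi * (r - e) ** 2
        assert abs(vol - analytic) < surface

    def test_gel_insert_fits_acquisition_grid(self):
        # 4.5 cm diameter x 5.0 cm long insert inside the 224x224x60 volume
        geom = GridGeometry((224, 224, 60), (0.6, 0.6, 2.0), (-66.9, -66.9, -59.0))
        mask = cylinder_roi(geom, (0, 0, 0), radius=22.5, length=50.0, erode_mm=3.0)
        assert mask.any()
        interior = np.zeros(geom.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert not mask[~interior].any()

    def test_degenerate_axis_rejected(self):
        geom = GridGeometry((4, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError, match="axis"):
            cylinder_roi(geom, (0, 0, 0), radius=2.0, axis=(0, 0, 0))

    def test_erosion_must_be_smaller_than_radius(self):
        geom = GridGeometry((4, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            cylinder_roi(geom, (0, 0, 0), radius=2.0, erode_mm=2.0)
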