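"""Lateral averaging, slope fitting, fold-bias correction, percent change."""

import numpy as np
import pytest

from psoct import (
    ImagingConfig,
    LayerWindows,
    bladder_windows,
    detect_surfaces,
    fit_birefringence,
    flatten,
    lateral_average,
    layer_birefringence,
    make_slab_model,
    percent_change,
    simulate_bscan,
)
from psoct.fitting import (
    RetardationProfile,
    columns_for_extent,
    estimate_retardation_noise,
    fold_bias_correct,
    fold_bias_mean,
)
from psoct.simulate import NoiseModel


def slab_flat(small_config, dn=1e-4, thickness=700.0, noise=None):
    model = make_slab_model(thickness, birefringence=dn, surface_profile=np.full(64, 55.0))
    pair = simulate_bscan(model, small_config, noise or NoiseModel.off())
    seg = detect_surfaces(pair)
    return pair, seg, flatten(pair, seg)


class TestLateralAverage:
    def test_single_column_equals_that_column(self, small_config):
        pair, seg, flat = slab_flat(small_config)
        prof = lateral_average(flat, (5, 6))
        col = flat.retardation[:, 5]
        assert prof.n_columns == 1
        assert np.allclose(prof.mean_retardation_deg, col[~np.isnan(col)][: prof.depth_um.size])

    def test_identical_columns_average_to_one_of_them(self, small_config):
        pair, seg, flat = slab_flat(small_config)
        a = lateral_average(flat, (0, 1))
        b = lateral_average(flat, (0, 64))
        assert b.n_columns == 64
        assert np.allclose(a.mean_retardation_deg, b.mean_retardation_deg)

    def test_two_mm_range_is_256_columns(self):
        assert columns_for_extent(2000.0, ImagingConfig()) == 256

    def test_no_valid_columns_raises(self, small_config):
        pair, seg, flat = slab_flat(small_config)
        flat.valid[:] = False
        with pytest.raises(ValueError):
            lateral_average(flat)

    def test_depth_axis_is_physical_units(self, small_config):
        _, _, flat = slab_flat(small_config)
        prof = lateral_average(flat, refractive_index=1.4)
        step = small_config.axial_pixel_spacing_air_um / 1.4
        assert np.allclose(np.diff(prof.depth_um), step)


class TestFitBirefringence:
    def test_constant_profile_gives_zero_slope(self, small_config):
        prof = RetardationProfile(np.arange(10.0) * 2.0, np.full(10, 5.0), 4, 100.0)
        est = fit_birefringence(prof, small_config, (0.0, 20.0))
        assert est.delta_n == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == 1.0

    @pytest.mark.parametrize("dn", [1e-5, 5e-5, 1e-4, 2.1e-4])
    def test_forward_inverse_round_trip(self, small_config, dn):
        """Noise-free recovery within 0.5% across the working dn range."""
        pair, seg, flat = slab_flat(small_config, dn=dn)
        max_px = int(np.median(seg.depth_extent()[seg.valid]))
        prof = lateral_average(flat, max_depth_px=max_px)
        est = fit_birefringence(prof, small_config, (10.0, prof.depth_um[-1] + 1))
        assert est.delta_n == pytest.approx(dn, rel=5e-3)

    def test_linearity_in_delta_n(self, small_config):
        pair1, seg1, flat1 = slab_flat(small_config, dn=5e-5)
        pair2, seg2, flat2 = slab_flat(small_config, dn=1.5e-4)
        e1 = fit_birefringence(lateral_average(flat1), small_config, (10.0, 480.0))
        e2 = fit_birefringence(lateral_average(flat2), small_config, (10.0, 480.0))
        assert e2.delta_n == pytest.approx(3.0 * e1.delta_n, rel=1e-9)

    def test_wavelength_consistency(self):
        """Recovered dn is invariant to lambda used in both directions."""
        out = []
        for wl in (1050.0, 1300.0):
            config = ImagingConfig(wavelength_nm=wl, depth_pixels=420, lateral_pixels=16)
            model = make_slab_model(700.0, birefringence=1e-4, surface_profile=np.full(16, 55.0))
            pair = simulate_bscan(model, config, NoiseModel.off())
            seg = detect_surfaces(pair)
            prof = lateral_average(flatten(pair, seg))
            out.append(fit_birefringence(prof, config, (10.0, 480.0)).delta_n)
        assert out[0] == pytest.approx(out[1], rel=1e-9)

    def test_negative_slope_reported_not_clipped(self, small_config):
        z = np.arange(20.0) * 2.0
        prof = RetardationProfile(z, 10.0 - 0.05 * z, 4, 100.0)
        est = fit_birefringence(prof, small_config, (0.0, 40.0))
        assert est.delta_n < 0

    def test_fit_window_stops_before_fold(self):
        """The fitted window never reaches depths past the 90-deg fold."""
        config = ImagingConfig(depth_pixels=2400, lateral_pixels=8)
        model = make_slab_model(4000.0, birefringence=2.1e-4, surface_profile=np.full(8, 55.0))
        pair = simulate_bscan(model, config, NoiseModel.off())
        seg = detect_surfaces(pair)
        prof = lateral_average(flatten(pair, seg))
        # depth at which the noise-free phase reaches 90 deg
        z90 = 90.0 / (360.0 * 2.1e-4 / (1300e-3))
        est = fit_birefringence(prof, config, (10.0, 4000.0))
        assert est.fit_window_um[1] <= z90
        assert est.delta_n == pytest.approx(2.1e-4, rel=0.02)

    def test_too_few_points_and_zero_spread_raise(self, small_config):
        prof = RetardationProfile(np.array([1.0, 2.0]), np.array([0.1, 0.2]), 1, 10.0)
        with pytest.raises(ValueError):
            fit_birefringence(prof, small_config, (0.0, 5.0))
        with pytest.raises(ValueError):
            fit_birefringence(prof, small_config, (5.0, 1.0))


class TestFoldBiasCorrection:
    def test_mean_model_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        sigma = 2.0
        for mu in (0.0, 1.0, 3.0, 8.0):
            draws = np.abs(mu + rng.normal(0, sigma, 200_000))
            assert fold_bias_mean(np.array([mu]), sigma)[0] == pytest.approx(
                draws.mean(), abs=0.02
            )

    def test_correction_inverts_mean_model(self):
        mu = np.linspace(0.0, 30.0, 61)
        corrected = fold_bias_correct(fold_bias_mean(mu, 2.0), 2.0)
        assert np.allclose(corrected, mu, atol=0.02)

    def test_zero_sigma_is_identity(self):
        y = np.linspace(0, 40, 11)
        assert np.array_equal(fold_bias_correct(y, 0.0), y)

    def test_noise_sd_estimated_from_above_surface_pixels(self, small_config):
        pair, seg, _ = slab_flat(small_config, noise=NoiseModel(True, 2.0, 1e-3, 1))
        sd = estimate_retardation_noise(pair.retardation, seg.top_index, seg.valid)
        assert sd == pytest.approx(2.0, rel=0.1)

    def test_noisy_recovery_within_five_percent_and_se_shrinks(self):
        """Mean over 20 seeds within 5%; s.e. scales ~ 1/sqrt(n_columns)."""
        config = ImagingConfig(depth_pixels=420, lateral_pixels=128)
        model = make_slab_model(700.0, birefringence=1e-4, surface_profile=np.full(128, 55.0))
        full = []
        deep = {16: [], 128: []}
        for seed in range(20):
            pair = simulate_bscan(model, config, NoiseModel(True, 2.0, 1e-3, seed))
            seg = detect_surfaces(pair)
            flat = flatten(pair, seg)
            sd = estimate_retardation_noise(pair.retardation, seg.top_index, seg.valid)
            full.append(
                fit_birefringence(
                    lateral_average(flat), config, (10.0, 480.0), noise_sd_deg=sd
                ).delta_n
            )
            # s.e. scaling is checked away from the 0-deg fold, where the
            # de-biasing is negligible and the fit is linear in the noise
            for ncols in deep:
                prof = lateral_average(flat, (0, ncols))
                deep[ncols].append(
                    fit_birefringence(prof, config, (150.0, 480.0), noise_sd_deg=sd).delta_n
                )
        assert np.mean(full) == pytest.approx(1e-4, rel=0.05)
        se16, se128 = np.std(deep[16]), np.std(deep[128])
        # eight-fold column increase: s.e. should shrink close to sqrt(8)
        assert se128 < se16 / 2.0


class TestLayerWindows:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            LayerWindows([("a", (0.0, 100.0)), ("b", (50.0, 200.0))])
        with pytest.raises(ValueError):
            LayerWindows([("a", (10.0, 10.0))])

    def test_window_beyond_detection_depth_marked_absent(self, small_config):
        pair, seg, flat = slab_flat(small_config, thickness=300.0)
        windows = LayerWindows([("near", (0.0, 250.0)), ("deep", (500.0, 900.0))])
        out = layer_birefringence(flat, windows, small_config, max_depth_px=int(300 * 1.4 / 2.75))
        assert out["near"] is not None
        assert out["deep"] is None

    def test_bladder_windows_follow_tissue_convention(self):
        w = dict(bladder_windows("normal").windows)
        assert w["urothelium"] == (0.0, 50.0)
        assert w["LP"] == (50.0, 250.0)  # 200 um below the 50-um urothelium
        assert dict(bladder_windows("diseased").windows)["fused"] == (0.0, 450.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(1.40e-4, 1.01e-4, 38.6), (1.37e-4, 1.01e-4, 35.6), (2.0, 2.0, 0.0)],
    )
    def test_reference_values(self, test, ref, expected):
        assert percent_change(test, ref) == pytest.approx(expected, abs=0.05)

    def test_signed_and_zero_reference(self):
        assert percent_change(0.5, 1.0) == pytest.approx(-50.0)
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)
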