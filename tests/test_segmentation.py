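"""Otsu thresholding, surface detection, flattening, thickness conversion."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from psoct import (
    ImagingConfig,
    detect_surfaces,
    flatten,
    make_slab_model,
    otsu_threshold,
    pixels_to_physical_thickness,
    simulate_bscan,
    unflatten,
)
from psoct.segmentation import image_histogram
from psoct.simulate import NoiseModel


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class-variance maximization."""
    h = np.asarray(hist, dtype=float)
    bins = np.arange(h.size)
    total = h.sum()
    best_t, best_v = None, -np.inf
    for t in range(1, h.size):
        w0 = h[:t].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (h[:t] * bins[:t]).sum() / h[:t].sum()
        mu1 = (h[t:] * bins[t:]).sum() / h[t:].sum()
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_point_histogram_separates_classes(self):
        h = np.zeros(256)
        h[10], h[200] = 40, 60
        t = otsu_threshold(h)
        assert 10 < t <= 200  # every split in that range is co-optimal; lowest returned
        assert t == 11

    def test_matches_brute_force_on_random_histograms(self):
        """Property: equals exhaustive search on 200 random histograms."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            nbins = int(rng.integers(8, 256))
            hist = rng.integers(0, 50, size=nbins)
            if np.count_nonzero(hist) < 2:
                hist[[0, nbins - 1]] = 1
            t = otsu_threshold(hist)
            t_oracle = brute_force_otsu(hist)
            h = hist.astype(float)
            bins = np.arange(nbins)

            def bcv(t):
                w0 = h[:t].sum()
                w1 = h[t:].sum()
                mu0 = (h[:t] * bins[:t]).sum() / w0
                mu1 = (h[t:] * bins[t:]).sum() / w1
                return w0 * w1 * (mu0 - mu1) ** 2

            assert bcv(t) == pytest.approx(bcv(t_oracle), rel=1e-12)
            assert t <= t_oracle  # smallest co-optimal index

    def test_mirrored_histogram_tie_break_returns_lower(self):
        rng = np.random.default_rng(3)
        h = rng.integers(0, 100, size=128)
        hist = np.concatenate([h, h[::-1]]).astype(float)
        t = otsu_threshold(hist)
        mirror = 256 - t
        bins = np.arange(256)

        def bcv(t):
            w0, w1 = hist[:t].sum(), hist[t:].sum()
            mu0 = (hist[:t] * bins[:t]).sum() / w0
            mu1 = (hist[t:] * bins[t:]).sum() / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        assert bcv(t) == pytest.approx(bcv(mirror), rel=1e-9)
        assert t <= mirror

    def test_agrees_with_skimage_on_an_image(self):
        rng = np.random.default_rng(11)
        img = np.concatenate([rng.normal(40, 6, 3000), rng.normal(180, 12, 2000)])
        img = np.clip(img, 0, 255).reshape(50, 100)
        counts, lo, hi = image_histogram(img, 256)
        t = otsu_threshold(counts)
        ours = lo + t * (hi - lo) / 256
        theirs = skimage_otsu(img, nbins=256)
        assert ours == pytest.approx(theirs, abs=(hi - lo) / 256 * 2)

    def test_single_valued_image_is_an_error(self):
        with pytest.raises(ValueError):
            image_histogram(np.ones((8, 8)))
        with pytest.raises(ValueError):
            h = np.zeros(256)
            h[5] = 10
            otsu_threshold(h)


class TestDetectSurfaces:
    def test_flat_surface_found_exactly_noise_free(self, small_config):
        model = make_slab_model(500.0, surface_profile=np.full(64, 110.0))
        pair = simulate_bscan(model, small_config, NoiseModel.off())
        seg = detect_surfaces(pair)
        assert np.all(seg.valid)
        assert np.all(seg.top_index == round(110.0 / 2.75))

    def test_whole_pixel_surface_profile_recovered_exactly(self, small_config):
        rows = np.arange(64) % 20 + 10  # arbitrary whole-pixel heights
        profile = rows * small_config.axial_pixel_spacing_air_um
        model = make_slab_model(500.0, surface_profile=profile)
        pair = simulate_bscan(model, small_config, NoiseModel.off())
        # smoothing off: the speckle filter intentionally blurs abrupt
        # column-to-column surface jumps, so exactness is a noise-free claim
        seg = detect_surfaces(pair, smoothing_halfwidth=0)
        assert np.array_equal(seg.top_index, rows)

    def test_speckle_surface_within_two_pixels(self, small_config):
        model = make_slab_model(500.0, surface_profile=np.full(64, 110.0))
        pair = simulate_bscan(model, small_config, NoiseModel(True, 2.0, 1e-3, 5))
        seg = detect_surfaces(pair)
        truth = round(110.0 / 2.75)
        hits = np.abs(seg.top_index[seg.valid] - truth) <= 2
        assert seg.valid.mean() >= 0.99
        assert hits.mean() >= 0.99

    def test_all_background_columns_flagged_invalid(self, small_config):
        model = make_slab_model(500.0, surface_profile=np.full(64, 110.0))
        pair = simulate_bscan(model, small_config, NoiseModel(False, 0.0, 1e-3, 0))
        pair.intensity[:, 9:12] = 1e-3  # erase the sample in a 3-column band
        seg = detect_surfaces(pair)
        assert not seg.valid[10]
        assert seg.top_index[10] == -1

    def test_bottom_visible_vs_max_detection_depth(self):
        config = ImagingConfig(depth_pixels=300, lateral_pixels=16)
        # shallow slab: bottom inside the frame -> bottom_index set
        shallow = make_slab_model(400.0, surface_profile=np.full(16, 55.0))
        seg = detect_surfaces(simulate_bscan(shallow, config, NoiseModel.off()))
        assert np.all(seg.bottom_index[seg.valid] >= 0)
        bottom_row = round(55.0 / 2.75) + round(400.0 * 1.4 / 2.75)
        assert np.all(np.abs(seg.bottom_index[seg.valid] - bottom_row) <= 1)
        # slab reaching the last row: trailing region stays suprathreshold
        config2 = ImagingConfig(depth_pixels=200, lateral_pixels=16)
        deep = make_slab_model(
            353.0, attenuation_mm=0.5, surface_profile=np.full(16, 55.0)
        )
        seg2 = detect_surfaces(simulate_bscan(deep, config2, NoiseModel.off()))
        assert np.all(seg2.bottom_index[seg2.valid] == -1)
        assert np.all(seg2.max_detection_depth[seg2.valid] == 199)


class TestFlatten:
    def test_already_flat_input_is_unchanged(self, small_config):
        model = make_slab_model(500.0)  # surface at row 0 everywhere
        pair = simulate_bscan(model, small_config, NoiseModel.off())
        seg = detect_surfaces(pair)
        flat = flatten(pair, seg)
        assert np.all(flat.shifts == 0)
        assert np.array_equal(flat.retardation, pair.retardation)

    def test_linear_ramp_flattens_to_zero_variance(self, small_config):
        ramp = np.arange(64) * small_config.axial_pixel_spacing_air_um  # 1 px/column
        model = make_slab_model(500.0, surface_profile=ramp + 2.75)
        pair = simulate_bscan(model, small_config, NoiseModel.off())
        seg = detect_surfaces(pair)
        flat = flatten(pair, seg)
        surface_rows = np.argmax(~np.isnan(flat.intensity), axis=0)
        assert np.var(surface_rows) == 0.0

    def test_unflatten_restores_sample_region_exactly(self, small_config):
        profile = (np.arange(64) % 15 + 5) * small_config.axial_pixel_spacing_air_um
        model = make_slab_model(500.0, birefringence=1e-4, surface_profile=profile)
        pair = simulate_bscan(model, small_config, NoiseModel(True, 2.0, 1e-3, 9))
        seg = detect_surfaces(pair)
        flat = flatten(pair, seg)
        inten, ret = unflatten(flat)
        for c in np.nonzero(seg.valid)[0]:
            t = seg.top_index[c]
            assert np.array_equal(inten[t:, c], pair.intensity[t:, c])
            assert np.array_equal(ret[t:, c], pair.retardation[t:, c])
            assert np.all(np.isnan(ret[:t, c]))

    def test_shape_mismatch_raises(self, small_config, normal_pair_clean):
        model = make_slab_model(500.0)
        pair = simulate_bscan(model, small_config, NoiseModel.off())
        seg = detect_surfaces(pair)
        with pytest.raises(ValueError):
            flatten(normal_pair_clean, seg)


class TestThicknessConversion:
    def test_conversion_arithmetic(self, config):
        assert pixels_to_physical_thickness(0, config) == 0.0
        assert pixels_to_physical_thickness(140, config, 1.4) == pytest.approx(275.0)
        assert pixels_to_physical_thickness(100, config, 1.0) == pytest.approx(275.0)

    def test_air_index_is_identity_scaling(self, config):
        n_px = 37
        assert pixels_to_physical_thickness(n_px, config, 1.0) == pytest.approx(
            n_px * config.axial_pixel_spacing_air_um
        )

    def test_domain_errors(self, config):
        with pytest.raises(ValueError):
            pixels_to_physical_thickness(-1, config)
        with pytest.raises(ValueError):
            pixels_to_physical_thickness(10, config, refractive_index=0.9)
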