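"""Preprocessing operators against brute-force oracles and closed forms."""

import numpy as np
import pytest

from retimorph.imaging_core import (
    Image,
    PreprocessConfig,
    _local_histograms,
    _quantise,
    adjust_gamma,
    apply_artefact_mask,
    attribute_tophat,
    despeckle,
    local_threshold,
    remove_outliers,
)


def _img(arr, **kw):
    return Image(np.asarray(arr, dtype=float), **kw)


# ---------------------------------------------------------------------------
# artefact mask
# ---------------------------------------------------------------------------


class TestArtefactMask:
    def test_all_true_mask_is_identity(self, rng):
        img = _img(rng.random((20, 20)))
        out = apply_artefact_mask(img, np.ones((20, 20), bool))
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert out.analysed_mask.all()

    def test_all_false_mask_zeroes_everything(self, rng):
        img = _img(rng.random((20, 20)))
        out = apply_artefact_mask(img, np.zeros((20, 20), bool))
        assert not out.pixels.any()
        assert not out.analysed_mask.any()

    def test_block_exclusion_reduces_analysed_count_exactly(self, rng):
        img = _img(rng.random((40, 40)))
        mask = np.ones((40, 40), bool)
        mask[5:15, 7:17] = False
        out = apply_artefact_mask(img, mask)
        assert out.analysed_mask.sum() == 40 * 40 - 100
        assert (out.pixels[5:15, 7:17] == 0).all()

    def test_dimension_mismatch_raises(self, rng):
        img = _img(rng.random((10, 10)))
        with pytest.raises(ValueError, match="shape"):
            apply_artefact_mask(img, np.ones((9, 10), bool))


# ---------------------------------------------------------------------------
# despeckle / remove outliers
# ---------------------------------------------------------------------------


def _median3x3_oracle(arr):
    """Naive sort-based 3x3 median with symmetric (reflect) padding."""
    padded = np.pad(arr, 1, mode="symmetric")
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = sorted(padded[i : i + 3, j : j + 3].ravel())[4]
    return out


class TestDespeckle:
    def test_constant_image_unchanged(self):
        img = _img(np.full((12, 12), 0.4))
        np.testing.assert_array_equal(despeckle(img).pixels, img.pixels)

    def test_single_bright_pixel_removed(self):
        arr = np.full((9, 9), 0.2)
        arr[4, 4] = 1.0
        out = despeckle(_img(arr))
        assert out.pixels[4, 4] == pytest.approx(0.2)

    def test_matches_bruteforce_median_oracle(self, rng):
        arr = rng.random((16, 16))
        out = despeckle(_img(arr))
        np.testing.assert_allclose(out.pixels, _median3x3_oracle(arr), atol=1e-12)


class TestRemoveOutliers:
    def test_huge_threshold_is_identity(self, rng):
        img = _img(rng.random((15, 15)))
        out = remove_outliers(img, radius=2, threshold=2.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_isolated_spike_replaced_by_local_median(self):
        arr = np.full((11, 11), 0.3)
        arr[5, 5] = 0.9  # 0.6 above the median, threshold 0.25
        out = remove_outliers(_img(arr), radius=2, threshold=0.25)
        assert out.pixels[5, 5] == pytest.approx(0.3)

    def test_matches_per_pixel_bruteforce_oracle(self, rng):
        arr = rng.random((14, 14))
        radius, thr = 2, 0.2
        out = remove_outliers(_img(arr), radius=radius, threshold=thr)
        padded = np.pad(arr, radius, mode="symmetric")
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        disc = (xx**2 + yy**2) <= radius**2
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                window = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
                med = np.median(window[disc])
                expected = med if arr[i, j] - med > thr else arr[i, j]
                assert out.pixels[i, j] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# gamma
# ---------------------------------------------------------------------------


class TestGamma:
    def test_gamma_one_is_identity(self, rng):
        img = _img(rng.random((10, 10)))
        np.testing.assert_allclose(adjust_gamma(img, 1.0).pixels, img.pixels)

    @pytest.mark.parametrize("gamma", [0.3, 0.8, 1.0, 2.2])
    def test_endpoints_fixed_for_any_gamma(self, rng, gamma):
        arr = 0.05 + 0.89 * rng.random((10, 10))
        arr.flat[0], arr.flat[-1] = 0.05, 0.95
        out = adjust_gamma(_img(arr), gamma)
        assert out.pixels.min() == pytest.approx(0.05)
        assert out.pixels.max() == pytest.approx(0.95)

    def test_midtone_value_gamma_half(self):
        # 8-bit analogue: 255 * (128/255)**0.5 ~ 180.6
        arr = np.zeros((2, 2))
        arr[0, 0], arr[0, 1], arr[1, 0] = 255.0, 128.0, 0.0
        out = adjust_gamma(_img(arr), 0.5)
        assert out.pixels[0, 1] == pytest.approx(255 * (128 / 255) ** 0.5, abs=0.01)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            adjust_gamma(_img(np.ones((4, 4))), 0.0)


# ---------------------------------------------------------------------------
# attribute top-hat
# ---------------------------------------------------------------------------


class TestAttributeTophat:
    def test_constant_image_maps_to_zero(self):
        out = attribute_tophat(_img(np.full((30, 30), 0.7)), area_lambda=100)
        assert not out.pixels.any()

    def test_small_blob_retained_at_contrast_background_flattened(self):
        arr = np.full((40, 40), 0.2)
        arr[10:15, 10:15] = 0.9  # 25 px < lambda
        out = attribute_tophat(_img(arr), area_lambda=100)
        np.testing.assert_allclose(out.pixels[10:15, 10:15], 0.7, atol=1e-12)
        outside = np.ones((40, 40), bool)
        outside[10:15, 10:15] = False
        assert np.abs(out.pixels[outside]).max() < 1e-12

    def test_smooth_ramp_suppressed(self):
        ramp = np.tile(np.linspace(0.1, 0.9, 50), (50, 1))
        out = attribute_tophat(_img(ramp), area_lambda=100)
        # the ramp has no connected bright structure smaller than lambda
        assert out.pixels.max() < 0.9 - 0.1

    def test_output_nonnegative_and_shape_preserved(self, rng):
        img = _img(rng.random((25, 25)), scale_um_per_px=0.5)
        out = attribute_tophat(img, area_lambda=50)
        assert out.pixels.shape == img.pixels.shape
        assert out.scale_um_per_px == 0.5
        assert (out.pixels >= 0).all()


# ---------------------------------------------------------------------------
# local auto-threshold
# ---------------------------------------------------------------------------


def _isodata_oracle(hist):
    """Plain-Python iterative intermeans on one histogram."""
    n_bins = len(hist)
    occupied = [b for b in range(n_bins) if hist[b] > 0]
    if len(occupied) <= 1:
        return n_bins - 1
    lo, hi = occupied[0], occupied[-1]
    t = min(max((lo + hi) // 2, lo), hi - 1)
    for _ in range(256):
        n_low = s_low = n_high = s_high = 0.0
        for b in range(n_bins):
            if b <= t:
                n_low += hist[b]
                s_low += b * hist[b]
            else:
                n_high += hist[b]
                s_high += b * hist[b]
        t_new = int(np.floor((s_low / n_low + s_high / n_high) / 2.0 + 0.5))
        t_new = min(max(t_new, lo), hi - 1)
        if t_new == t:
            break
        t = t_new
    return t


def _moments_oracle(hist):
    """Plain-Python Tsai moment-preserving threshold on one histogram."""
    n_bins = len(hist)
    if sum(1 for h in hist if h > 0) <= 1:
        return n_bins - 1
    total = float(sum(hist))
    m1 = sum(b * hist[b] for b in range(n_bins)) / total
    m2 = sum(b**2 * hist[b] for b in range(n_bins)) / total
    m3 = sum(b**3 * hist[b] for b in range(n_bins)) / total
    cd = m2 - m1 * m1
    if cd <= 0:
        return n_bins - 1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return n_bins - 1
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return n_bins - 1
    p0 = (z1 - m1) / (z1 - z0)
    acc = 0.0
    for b in range(n_bins):
        acc += hist[b] / total
        if acc > p0:
            return b
    return n_bins - 1


def _window_histograms_oracle(bins, radius, n_bins):
    """Histograms of each (2r+1)-square window via explicit padding."""
    padded = np.pad(bins, radius, mode="symmetric")
    h, w = bins.shape
    out = np.zeros((h, w, n_bins), dtype=int)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            out[i, j] = np.bincount(window.ravel(), minlength=n_bins)
    return out


class TestLocalThreshold:
    def test_constant_image_is_all_background(self):
        img = _img(np.full((20, 20), 0.5))
        for method in ("moments", "isodata"):
            assert not local_threshold(img, method, radius=3).any()

    def test_two_level_image_isodata_splits_at_midpoint(self):
        arr = np.full((30, 30), 0.2)
        arr[:, 15:] = 0.8
        img = _img(arr)
        fg = local_threshold(img, "isodata", radius=20)
        # radius large enough that every window sees both levels
        np.testing.assert_array_equal(fg, arr > 0.5)

    @pytest.mark.parametrize("method,oracle", [
        ("isodata", _isodata_oracle),
        ("moments", _moments_oracle),
    ])
    def test_matches_histogram_level_oracle(self, rng, method, oracle):
        n_bins = 64
        arr = rng.random((32, 32))
        img = _img(arr)
        radius = 4
        fg = local_threshold(img, method, radius=radius, n_bins=n_bins)
        bins = _quantise(arr, n_bins)
        hists = _window_histograms_oracle(bins, radius, n_bins)
        expected = np.zeros_like(fg)
        for i in range(32):
            for j in range(32):
                t = oracle(list(hists[i, j]))
                expected[i, j] = bins[i, j] > t
        np.testing.assert_array_equal(fg, expected)

    def test_isodata_invariant_to_affine_rescaling(self, rng):
        arr = rng.random((24, 24))
        a = local_threshold(_img(arr), "isodata", radius=5)
        b = local_threshold(_img(2.5 * arr + 0.7), "isodata", radius=5)
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            local_threshold(_img(rng.random((8, 8))), "otsu", radius=2)

    def test_min_contrast_suppresses_pure_noise(self, rng):
        arr = 0.5 + 0.01 * rng.standard_normal((40, 40))
        arr[10:20, 10:20] += 0.5  # one genuine bright block
        img = _img(arr)
        fg = local_threshold(img, "moments", radius=6, min_contrast=0.2)
        assert fg[12:18, 12:18].all()
        border = fg.copy()
        border[5:25, 5:25] = False
        assert not border.any()


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(gamma=-1)
        with pytest.raises(ValueError):
            PreprocessConfig(threshold_radius=0)
        with pytest.raises(ValueError):
            PreprocessConfig(threshold_method="otsu")

    def test_preprocessing_preserves_dimensions_and_scale(self, rng):
        from retimorph.imaging_core import preprocess

        img = _img(rng.random((30, 30)), scale_um_per_px=0.321)
        out = preprocess(img, PreprocessConfig())
        assert out.pixels.shape == (30, 30)
        assert out.scale_um_per_px == 0.321
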