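import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from mitomorph.image_io import RawImage
from mitomorph.preprocess import (
    ClaheParams,
    DegenerateImageError,
    clahe,
    denoise_and_blur,
    otsu_threshold,
    otsu_threshold_value,
)


def _img(arr, bit_depth=8, **kw):
    return RawImage(pixels=np.asarray(arr), bit_depth=bit_depth, **kw)


def brute_force_otsu(counts):
    """Exhaustive between-class-variance scan, ties to the smallest t."""
    counts = np.asarray(counts, dtype=float)
    best_t, best_v = None, -1.0
    levels = np.arange(len(counts))
    for t in range(len(counts) - 1):
        w0, w1 = counts[: t + 1].sum(), counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestClahe:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClaheParams(kernel_size=(1, 10))
        with pytest.raises(ValueError):
            ClaheParams(clip_limit=0.0)
        with pytest.raises(ValueError):
            ClaheParams(n_bins=1)

    def test_defaults_match_published_settings(self):
        p = ClaheParams()
        assert p.kernel_size == (10, 10)
        assert p.clip_limit == 0.02
        assert p.n_bins == 256

    def test_constant_image_stays_constant(self):
        img = _img(np.full((40, 40), 90, dtype=np.uint8))
        out = clahe(img)
        assert len(np.unique(out.pixels)) == 1

    def test_shape_dtype_and_determinism(self):
        rng = np.random.default_rng(0)
        img = _img(rng.integers(0, 4000, (64, 64)).astype(np.uint16), bit_depth=16)
        a = clahe(img)
        b = clahe(img)
        assert a.pixels.shape == img.shape and a.pixels.dtype == img.pixels.dtype
        assert a.bit_depth == 16
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_kernel_larger_than_image_rejected(self):
        img = _img(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            clahe(img, ClaheParams(kernel_size=(16, 16)))

    def test_illumination_gradient_is_evened_out(self):
        """Bright spots under a 2x gradient: CLAHE must pull the ratio of
        spot intensities between the brightest and dimmest quadrant
        strictly closer to 1."""
        h, w = 120, 120
        base = np.full((h, w), 500.0)
        spots = []
        rng = np.random.default_rng(5)
        for _ in range(30):
            r, c = rng.integers(6, h - 6), rng.integers(6, w - 6)
            spots.append((r, c))
            base[r - 1 : r + 2, c - 1 : c + 2] = 8000.0
        ramp = 1.0 + (np.arange(w) / (w - 1))[None, :]  # 1x .. 2x left-to-right
        img = _img(np.rint(base * ramp).astype(np.uint16), bit_depth=16)
        out = clahe(img)

        def spot_ratio(pixels):
            left = [pixels[r, c] for r, c in spots if c < w // 4]
            right = [pixels[r, c] for r, c in spots if c >= 3 * w // 4]
            return np.mean(right) / np.mean(left)

        before = spot_ratio(img.pixels.astype(float))
        after = spot_ratio(out.pixels.astype(float))
        assert abs(after - 1) < abs(before - 1)


class TestOtsu:
    def test_separable_bimodal_histogram(self):
        vals = np.concatenate([np.full(100, 10), np.full(100, 200)])
        img = _img(vals.reshape(10, 20).astype(np.uint8))
        mask = otsu_threshold(img)
        assert int(mask.pixels.sum()) == 100
        assert (img.pixels[mask.pixels] == 200).all()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 100_000))
    def test_matches_exhaustive_scan_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 12, size=256)
        counts[rng.integers(0, 256)] += 20  # ensure non-degenerate
        counts[rng.integers(0, 256)] += 20
        vals = np.repeat(np.arange(256, dtype=np.uint8), counts)
        if len(np.unique(vals)) < 2:
            return
        assert otsu_threshold_value(vals, 255) == brute_force_otsu(counts)

    def test_agrees_with_reference_implementation_8bit(self):
        rng = np.random.default_rng(7)
        arr = np.concatenate(
            [rng.normal(60, 12, 3000), rng.normal(190, 15, 1500)]
        ).clip(0, 255).astype(np.uint8)
        t_ref = skimage_otsu(arr, nbins=256)
        t_here = otsu_threshold_value(arr, 255)
        assert abs(int(t_here) - int(t_ref)) <= 1  # bin-center convention

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(_img(np.full((10, 10), 7, dtype=np.uint8)))

    def test_mask_invariant_under_constant_shift(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 200, (30, 30)).astype(np.uint8)
        m0 = otsu_threshold(_img(arr))
        m1 = otsu_threshold(_img(arr + 50))
        np.testing.assert_array_equal(m0.pixels, m1.pixels)

    def test_adaptive_mode_recovers_objects_under_gradient(self):
        rng = np.random.default_rng(3)
        base = np.full((120, 120), 30.0)
        truth = np.zeros((120, 120), dtype=bool)
        for r, c in [(20, 20), (60, 90), (100, 40)]:
            truth[r - 2 : r + 3, c - 2 : c + 3] = True
        base[truth] = 220.0
        ramp = 1.0 + 0.8 * (np.arange(120) / 119)[None, :]
        img = _img(np.clip(np.rint(base * ramp), 0, 255).astype(np.uint8))
        mask = otsu_threshold(img, mode="adaptive", window=40)
        assert (mask.pixels & truth).sum() >= 0.95 * truth.sum()

    def test_synthetic_rod_foreground_recovery(self, small_scene):
        from mitomorph.preprocess import clahe as _clahe

        spec, img, truth = small_scene
        mask = otsu_threshold(_clahe(img))
        covered = (mask.pixels & truth.stroke_mask).sum()
        assert covered >= 0.95 * truth.stroke_mask.sum()


class TestDenoiseAndBlur:
    def test_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        img = _img(rng.integers(0, 255, (20, 20)).astype(np.uint8))
        out = denoise_and_blur(img, min_feature=0, sigma=0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_single_bright_pixel_suppressed_by_opening(self):
        arr = np.full((21, 21), 20, dtype=np.uint8)
        arr[10, 10] = 250
        out = denoise_and_blur(_img(arr), min_feature=2, sigma=0)
        assert out.pixels[10, 10] == 20

    def test_two_cell_field_blurs_to_two_maxima(self):
        from skimage.feature import peak_local_max

        arr = np.full((80, 160), 10.0)
        arr[30:50, 20:40] += 150.0
        arr[30:50, 120:140] += 150.0
        img = _img(arr.astype(np.uint8))
        out = denoise_and_blur(img, min_feature=0, sigma=6)
        peaks = peak_local_max(out.pixels.astype(float), min_distance=15,
                               threshold_abs=30)
        assert len(peaks) == 2

    def test_negative_parameters_rejected(self):
        img = _img(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            denoise_and_blur(img, min_feature=-1, sigma=0)
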