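"""Synthetic phantom generator and preprocessing chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from usanomaly import (
    LesionSpec,
    PhantomConfig,
    apply_speckle,
    gamma_correct,
    gaussian_denoise,
    generate_background,
    generate_dataset,
    insert_lesion,
    normalize_pixels,
)


class TestBackground:
    def test_range_and_shape(self):
        bg = generate_background(64, 64, seed=1, smoothness=8)
        assert bg.shape == (64, 64)
        assert bg.min() >= 0.2 and bg.max() <= 0.8

    def test_deterministic(self):
        a = generate_background(64, 64, seed=1)
        b = generate_background(64, 64, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_seeds_differ(self):
        a = generate_background(64, 64, seed=1)
        b = generate_background(64, 64, seed=2)
        assert np.mean(a != b) >= 0.01

    @pytest.mark.parametrize("h,w", [(4, 64), (64, 7), (0, 0)])
    def test_small_dims_rejected(self, h, w):
        with pytest.raises(ValueError):
            generate_background(h, w, seed=0)


class TestSpeckle:
    def test_zero_noise_limit(self):
        img = generate_background(32, 32, seed=3)
        out = apply_speckle(img, seed=0, scale=1e-8)
        assert np.abs(out - img).max() < 1e-6

    def test_unit_mean_factor(self):
        # Monte-Carlo check: multiplicative factor has unit mean, so a
        # constant 0.5 image keeps its mean to within 3 standard errors
        img = np.full((100, 100), 0.5)
        out = apply_speckle(img, seed=42, scale=0.3)
        # sd of the unit-mean Rayleigh factor is sqrt((4-pi)/pi)
        se = 0.5 * 0.3 * math.sqrt((4 - math.pi) / math.pi) / 100
        assert abs(out.mean() - 0.5) < 3 * se

    def test_clipped_to_unit_interval(self):
        img = generate_background(32, 32, seed=3)
        out = apply_speckle(img, seed=1, scale=5.0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            apply_speckle(np.full((8, 8), 0.5), seed=0, scale=0.0)


class TestInsertLesion:
    def test_zero_drop_leaves_image_marks_mask(self):
        img = np.full((64, 64), 0.6)
        spec = LesionSpec(center=(32, 32), semi_axes=(10, 10), intensity_drop=0.0)
        out, mask = insert_lesion(img, spec)
        np.testing.assert_allclose(out, img)
        assert mask.sum() > 0

    def test_hard_ellipse_against_bruteforce(self):
        # independent oracle: explicit pixel-in-ellipse double loop
        img = np.full((64, 64), 0.6)
        spec = LesionSpec(center=(32, 32), semi_axes=(10, 10),
                          intensity_drop=0.5, edge_softness=0.0)
        out, mask = insert_lesion(img, spec)
        assert out[32, 32] == pytest.approx(0.3)
        assert out[0, 0] == pytest.approx(0.6)
        expected = 0
        for r in range(64):
            for c in range(64):
                if ((r - 32) / 10) ** 2 + ((c - 32) / 10) ** 2 <= 1.0:
                    expected += 1
                    assert mask[r, c] == 1
                else:
                    assert mask[r, c] == 0
        assert mask.sum() == expected

    def test_rotated_ellipse_matches_bruteforce(self):
        img = np.full((48, 48), 0.5)
        spec = LesionSpec(center=(24.0, 22.0), semi_axes=(9.0, 5.0),
                          rotation=0.7, intensity_drop=0.4, edge_softness=0.0)
        _, mask = insert_lesion(img, spec)
        cosr, sinr = math.cos(0.7), math.sin(0.7)
        for r in range(48):
            for c in range(48):
                u = (r - 24.0) * cosr + (c - 22.0) * sinr
                v = -(r - 24.0) * sinr + (c - 22.0) * cosr
                assert mask[r, c] == ((u / 9.0) ** 2 + (v / 5.0) ** 2 <= 1.0)

    def test_out_of_bounds_rejected(self):
        img = np.full((32, 32), 0.5)
        spec = LesionSpec(center=(5, 16), semi_axes=(10, 10), intensity_drop=0.5)
        with pytest.raises(ValueError):
            insert_lesion(img, spec)


class TestGenerateDataset:
    def test_counts_and_mask_invariants(self):
        cfg = PhantomConfig(height=32, width=32, n_train=5, n_val=2, n_test=3,
                            lesion_area_min_px=20, lesion_area_max_px=60, seed=1)
        ds = generate_dataset(cfg)
        assert (len(ds.train_normal), len(ds.val_normal), len(ds.test_abnormal)) == (5, 2, 3)
        for img in ds.train_normal + ds.val_normal:
            assert img.min() >= 0 and img.max() <= 1
        for img, mask in ds.test_abnormal:
            assert mask.sum() > 0
            assert set(np.unique(mask)) <= {0, 1}

    def test_deterministic(self):
        cfg = PhantomConfig(height=32, width=32, n_train=3, n_val=2, n_test=2,
                            lesion_area_min_px=20, lesion_area_max_px=60, seed=9)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for x, y in zip(a.train_normal, b.train_normal):
            np.testing.assert_array_equal(x, y)
        for (xi, xm), (yi, ym) in zip(a.test_abnormal, b.test_abnormal):
            np.testing.assert_array_equal(xi, yi)
            np.testing.assert_array_equal(xm, ym)

    def test_lesion_contrast(self):
        """Hypoechoic contract: lesions are darker than a surrounding annulus."""
        cfg = PhantomConfig(height=48, width=48, n_train=1, n_val=1, n_test=8,
                            lesion_area_min_px=40, lesion_area_max_px=120,
                            lesion_drop_min=0.4, lesion_drop_max=0.7,
                            lesion_softness=0.0, seed=3)
        ds = generate_dataset(cfg)
        for img, mask in ds.test_abnormal:
            annulus = ndimage.binary_dilation(mask, iterations=3) & ~mask.astype(bool)
            assert img[mask > 0].mean() < img[annulus].mean()

    def test_three_channel(self):
        cfg = PhantomConfig(height=32, width=32, channels=3, n_train=2, n_val=1,
                            n_test=1, lesion_area_min_px=20, lesion_area_max_px=40,
                            seed=4)
        ds = generate_dataset(cfg)
        img, mask = ds.test_abnormal[0]
        assert img.shape == (3, 32, 32)
        assert mask.shape == (32, 32)
        np.testing.assert_array_equal(img[0], img[1])  # replicated base grid

    def test_infeasible_lesion_rejected(self):
        cfg = PhantomConfig(height=16, width=16, n_train=1, n_val=1, n_test=1,
                            lesion_area_min_px=50, lesion_area_max_px=400)
        with pytest.raises(ValueError):
            generate_dataset(cfg)


class TestPreprocessing:
    @pytest.mark.parametrize("raw,expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_normalize_endpoints(self, raw, expected):
        assert normalize_pixels(np.array([raw]))[0] == pytest.approx(expected)

    def test_normalize_out_of_range(self):
        with pytest.raises(ValueError):
            normalize_pixels(np.array([256]))

    def test_denoise_identity_cases(self):
        img = generate_background(16, 16, seed=1)
        np.testing.assert_array_equal(gaussian_denoise(img, 0.0), img)
        const = np.full((16, 16), 0.4)
        np.testing.assert_allclose(gaussian_denoise(const, 2.0), const)

    def test_denoise_matches_explicit_kernel(self):
        # oracle: hand-built truncated discrete Gaussian kernel (radius 4*sigma)
        sigma = 1.0
        r = int(4.0 * sigma + 0.5)
        i = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (i / sigma) ** 2)
        k1 /= k1.sum()
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = gaussian_denoise(img, sigma)
        assert out[4, 4] == pytest.approx(k1[r] ** 2, abs=1e-12)

    @pytest.mark.parametrize("value,gamma,expected", [(0.25, 0.5, 0.5), (0.3, 1.0, 0.3)])
    def test_gamma_hand_values(self, value, gamma, expected):
        out = gamma_correct(np.array([[value] * 8] * 8), gamma)
        assert out[0, 0] == pytest.approx(expected)

    def test_gamma_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(np.full((8, 8), 0.5), 0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=0.3, max_value=2.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_chain_stays_in_unit_interval(self, seed, gamma):
        img = apply_speckle(generate_background(16, 16, seed=seed), seed=seed, scale=0.5)
        out = gamma_correct(gaussian_denoise(img, 1.0), gamma)
        assert out.min() >= 0.0 and out.max() <= 1.0
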