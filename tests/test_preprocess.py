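"""Preprocessing: background removal, padding, resizing, SSIM/PSNR."""

import numpy as np
import pytest
from scipy import ndimage

from ttcseg import preprocess


class TestRemoveBackground:
    def test_recovers_generator_foreground(self, small_cohort):
        exps, _ = small_cohort
        s = exps[0].slices[2]
        img, mask = s.apical_image, s.apical_mask
        cleaned, fg = preprocess.remove_background(img)
        truth = ndimage.binary_fill_holes(mask != 0)
        iou = (fg & truth).sum() / (fg | truth).sum()
        assert iou >= 0.95
        assert cleaned.shape == img.shape
        np.testing.assert_array_equal(cleaned[~fg],
                                      np.zeros_like(cleaned[~fg]))

    def test_all_background_errors(self):
        img = np.full((80, 80, 3), 40, dtype=np.uint8)
        with pytest.raises(preprocess.NoForegroundError):
            preprocess.remove_background(img)

    def test_idempotent(self, small_cohort):
        exps, _ = small_cohort
        img = exps[0].slices[2].basal_image
        once, fg1 = preprocess.remove_background(img)
        twice, fg2 = preprocess.remove_background(once)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(fg1, fg2)


class TestPadResize:
    def test_pad_rectangle(self):
        img = np.random.default_rng(0).integers(0, 255, (100, 60, 3),
                                                dtype=np.uint8)
        out = preprocess.pad_to_square(img)
        assert out.shape == (100, 100, 3)
        left = (100 - 60) // 2
        np.testing.assert_array_equal(out[:, left:left + 60], img)
        assert (out[:, :left] == 0).all() and (out[:, left + 60:] == 0).all()

    def test_pad_square_identity(self):
        img = np.ones((64, 64, 3), dtype=np.uint8)
        np.testing.assert_array_equal(preprocess.pad_to_square(img), img)

    def test_resize_mask_class_closure(self, rng):
        mask = rng.choice([0, 2, 3], size=(768, 768)).astype(np.uint8)
        out = preprocess.resize_uniform(mask, 384, is_mask=True)
        assert out.shape == (384, 384)
        assert set(np.unique(out)) <= {0, 2, 3}

    def test_resize_identity(self, rng):
        img = rng.integers(0, 255, (96, 96, 3), dtype=np.uint8)
        np.testing.assert_array_equal(preprocess.resize_uniform(img, 96), img)

    def test_resize_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            preprocess.resize_uniform(np.zeros((10, 20)), 8)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        assert preprocess.ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.integers(0, 255, (64, 64), dtype=np.uint8)
        b = rng.integers(0, 255, (64, 64), dtype=np.uint8)
        assert preprocess.ssim(a, b) == pytest.approx(preprocess.ssim(b, a))

    def test_constant_offset_matches_closed_form(self):
        """For constant images every window is identical, so the windowed
        mean equals the single-window closed form
        (2 μx μy + C1) / (μx² + μy² + C1)."""
        a = np.full((16, 16), 100, dtype=np.uint8)
        b = np.full((16, 16), 150, dtype=np.uint8)
        c1 = (0.01 * 255) ** 2
        expected = (2 * 100 * 150 + c1) / (100**2 + 150**2 + c1)
        assert preprocess.ssim(a, b) == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            preprocess.ssim(np.zeros((8, 8)), np.zeros((9, 9)))

    def test_brute_force_small_instance(self, rng):
        """Uniform-window SSIM on a small pair equals a directly coded
        sliding-window evaluation of the definition."""
        a = rng.integers(0, 255, (12, 12), dtype=np.uint8)
        b = np.clip(a.astype(float) + rng.normal(0, 20, a.shape),
                    0, 255).astype(np.uint8)
        af, bf = a.astype(float), b.astype(float)
        win, c1, c2 = 7, (0.01 * 255) ** 2, (0.03 * 255) ** 2
        vals = []
        for i in range(12 - win + 1):
            for j in range(12 - win + 1):
                x = af[i:i + win, j:j + win]
                y = bf[i:i + win, j:j + win]
                mx, my = x.mean(), y.mean()
                vx, vy = x.var(ddof=1), y.var(ddof=1)
                cov = ((x - mx) * (y - my)).sum() / (win * win - 1)
                vals.append(((2 * mx * my + c1) * (2 * cov + c2))
                            / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
        assert preprocess.ssim(a, b) == pytest.approx(np.mean(vals), abs=1e-7)


class TestPSNR:
    def test_unit_difference(self):
        a = np.full((10, 10), 100, dtype=np.uint8)
        b = np.full((10, 10), 101, dtype=np.uint8)
        assert preprocess.psnr(a, b) == pytest.approx(20 * np.log10(255),
                                                      abs=1e-9)

    def test_identical_infinite(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        assert preprocess.psnr(img, img) == float("inf")

    def test_maximal_difference_zero_db(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.full((8, 8), 255, dtype=np.uint8)
        assert preprocess.psnr(a, b) == pytest.approx(0.0, abs=1e-12)


class TestQualityReport:
    def test_native_size_perfect(self, rng):
        imgs = [rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
                for _ in range(3)]
        qr = preprocess.quality_report(imgs, 64)
        assert all(v == 1.0 for v in qr.ssim_values)

    def test_median_order_statistic(self):
        qr = preprocess.QualityReport(ssim_values=[0.9, 1.0, 0.8],
                                      psnr_values=[30.0, 40.0, 35.0])
        assert qr.ssim_median == pytest.approx(0.9)
        assert qr.psnr_median == pytest.approx(35.0)

    def test_phantom_cohort_low_quality_loss(self, small_cohort):
        """Downsizing phantoms to 96 px and back keeps SSIM high."""
        exps, _ = small_cohort
        imgs = [img for e in exps for s in e.slices for _, img, _m in s.faces()]
        qr = preprocess.quality_report(imgs[:10], 96)
        assert qr.ssim_median >= 0.9
        assert qr.psnr_median > 20

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            preprocess.quality_report([], 64)
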