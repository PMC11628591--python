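"""Metric and agreement-statistic correctness against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from ttcseg import evalstats
from ttcseg.scheme import N_CLASSES

from oracles import (oracle_acc, oracle_ap, oracle_bf1, oracle_dsc,
                     oracle_weighted_acc)


class TestSegmentationMetrics:
    def test_dsc_hand_example(self):
        # P has 4 px of class 1, G has 4 px, overlap 2 -> DSC 0.5
        pred = np.zeros((4, 4), dtype=int)
        gt = np.zeros((4, 4), dtype=int)
        pred[0, 0:4] = 1
        gt[0, 2:4] = 1
        gt[1, 0:2] = 1
        assert evalstats.dsc(pred, gt, 1) == pytest.approx(0.5)

    def test_dsc_identity_and_disjoint(self):
        m = np.arange(16).reshape(4, 4) % N_CLASSES
        assert evalstats.dsc(m, m, 2) == 1.0
        a = np.zeros((3, 3), dtype=int)
        b = np.zeros((3, 3), dtype=int)
        a[0, 0] = 3
        b[2, 2] = 3
        assert evalstats.dsc(a, b, 3) == 0.0
        assert evalstats.dsc(a, b, 4) == 1.0  # absent from both

    def test_acc_hand_example(self):
        # 10 pixels, one false positive and one false negative -> 0.8
        pred = np.array([[1, 0, 0, 0, 0], [0, 0, 0, 1, 1]])
        gt = np.array([[0, 0, 0, 0, 0], [0, 0, 0, 1, 0]])
        pred_fn = gt.copy()
        pred_fn[1, 3] = 0       # false negative
        pred_fn[0, 0] = 1       # false positive
        assert evalstats.acc(pred_fn, gt, 1) == pytest.approx(0.8)

    def test_boundary_f1_shifted_square(self):
        """1-px-shifted square at tolerance 0 matches the exhaustive oracle."""
        gt = np.zeros((8, 8), dtype=int)
        gt[2:6, 2:6] = 3
        pred = np.zeros((8, 8), dtype=int)
        pred[2:6, 3:7] = 3
        for tol in (0.0, 1.0, 2.0):
            assert evalstats.boundary_f1(pred, gt, 3, tol) == pytest.approx(
                oracle_bf1(pred, gt, 3, tol), abs=1e-12)

    def test_boundary_f1_absence_conventions(self):
        a = np.zeros((5, 5), dtype=int)
        b = np.zeros((5, 5), dtype=int)
        assert evalstats.boundary_f1(a, b, 2) == 1.0
        b2 = b.copy()
        b2[2, 2] = 2
        assert evalstats.boundary_f1(a, b2, 2) == 0.0

    def test_ap_hand_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        got = evalstats.average_precision(scores, labels, 1)
        assert got == pytest.approx(5.0 / 6.0, abs=1e-9)
        assert got == pytest.approx(oracle_ap(scores, labels), abs=1e-9)

    def test_ap_all_ties_equals_prevalence(self):
        scores = np.full(20, 0.5)
        labels = (np.arange(20) < 7).astype(int)
        assert evalstats.average_precision(scores, labels, 1) == pytest.approx(
            7 / 20, abs=1e-9)

    def test_random_masks_agree_with_oracles(self, rng):
        for _ in range(25):
            h, w = rng.integers(3, 17, 2)
            pred = rng.integers(0, N_CLASSES, (h, w))
            gt = rng.integers(0, N_CLASSES, (h, w))
            tol = float(rng.integers(0, 3))
            for c in range(N_CLASSES):
                assert evalstats.dsc(pred, gt, c) == pytest.approx(
                    oracle_dsc(pred, gt, c), abs=1e-9)
                assert evalstats.acc(pred, gt, c) == pytest.approx(
                    oracle_acc(pred, gt, c), abs=1e-9)
                assert evalstats.boundary_f1(pred, gt, c, tol) == pytest.approx(
                    oracle_bf1(pred, gt, c, tol), abs=1e-9)
            assert evalstats.weighted_acc(pred, gt) == pytest.approx(
                oracle_weighted_acc(pred, gt), abs=1e-9)
            probs = rng.random((N_CLASSES, h, w))
            for c in range(N_CLASSES):
                if np.any(gt == c):
                    assert evalstats.average_precision(probs[c], gt, c) == \
                        pytest.approx(oracle_ap(probs[c], gt == c), abs=1e-9)

    def test_weighted_acc_bounded_by_class_accs(self, rng):
        pred = rng.integers(0, N_CLASSES, (12, 12))
        gt = rng.integers(0, N_CLASSES, (12, 12))
        accs = [evalstats.acc(pred, gt, c) for c in range(N_CLASSES)
                if np.any(gt == c)]
        w = evalstats.weighted_acc(pred, gt)
        assert min(accs) - 1e-12 <= w <= max(accs) + 1e-12

    def test_metrics_report_identity(self, rng):
        masks = [rng.integers(0, N_CLASSES, (16, 16)) for _ in range(3)]
        rep = evalstats.metrics_report(masks, masks)
        frame = rep.to_frame()
        assert frame.shape == (6, 4)          # 5 class rows + overall
        assert np.allclose(frame.to_numpy(dtype=float), 1.0)

    def test_mean_ap_warns_on_absent_class(self, rng):
        gt = np.zeros((8, 8), dtype=int)
        gt[:4] = 1
        probs = rng.random((N_CLASSES, 8, 8))
        with pytest.warns(UserWarning):
            val = evalstats.mean_ap(probs, gt)
        assert 0.0 <= val <= 1.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            evalstats.dsc(np.zeros((3, 3)), np.zeros((4, 4)), 0)
        with pytest.raises(ValueError):
            evalstats.weighted_acc(np.zeros((3, 3)), np.zeros((4, 3)))


class TestAgreementStatistics:
    def test_pearson_linreg_exact_line(self):
        x = np.array([0.0, 1.0, 2.0])
        r, slope, intercept = evalstats.pearson_linreg(x, 2 * x + 1)
        assert (r, slope, intercept) == pytest.approx((1.0, 2.0, 1.0))

    def test_pearson_zero_variance_error(self):
        with pytest.raises(ValueError):
            evalstats.pearson_linreg([1, 1, 1], [1, 2, 3])

    def test_bland_altman_hand_triple(self):
        # differences (1,2,3): bias 2, SD 1, limits 2 -/+ 1.96
        bias, lo, hi = evalstats.bland_altman([2, 4, 6], [1, 2, 3])
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(0.04)
        assert hi == pytest.approx(3.96)

    def test_bland_altman_identity(self):
        bias, lo, hi = evalstats.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == lo == hi == 0.0

    def test_bland_altman_limits_definitional(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        bias, lo, hi = evalstats.bland_altman(a, b)
        sd = np.std(a - b, ddof=1)
        assert hi - bias == pytest.approx(1.96 * sd)
        assert bias - lo == pytest.approx(1.96 * sd)

    def test_bland_altman_coverage_large_normal(self, rng):
        d = rng.normal(0, 2, 5000)
        a = rng.normal(10, 5, 5000)
        bias, lo, hi = evalstats.bland_altman(a + d, a)
        frac = np.mean((d >= lo) & (d <= hi))
        assert frac > 0.93

    def test_ancova_identity_sentinel(self):
        x = np.linspace(0, 10, 20)
        f, p = evalstats.ancova_identity(x, x)
        assert p == 1.0

    def test_ancova_rejects_shift(self, rng):
        x = np.linspace(0, 50, 50)
        y = x + 10 + rng.normal(0, 1, 50)
        _, p = evalstats.ancova_identity(x, y)
        assert p < 0.05

    def test_ancova_accepts_identity_with_noise(self, rng):
        x = np.linspace(0, 50, 50)
        y = x + rng.normal(0, 1, 50)
        _, p = evalstats.ancova_identity(x, y)
        assert p > 0.05

    def test_ks_normal_sample(self, rng):
        stat, p = evalstats.ks_normality(rng.normal(3, 2, 500))
        assert 0 <= stat <= 1
        assert p > 0.05

    def test_ks_bimodal_rejects(self, rng):
        x = np.concatenate([rng.normal(-3, 0.5, 100), rng.normal(3, 0.5, 100)])
        _, p = evalstats.ks_normality(x)
        assert p < 0.05

    def test_ks_constant_errors(self):
        with pytest.raises(ValueError):
            evalstats.ks_normality(np.ones(10))

    def test_agreement_report_self(self, rng):
        a = rng.uniform(0, 70, 30)
        rep = evalstats.agreement_report(a, a.copy())
        assert rep.r == pytest.approx(1.0)
        assert rep.bias == rep.loa_low == rep.loa_high == 0.0
        assert rep.ancova_p == 1.0
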