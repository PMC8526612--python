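"""Calibration: ROC/PR construction, Youden and max-F1 selection, and
their exact agreement with brute-force threshold search."""

import warnings

import numpy as np
import pytest

from metseg.calibration import (
    PRCurve,
    max_f1_threshold,
    pr_curve_pixels,
    roc_curve,
    youden_threshold,
)
from metseg.model_bank import SimulatedBank
from metseg.phantom import Degradation
from metseg.preprocessing import ProcessedSlice


def brute_force_youden(labels, scores):
    """Independent oracle: enumerate every unique score as threshold with
    the (score >= t) rule; smallest threshold among the J maximizers."""
    labels = np.asarray(labels, bool)
    best_j, best_t = -np.inf, None
    for t in sorted(set(scores)):
        pred = np.asarray(scores) >= t
        tpr = (pred & labels).sum() / labels.sum()
        fpr = (pred & ~labels).sum() / (~labels).sum()
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t


def brute_force_max_f1(truth, values):
    """Oracle for the pixel rule (value > t) over every unique value."""
    truth = np.asarray(truth, bool)
    best_f1, best_t = -1.0, None
    for t in sorted(set(values)):
        pred = np.asarray(values) > t
        tp = (pred & truth).sum()
        denom = pred.sum() + truth.sum()
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, t
    return best_t


def concordance_auc(labels, scores):
    """Pairwise concordance with half credit for ties."""
    labels = np.asarray(labels, bool)
    pos = np.asarray(scores)[labels]
    neg = np.asarray(scores)[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return wins / (len(pos) * len(neg))


class TestROC:
    @pytest.mark.parametrize(
        "labels, scores, auc",
        [
            ((0, 0, 1, 1), (0.1, 0.2, 0.8, 0.9), 1.0),  # perfect separation
            ((0, 1), (0.5, 0.5), 0.5),                  # complete tie
            ((0, 0, 1), (0.1, 0.8, 0.6), 0.5),          # 1 of 2 pairs concordant
        ],
    )
    def test_auc_examples(self, labels, scores, auc):
        assert roc_curve(labels, scores).auc == pytest.approx(auc)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 1, 1], [0.1, 0.2, 0.3])

    def test_curve_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(rng.random(100) < 0.4, rng.random(100))
        assert (np.diff(curve.thresholds) <= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()

    def test_auc_equals_concordance_and_sklearn(self):
        """Trapezoidal AUC = rank statistic; cross-checked against the
        reference implementation, with and without ties."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for trial in range(20):
            labels = rng.random(60) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = rng.random(60) + labels * rng.random()
            if trial % 2:  # force ties
                scores = np.round(scores, 1)
            auc = roc_curve(labels, scores).auc
            assert auc == pytest.approx(concordance_auc(labels, scores), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestYouden:
    def test_perfect_separation_smallest_optimum(self):
        curve = roc_curve((0, 0, 1, 1), (0.1, 0.2, 0.8, 0.9))
        assert youden_threshold(curve) == pytest.approx(0.8)

    def test_degenerate_all_tied_warns(self):
        curve = roc_curve((0, 1, 0, 1), (0.4, 0.4, 0.4, 0.4))
        with pytest.warns(UserWarning, match="degenerate"):
            assert youden_threshold(curve) == pytest.approx(0.4)

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = rng.random(200) < 0.3
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(200) + 0.3 * labels, 2)
            got = youden_threshold(roc_curve(labels, scores))
            assert got == brute_force_youden(labels, scores)


class TestPRPixels:
    def test_four_pixel_example(self):
        truth = [np.array([[1, 1, 0, 0]])]
        vals = [np.array([[0.9, 0.6, 0.55, 0.1]])]
        curve = pr_curve_pixels(truth, vals)
        assert curve.f1.max() == pytest.approx(1.0)
        assert max_f1_threshold(curve) == pytest.approx(0.55)

    def test_fused_equals_truth_is_perfect_at_any_interior_threshold(self):
        rng = np.random.default_rng(2)
        truth = rng.random((32, 32)) < 0.2
        fused = truth.astype(float)
        for t in np.linspace(0.1, 0.9, 9):
            pred = fused > t
            tp = (pred & truth).sum()
            assert 2 * tp / (pred.sum() + truth.sum()) == pytest.approx(1.0)
        curve = pr_curve_pixels([truth], [fused])
        assert curve.f1.max() == pytest.approx(1.0)

    def test_all_zero_fused_has_zero_recall(self):
        truth = [np.ones((4, 4), bool)]
        curve = pr_curve_pixels(truth, [np.zeros((4, 4))])
        assert (curve.recall[curve.thresholds > 0] == 0).all()

    def test_no_positive_truth_raises(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve_pixels([np.zeros((4, 4), bool)], [np.random.rand(4, 4)])

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            truth = rng.random(500) < 0.2
            if not truth.any():
                continue
            vals = np.round(rng.random(500) + 0.3 * truth, 2).clip(0, 1)
            curve = pr_curve_pixels([truth[None, :]], [vals[None, :]])
            assert max_f1_threshold(curve) == brute_force_max_f1(truth, vals)

    def test_single_threshold_curve(self):
        curve = PRCurve(
            thresholds=np.array([0.3]),
            precision=np.array([0.8]),
            recall=np.array([0.9]),
            f1=np.array([0.847]),
            auc=0.8,
        )
        assert max_f1_threshold(curve) == pytest.approx(0.3)


class TestLesionDetectionCurve:
    def test_perfect_maps_detect_everything_below_one(self):
        from metseg.calibration import lesion_detection_curve

        rng = np.random.default_rng(0)
        truth = np.zeros((32, 32), bool)
        truth[4:8, 4:8] = True
        truth[20:25, 20:24] = True
        ts, rate = lesion_detection_curve([truth], [truth.astype(float)])
        assert (rate[ts < 1.0] == 1.0).all()
        # detection rate can only fall as the threshold rises
        assert (np.diff(rate) <= 0).all()

    def test_no_lesions_raises(self):
        from metseg.calibration import lesion_detection_curve

        with pytest.raises(ValueError, match="lesions"):
            lesion_detection_curve([np.zeros((8, 8), bool)], [np.zeros((8, 8))])


class TestCalibrate:
    def _validation(self, n=16, corrupt=False, seed=0):
        from metseg.calibration import calibrate

        rng = np.random.default_rng(seed)
        truths, pairs = {}, []
        for i in range(n):
            truth = np.zeros((32, 32))
            if i % 3 == 0:
                truth[8:16, 8 : 12 + (i % 4)] = 1
            slc = ProcessedSlice(
                pixels=rng.random((32, 32)),
                roi=np.ones((32, 32), bool),
                patient_id="v",
                slice_index=i,
            )
            truths[slc.slice_id] = truth
            pairs.append((slc, truth.astype(bool)))
        degs = (
            (Degradation(blend=0.3, noise_sd=0.1),) * 4
            if corrupt
            else (Degradation(),) * 4
        )
        bank = SimulatedBank(truths, degs, seed=seed)
        return calibrate, bank, pairs

    def test_zero_corruption_gives_perfect_validation_auc(self):
        calibrate, bank, pairs = self._validation()
        th = calibrate(bank, pairs)
        assert th.roc.auc == 1.0
        assert th.pr.f1.max() == pytest.approx(1.0)

    def test_seeded_calibration_is_reproducible(self):
        calibrate, bank, pairs = self._validation(corrupt=True, seed=3)
        a = calibrate(bank, pairs)
        b = calibrate(bank, pairs)
        assert (a.t_c, a.mask_c) == (b.t_c, b.mask_c)

    def test_degenerate_validation_set_raises(self):
        calibrate, bank, pairs = self._validation()
        only_neg = [(s, t) for s, t in pairs if not t.any()]
        with pytest.raises(ValueError, match="both classes"):
            calibrate(bank, only_neg)
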