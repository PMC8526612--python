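"""Metrics: Dice/IoU identities, precision/recall, lesion volumes, the
0.15 ml filter, Wilson intervals and the pooled evaluation report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metseg.metrics import (
    ConfusionCounts,
    LesionComponent,
    dice_iou,
    evaluate,
    filter_small_lesions,
    prf,
    proportion_ci,
    volume_from_mask,
)


def _mask_from_count(n, size=100):
    m = np.zeros(size, bool)
    m[:n] = True
    return m.reshape(10, 10)


class TestDiceIoU:
    def test_set_arithmetic_example(self):
        pred = np.zeros((4, 4), bool)
        truth = np.zeros((4, 4), bool)
        pred.flat[:4] = True        # |pred| = 4
        truth.flat[1:7] = True      # |truth| = 6, |inter| = 3
        iou, dice = dice_iou(pred, truth)
        assert iou == pytest.approx(3 / 7)
        assert dice == pytest.approx(0.6)

    def test_identical_and_disjoint(self):
        a = _mask_from_count(10)
        assert dice_iou(a, a) == (1.0, 1.0)
        b = np.roll(a, 50)
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), bool)
        assert dice_iou(z, z) == (1.0, 1.0)

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
        with pytest.raises(ValueError, match="binary"):
            dice_iou(np.full((2, 2), 0.5), np.zeros((2, 2), bool))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_dice_iou_identity(self, seed):
        """Dice = 2*IoU/(1+IoU) exactly; Dice >= IoU with equality only
        at 0 or 1."""
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) < 0.3
        b = rng.random((12, 12)) < 0.3
        iou, dice = dice_iou(a, b)
        assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-12)
        assert dice >= iou
        if dice == iou:
            assert iou in (0.0, 1.0)


class TestPRF:
    def test_basic(self):
        p, r, f1 = prf(ConfusionCounts(3, 1, 1, 5))
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_zero_denominator_sentinels(self):
        with pytest.warns(UserWarning, match="precision"):
            p, r, f1 = prf(ConfusionCounts(0, 0, 5, 5))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_identity_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fp, fn = (int(v) for v in rng.integers(1, 50, 3))
            _, _, f1 = prf(ConfusionCounts(tp, fp, fn, 0))
            assert f1 == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestVolumes:
    def test_volume_arithmetic(self):
        mask = np.zeros((20, 20), bool)
        mask.flat[:100] = True  # one 100-pixel component
        comps = volume_from_mask(mask, (0.5, 0.5), 3.0)
        assert len(comps) == 1
        assert comps[0].volume_ml == pytest.approx(0.075)

    def test_empty_mask(self):
        assert volume_from_mask(np.zeros((5, 5), bool), (1, 1), 1) == []

    def test_connectivity_modes(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True  # touching diagonally
        assert len(volume_from_mask(mask, (1, 1), 1, connectivity=8)) == 1
        assert len(volume_from_mask(mask, (1, 1), 1, connectivity=4)) == 2

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            volume_from_mask(np.zeros((4, 4), bool), (0.0, 0.5), 3.0)


class TestLesionFilter:
    def test_strictly_greater_than(self):
        mk = lambda v: LesionComponent(1, v, (0, 0), 1)
        kept = filter_small_lesions([mk(0.075), mk(0.15), mk(0.1875)])
        assert [l.volume_ml for l in kept] == [0.1875]


class TestWilson:
    def test_closed_form_oracle(self):
        """8/10 at 95%: centre (p + z^2/2n)/(1 + z^2/n), half-width
        z*sqrt(p(1-p)/n + z^2/4n^2)/(1 + z^2/n), z = 1.959964."""
        z = 1.959963984540054
        p, n = 0.8, 10
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = proportion_ci(8, 10)
        assert lo == pytest.approx(centre - half, abs=1e-9)
        assert hi == pytest.approx(centre + half, abs=1e-9)
        assert (round(lo, 3), round(hi, 3)) == (0.490, 0.943)

    def test_zero_successes_lower_bound_zero(self):
        lo, _ = proportion_ci(0, 10)
        assert lo == 0.0

    def test_width_shrinks_like_inverse_sqrt_n(self):
        w100 = np.diff(proportion_ci(50, 100))[0]
        w400 = np.diff(proportion_ci(200, 400))[0]
        assert w400 / w100 == pytest.approx(0.5, abs=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 0)
        with pytest.raises(ValueError):
            proportion_ci(11, 10)


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(1)
        truths = [rng.random((8, 8)) < 0.3 for _ in range(5)]
        rep = evaluate(truths, truths)
        assert rep.slice_f1 == 1.0
        assert rep.mean_dice == 1.0
        assert rep.pixel_precision == 1.0
        assert rep.lesion_detection_rate == 1.0

    def test_all_negative_predictions(self):
        truths = [_mask_from_count(5), np.zeros((10, 10), bool)]
        preds = [np.zeros((10, 10), bool)] * 2
        rep = evaluate(preds, truths)
        assert rep.slice_recall == 0.0
        assert rep.slice_counts.tn == 1
        assert rep.slice_counts.fn == 1

    def test_pooled_pixel_counts_match_flat_oracle(self):
        rng = np.random.default_rng(2)
        preds = [rng.random((8, 8)) < 0.4 for _ in range(6)]
        truths = [rng.random((8, 8)) < 0.4 for _ in range(6)]
        rep = evaluate(preds, truths)
        p = np.concatenate([m.ravel() for m in preds])
        t = np.concatenate([m.ravel() for m in truths])
        tp = int((p & t).sum())
        assert rep.pixel_counts.tp == tp
        assert rep.pixel_precision == pytest.approx(tp / p.sum())
        assert rep.pixel_recall == pytest.approx(tp / t.sum())

    def test_misaligned_inputs_raise(self):
        with pytest.raises(ValueError, match="align"):
            evaluate([np.zeros((2, 2), bool)], [])

    def test_slice_counts_sum_to_n_slices(self):
        rng = np.random.default_rng(3)
        preds = [rng.random((6, 6)) < 0.2 for _ in range(9)]
        truths = [rng.random((6, 6)) < 0.2 for _ in range(9)]
        rep = evaluate(preds, truths)
        assert rep.slice_counts.total == 9
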