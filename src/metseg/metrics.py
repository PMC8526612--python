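"""Evaluation: confusion counts, precision/recall/F1, IoU/Dice, lesion
volumes and the 0.15 ml clinical filter, with confidence intervals.

Volumes use the scanner geometry: ``pixel_count * pixel_area(mm^2) *
slice_thickness(mm) / 1000`` millilitres, computed per in-plane connected
component (8-connectivity by default).  Lesions at or below 0.15 ml are
excluded by a strictly-greater-than filter, mirroring the clinical
inclusion rule of the target workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from statsmodels.stats.proportion import proportion_confint

from .ensemble import BinaryMask

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "LesionComponent",
    "dice_iou",
    "prf",
    "volume_from_mask",
    "filter_small_lesions",
    "proportion_ci",
    "bootstrap_mean_ci",
    "evaluate",
]

MIN_LESION_VOLUME_ML = 0.15


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN at either the slice or the pixel level."""

    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "slice"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class LesionComponent:
    """One connected component of a mask with its physical volume."""

    pixel_count: int
    volume_ml: float
    centroid: tuple[float, float]
    label: int


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask.values if isinstance(mask, BinaryMask) else mask)
    if not np.isin(m, [0, 1]).all():
        raise ValueError("mask must be binary")
    return m.astype(bool)


def dice_iou(pred, truth) -> tuple[float, float]:
    """Return (IoU, Dice) between two binary masks.

    IoU = |A∩B| / |A∪B| and Dice = 2|A∩B| / (|A| + |B|); they satisfy
    Dice = 2·IoU / (1 + IoU).  When both masks are empty the pair is
    reported as (1.0, 1.0) - nothing to find, nothing found - and
    aggregate reports additionally expose an average that excludes such
    trivially perfect slices.
    """
    a, b = _as_binary(pred), _as_binary(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2 * inter / (int(a.sum()) + int(b.sum()))
    return iou, dice


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 from confusion counts.

    Zero denominators yield 0.0 with a warning rather than NaN.
    """
    if counts.tp + counts.fp == 0:
        warnings.warn("no predicted positives; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        warnings.warn("no true positives in truth; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def volume_from_mask(
    mask,
    pixel_spacing: tuple[float, float],
    slice_thickness: float,
    connectivity: int = 8,
) -> list[LesionComponent]:
    """Connected components of a binary mask with volumes in ml.

    ``connectivity`` is 8 (default, diagonal neighbours merge) or 4.
    """
    if min(pixel_spacing) <= 0 or slice_thickness <= 0:
        raise ValueError("pixel spacing and slice thickness must be positive")
    m = _as_binary(mask)
    structure = (
        np.ones((3, 3), dtype=int)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(m, structure=structure)
    pixel_area = pixel_spacing[0] * pixel_spacing[1]
    out = []
    for k in range(1, n + 1):
        comp = labels == k
        count = int(comp.sum())
        cy, cx = ndimage.center_of_mass(comp)
        out.append(
            LesionComponent(
                pixel_count=count,
                volume_ml=count * pixel_area * slice_thickness / 1000.0,
                centroid=(float(cy), float(cx)),
                label=k,
            )
        )
    return out


def filter_small_lesions(
    lesions: Sequence[LesionComponent],
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
) -> list[LesionComponent]:
    """Keep only lesions with volume strictly greater than the cutoff
    (a lesion of exactly 0.15 ml is removed)."""
    return [l for l in lesions if l.volume_ml > min_volume_ml]


def proportion_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form: centre (p + z²/2n) / (1 + z²/n) with half-width
    z·sqrt(p(1-p)/n + z²/4n²) / (1 + z²/n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def bootstrap_mean_ci(
    values: Sequence[float],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap interval for a mean (used for the
    per-image IoU/Dice averages, which are not simple proportions)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to bootstrap")
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


@dataclass
class EvaluationReport:
    """Slice-level and pixel-level performance of a set of predictions."""

    slice_counts: ConfusionCounts
    slice_precision: float
    slice_recall: float
    slice_f1: float
    slice_precision_ci: tuple[float, float]
    slice_recall_ci: tuple[float, float]
    pixel_counts: ConfusionCounts
    pixel_precision: float
    pixel_recall: float
    pixel_f1: float
    per_image_iou: list[float]
    per_image_dice: list[float]
    mean_iou: float
    mean_dice: float
    mean_iou_ci: tuple[float, float]
    mean_dice_ci: tuple[float, float]
    mean_iou_all: float  # includes empty-empty slices as 1.0
    mean_dice_all: float
    lesions_total: int
    lesions_detected: int
    lesion_detection_rate: float

    def to_dict(self) -> dict:
        c = self.slice_counts
        p = self.pixel_counts
        return {
            "slice": {
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "precision": self.slice_precision,
                "recall": self.slice_recall,
                "f1": self.slice_f1,
                "precision_ci": list(self.slice_precision_ci),
                "recall_ci": list(self.slice_recall_ci),
            },
            "pixel": {
                "tp": p.tp, "fp": p.fp, "fn": p.fn, "tn": p.tn,
                "precision": self.pixel_precision,
                "recall": self.pixel_recall,
                "f1": self.pixel_f1,
            },
            "segmentation": {
                "mean_iou": self.mean_iou,
                "mean_dice": self.mean_dice,
                "mean_iou_ci": list(self.mean_iou_ci),
                "mean_dice_ci": list(self.mean_dice_ci),
                "mean_iou_all_slices": self.mean_iou_all,
                "mean_dice_all_slices": self.mean_dice_all,
                "n_images": len(self.per_image_iou),
            },
            "lesions": {
                "total": self.lesions_total,
                "detected": self.lesions_detected,
                "detection_rate": self.lesion_detection_rate,
            },
        }


def evaluate(
    predictions: Sequence,
    truths: Sequence[np.ndarray],
    seed: int = 0,
) -> EvaluationReport:
    """Score aligned prediction/truth mask pairs.

    Slice-level counts treat a slice as positive when its mask is
    nonempty.  Per-image IoU/Dice are averaged over images where
    prediction or truth is nonempty (the all-slices average, counting
    empty-empty pairs as 1.0, is also reported).  Lesion-level detection
    counts a truth lesion as found iff at least one of its pixels is
    predicted positive.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    if len(predictions) == 0:
        raise ValueError("nothing to evaluate")

    preds = [_as_binary(p) for p in predictions]
    trus = [_as_binary(t) for t in truths]
    for p, t in zip(preds, trus):
        if p.shape != t.shape:
            raise ValueError("prediction/truth shape mismatch")

    s_tp = sum(1 for p, t in zip(preds, trus) if p.any() and t.any())
    s_fp = sum(1 for p, t in zip(preds, trus) if p.any() and not t.any())
    s_fn = sum(1 for p, t in zip(preds, trus) if not p.any() and t.any())
    s_tn = sum(1 for p, t in zip(preds, trus) if not p.any() and not t.any())
    slice_counts = ConfusionCounts(s_tp, s_fp, s_fn, s_tn, level="slice")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp, sr, sf1 = prf(slice_counts)
    sp_ci = (
        proportion_ci(s_tp, s_tp + s_fp) if s_tp + s_fp > 0 else (0.0, 0.0)
    )
    sr_ci = (
        proportion_ci(s_tp, s_tp + s_fn) if s_tp + s_fn > 0 else (0.0, 0.0)
    )

    p_tp = sum(int((p & t).sum()) for p, t in zip(preds, trus))
    p_fp = sum(int((p & ~t).sum()) for p, t in zip(preds, trus))
    p_fn = sum(int((~p & t).sum()) for p, t in zip(preds, trus))
    p_tn = sum(int((~p & ~t).sum()) for p, t in zip(preds, trus))
    pixel_counts = ConfusionCounts(p_tp, p_fp, p_fn, p_tn, level="pixel")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pp, pr_, pf1 = prf(pixel_counts)

    iou_all, dice_all, iou_ne, dice_ne = [], [], [], []
    for p, t in zip(preds, trus):
        i, d = dice_iou(p, t)
        iou_all.append(i)
        dice_all.append(d)
        if p.any() or t.any():
            iou_ne.append(i)
            dice_ne.append(d)
    if iou_ne:
        iou_ci = bootstrap_mean_ci(iou_ne, seed=seed)
        dice_ci = bootstrap_mean_ci(dice_ne, seed=seed + 1)
        mean_iou, mean_dice = float(np.mean(iou_ne)), float(np.mean(dice_ne))
    else:
        iou_ci = dice_ci = (1.0, 1.0)
        mean_iou = mean_dice = 1.0

    structure = np.ones((3, 3), dtype=int)
    lesions_total = lesions_detected = 0
    for p, t in zip(preds, trus):
        labels, n = ndimage.label(t, structure=structure)
        lesions_total += n
        for k in range(1, n + 1):
            if (p & (labels == k)).any():
                lesions_detected += 1

    return EvaluationReport(
        slice_counts=slice_counts,
        slice_precision=sp,
        slice_recall=sr,
        slice_f1=sf1,
        slice_precision_ci=sp_ci,
        slice_recall_ci=sr_ci,
        pixel_counts=pixel_counts,
        pixel_precision=pp,
        pixel_recall=pr_,
        pixel_f1=pf1,
        per_image_iou=iou_ne,
        per_image_dice=dice_ne,
        mean_iou=mean_iou,
        mean_dice=mean_dice,
        mean_iou_ci=iou_ci,
        mean_dice_ci=dice_ci,
        mean_iou_all=float(np.mean(iou_all)),
        mean_dice_all=float(np.mean(dice_all)),
        lesions_total=lesions_total,
        lesions_detected=lesions_detected,
        lesion_detection_rate=(
            lesions_detected / lesions_total if lesions_total else 0.0
        ),
    )
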