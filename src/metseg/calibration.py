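"""Threshold calibration on a validation set.

The classification threshold T_c is the Youden-index maximizer
(argmax TPR - FPR) over the ROC curve of the slice scores, with ties
broken toward the smallest threshold so that false negatives are
minimized - a missed tumor slice is the costly error in treatment
planning.  The mask threshold Mask_c is the max-F1 operating point of
the pixel-level precision-recall curve of the fused maps, with the same
recall-favouring tie-break.

Candidate thresholds are the unique observed values (not a fixed grid),
so both selections are exact argmaxes and can be checked against
exhaustive search.  Decision semantics match the ensemble stage exactly:
slices are positive when score >= t, pixels when value > t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_bank import ModelBank
from .preprocessing import ProcessedSlice

__all__ = [
    "ROCCurve",
    "PRCurve",
    "Thresholds",
    "roc_curve",
    "youden_threshold",
    "pr_curve_pixels",
    "max_f1_threshold",
    "lesion_detection_curve",
    "calibrate",
]


@dataclass(frozen=True)
class ROCCurve:
    """ROC points ordered by decreasing threshold, with trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class PRCurve:
    """PR points ordered by decreasing threshold, with trapezoidal AUC."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    auc: float


@dataclass(frozen=True)
class Thresholds:
    """The calibrated operating pair plus its provenance curves."""

    t_c: float
    mask_c: float
    roc: ROCCurve | None = None
    pr: PRCurve | None = None
    calibration_id: str = ""


def roc_curve(labels: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """ROC of the slice-level decision rule (score >= threshold).

    Candidate thresholds are the sorted unique scores plus one sentinel
    above the maximum (the no-positive point).  The AUC is the trapezoidal
    integral, which on the same data equals the pairwise concordance
    statistic with half credit for ties.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be aligned 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each unique score when sorted descending
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[s_sorted[distinct][0] + 1.0, s_sorted[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_threshold(curve: ROCCurve) -> float:
    """T_c = argmax (TPR - FPR); ties go to the smallest threshold.

    The smallest tying threshold admits the most slices as positive,
    i.e. it minimizes false negatives among the optima.
    """
    j = curve.tpr - curve.fpr
    best = j.max()
    if best <= 0:
        warnings.warn(
            "degenerate ROC: Youden index is 0 everywhere; "
            "returning the smallest candidate threshold",
            stacklevel=2,
        )
    candidates = curve.thresholds[np.isclose(j, best)]
    return float(candidates.min())


def pr_curve_pixels(
    truth_masks: Sequence[np.ndarray],
    fused_maps: Sequence[np.ndarray],
) -> PRCurve:
    """Pixel-level PR curve pooled over all contributing slices.

    Predictions use the mask rule (value > threshold), matching the
    final binarization exactly.  Candidate thresholds are the unique
    pooled values.  Where a threshold admits no positive pixel at all,
    precision is reported as 1.0 (no false positives were made).
    """
    if len(truth_masks) != len(fused_maps):
        raise ValueError("truth masks and fused maps must align")
    if len(truth_masks) == 0:
        raise ValueError("no slices to pool")
    t = np.concatenate([np.asarray(m).astype(bool).ravel() for m in truth_masks])
    v = np.concatenate([np.asarray(m, dtype=float).ravel() for m in fused_maps])
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("no positive pixels in the pooled truth")

    order = np.argsort(-v, kind="stable")
    v_sorted, t_sorted = v[order], t[order]
    distinct = np.r_[np.nonzero(np.diff(v_sorted))[0], v_sorted.size - 1]
    thresholds = v_sorted[distinct]
    # strict '>' rule: at threshold u_k, positives are the values above u_k,
    # i.e. everything before u_k's first occurrence in the sorted order
    first = np.r_[0, distinct[:-1] + 1]
    tp = np.r_[0, np.cumsum(t_sorted)][first]
    pp = first  # number of predicted-positive pixels
    with np.errstate(invalid="ignore"):
        precision = np.where(pp > 0, tp / np.maximum(pp, 1), 1.0)
    recall = tp / n_pos
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    order_r = np.argsort(recall, kind="stable")
    auc = float(np.trapezoid(precision[order_r], recall[order_r]))
    return PRCurve(
        thresholds=thresholds, precision=precision, recall=recall, f1=f1, auc=auc
    )


def max_f1_threshold(curve: PRCurve) -> float:
    """Mask_c = argmax F1 on the PR curve; ties go to the smallest
    threshold (recall-favouring, like the Youden tie-break)."""
    best = curve.f1.max()
    candidates = curve.thresholds[np.isclose(curve.f1, best)]
    return float(candidates.min())


def lesion_detection_curve(
    truth_masks: Sequence[np.ndarray],
    fused_maps: Sequence[np.ndarray],
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Secondary, lesion-level view: fraction of truth lesions detected
    (any lesion pixel above threshold) as a function of the threshold."""
    from scipy.ndimage import label as cc_label

    lesion_peaks: list[float] = []
    for truth, fused in zip(truth_masks, fused_maps):
        lab, n = cc_label(np.asarray(truth).astype(bool),
                          structure=np.ones((3, 3), dtype=int))
        f = np.asarray(fused, dtype=float)
        for k in range(1, n + 1):
            lesion_peaks.append(float(f[lab == k].max()))
    if not lesion_peaks:
        raise ValueError("no lesions in the pooled truth")
    peaks = np.asarray(lesion_peaks)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    detected = (peaks[None, :] > thresholds[:, None]).mean(axis=1)
    return thresholds, detected


def calibrate(
    bank: ModelBank,
    validation: Sequence[tuple[ProcessedSlice, np.ndarray]],
    calibration_id: str = "validation",
) -> Thresholds:
    """Full calibration pass over (processed slice, truth mask) pairs.

    Runs the bank on every slice, selects T_c from the slice-score ROC,
    then pools the fused maps of the positively *classified* slices to
    select Mask_c from the pixel PR curve.
    """
    if not validation:
        raise ValueError("empty validation set")
    labels, scores, fused_all, truths = [], [], [], []
    for slc, truth in validation:
        maps = bank.predict(slc)
        vals = [m.values for m in maps]
        labels.append(bool(np.asarray(truth).any()))
        scores.append(float(np.median([v.max() for v in vals])))
        fused_all.append(np.mean(vals, axis=0))
        truths.append(np.asarray(truth).astype(bool))

    roc = roc_curve(labels, scores)
    t_c = youden_threshold(roc)

    keep = [i for i, s in enumerate(scores) if s >= t_c]
    pr = pr_curve_pixels([truths[i] for i in keep], [fused_all[i] for i in keep])
    mask_c = max_f1_threshold(pr)
    return Thresholds(
        t_c=t_c, mask_c=mask_c, roc=roc, pr=pr, calibration_id=calibration_id
    )
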