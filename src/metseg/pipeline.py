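"""End-to-end phantom pipeline: generate -> preprocess -> calibrate ->
predict -> evaluate.

This is the reproducible experiment the command line exposes as
``metseg report``: a seeded cohort of head phantoms is split by patient,
the model bank (simulated by default) is calibrated on the validation
patients, and the calibrated two-stage ensemble is scored on the held-out
test patients.  Everything downstream of the seed is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics
from .calibration import calibrate
from .ensemble import run_two_stage
from .model_bank import simulated_bank_for
from .phantom import (
    DEFAULT_DEGRADATIONS,
    Degradation,
    PhantomConfig,
    generate_cohort,
    split_patients,
)
from .preprocessing import ProcessedSlice, SnakeParams, preprocess, extract_roi_snake, resize_mask

__all__ = ["ReportConfig", "run_report", "preprocess_patient"]


@dataclass(frozen=True)
class ReportConfig:
    """Configuration of one end-to-end phantom experiment."""

    phantom: PhantomConfig = PhantomConfig()
    snake: SnakeParams = SnakeParams()
    n_patients: int = 30
    n_train: int = 10
    n_val: int = 10
    n_test: int = 10
    degradations: tuple[Degradation, ...] = DEFAULT_DEGRADATIONS
    seed: int = 0
    roi_per_patient: bool = True  # one snake per patient, reused across its slices


def preprocess_patient(patient, snake: SnakeParams, roi_per_patient: bool = True):
    """Preprocess every slice of a patient.

    With ``roi_per_patient`` the snake runs once, on the middle slice,
    and its contour is reused for the whole stack - the skull does not
    move between slices of one series, and this cuts the dominant cost
    of preprocessing by the stack length.
    """
    roi = None
    if roi_per_patient:
        mid = patient.slices[len(patient.slices) // 2]
        roi = extract_roi_snake(mid, snake)
    out = []
    for slc, mask in zip(patient.slices, patient.masks):
        proc = preprocess(slc, snake, roi=roi)
        out.append((proc, resize_mask(mask, proc.pixels.shape[0])))
    return out


def run_report(config: ReportConfig = ReportConfig()) -> dict:
    """Run the full experiment and return a JSON-serializable report."""
    cfg = config
    phantom_cfg = cfg.phantom
    if phantom_cfg.seed != cfg.seed:
        phantom_cfg = PhantomConfig(
            **{**phantom_cfg.__dict__, "seed": cfg.seed}
        )

    cohort = generate_cohort(phantom_cfg, cfg.n_patients)
    train, val, test = split_patients(
        cohort, cfg.n_train, cfg.n_val, cfg.n_test, seed=cfg.seed
    )

    bank = simulated_bank_for(cohort, cfg.degradations, seed=cfg.seed)

    val_pairs: list[tuple[ProcessedSlice, np.ndarray]] = []
    for pat in val:
        val_pairs.extend(preprocess_patient(pat, cfg.snake, cfg.roi_per_patient))
    thresholds = calibrate(bank, val_pairs, calibration_id=f"seed-{cfg.seed}")

    test_pairs: list[tuple[ProcessedSlice, np.ndarray]] = []
    for pat in test:
        test_pairs.extend(preprocess_patient(pat, cfg.snake, cfg.roi_per_patient))
    results = run_two_stage(bank, [p for p, _ in test_pairs], thresholds)

    # test-set slice-score ROC (threshold-free classification quality)
    from .calibration import roc_curve

    test_labels = [bool(t.any()) for _, t in test_pairs]
    test_scores = [s1.score for s1, _ in results]
    test_roc = roc_curve(test_labels, test_scores)

    report = metrics.evaluate(
        [m for _, m in results], [t for _, t in test_pairs], seed=cfg.seed
    )

    # Dice/IoU restricted to truly tumor-bearing slices
    pos_dice, pos_iou = [], []
    for (_, mask), (_, truth) in zip(results, test_pairs):
        if truth.any():
            iou, dice = metrics.dice_iou(mask.values, truth)
            pos_iou.append(iou)
            pos_dice.append(dice)

    return {
        "seed": cfg.seed,
        "n_patients": {"train": cfg.n_train, "val": cfg.n_val, "test": cfg.n_test},
        "thresholds": {
            "t_c": thresholds.t_c,
            "mask_c": thresholds.mask_c,
            "validation_roc_auc": thresholds.roc.auc,
            "validation_pr_auc": thresholds.pr.auc,
        },
        "test": {
            "classification_auc": test_roc.auc,
            **report.to_dict(),
            "mean_positive_slice_dice": float(np.mean(pos_dice)) if pos_dice else None,
            "mean_positive_slice_iou": float(np.mean(pos_iou)) if pos_iou else None,
        },
        "_thresholds_obj": thresholds,  # stripped before JSON dump
    }


def report_to_json_dict(report: dict) -> dict:
    """Drop non-serializable members from a report."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
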