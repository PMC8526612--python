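"""The two-stage ensemble: slice classification then mask binarization.

Stage one computes the slice score

    score_i = median( max f_1i, max f_2i, max f_3i, max f_4i )

and declares the slice tumor-free iff ``score_i < T_c`` (strict: a score
exactly equal to the threshold is a positive).  Negative slices get an
all-zero fused map; positive slices get the pixelwise mean of the four
probability maps.  Stage two binarizes the fused map g(x, y):

    h(x, y) = 1  iff  g(x, y) > Mask_c      (strict: g = Mask_c maps to 0)

Both boundary semantics are deliberate and asserted in tests; raising
either threshold can only remove positives, never add them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .model_bank import ModelBank, ProbabilityMap
from .preprocessing import ProcessedSlice

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import Thresholds

__all__ = [
    "StageOneOutput",
    "BinaryMask",
    "ensemble_score",
    "classify_and_fuse",
    "apply_mask_threshold",
    "run_two_stage",
]


@dataclass(frozen=True)
class StageOneOutput:
    """Classification decision and fused map for one slice."""

    slice_id: str
    score: float
    decision: bool  # True = tumor present
    fused: np.ndarray  # all-zero if negative, mean of the four maps if positive


@dataclass(frozen=True)
class BinaryMask:
    """Final {0, 1} prediction mask for one slice."""

    slice_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, [0, 1]).all():
            raise ValueError("binary mask must contain only 0 and 1")
        object.__setattr__(self, "values", v.astype(np.uint8))


def _map_values(maps: Sequence[ProbabilityMap | np.ndarray]) -> list[np.ndarray]:
    out = []
    for m in maps:
        v = m.values if isinstance(m, ProbabilityMap) else np.asarray(m, dtype=float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probability values must lie in [0, 1]")
        out.append(v)
    return out


def ensemble_score(maps: Sequence[ProbabilityMap | np.ndarray]) -> float:
    """Median of the four per-map maxima.

    For four values the median is the mean of the two middle order
    statistics, so the score is insensitive to one wildly optimistic and
    one wildly pessimistic model at once.
    """
    vals = _map_values(maps)
    if len(vals) != 4:
        raise ValueError(f"the ensemble score is defined for 4 maps, got {len(vals)}")
    return float(np.median([v.max() for v in vals]))


def classify_and_fuse(
    maps: Sequence[ProbabilityMap | np.ndarray],
    t_c: float,
    slice_id: str = "",
) -> StageOneOutput:
    """Stage one: threshold the score, fuse by pixelwise mean if positive."""
    if not 0.0 <= t_c <= 1.0:
        raise ValueError("T_c must lie in [0, 1]")
    vals = _map_values(maps)
    if len(vals) != 4:
        raise ValueError(f"stage one is defined for 4 maps, got {len(vals)}")
    score = float(np.median([v.max() for v in vals]))
    if score < t_c:  # strict: score == T_c is positive
        return StageOneOutput(
            slice_id=slice_id,
            score=score,
            decision=False,
            fused=np.zeros_like(vals[0]),
        )
    return StageOneOutput(
        slice_id=slice_id,
        score=score,
        decision=True,
        fused=np.mean(vals, axis=0),
    )


def apply_mask_threshold(
    fused: np.ndarray | StageOneOutput, mask_c: float, slice_id: str = ""
) -> BinaryMask:
    """Stage two: binarize the fused map at ``Mask_c`` (strict greater-than)."""
    if isinstance(fused, StageOneOutput):
        slice_id = slice_id or fused.slice_id
        fused = fused.fused
    g = np.asarray(fused, dtype=float)
    if not 0.0 <= mask_c <= 1.0:
        raise ValueError("Mask_c must lie in [0, 1]")
    if g.min() < 0 or g.max() > 1:
        raise ValueError("fused map values must lie in [0, 1]")
    return BinaryMask(slice_id=slice_id, values=(g > mask_c).astype(np.uint8))


def run_two_stage(
    bank: ModelBank,
    slices: Sequence[ProcessedSlice],
    thresholds: "Thresholds",
) -> list[tuple[StageOneOutput, BinaryMask]]:
    """Predict -> classify/fuse -> binarize for every slice, in order.

    Classification gates segmentation: a slice judged tumor-free yields
    an all-zero binary mask regardless of its probability maps.
    """
    results = []
    for slc in slices:
        try:
            maps = bank.predict(slc)
            stage1 = classify_and_fuse(maps, thresholds.t_c, slc.slice_id)
            mask = apply_mask_threshold(stage1, thresholds.mask_c)
        except Exception as exc:
            raise RuntimeError(f"two-stage pipeline failed on {slc.slice_id}") from exc
        results.append((stage1, mask))
    return results
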