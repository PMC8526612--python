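"""Slice preprocessing: snake ROI extraction, z-score enhancement,
resizing and intensity rescaling.

The chain is ROI -> z-score -> resize -> min-max rescale to [-1, 1] ->
re-zero background.  The region of interest is the interior of an active
contour ("snake") initialised as a large circle and contracted onto the
skull outline; everything outside it is forced to exactly zero so that
downstream convolutional models never see the noisy air background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import gaussian
from skimage.segmentation import active_contour
from skimage.transform import resize

__all__ = [
    "RawSlice",
    "ROIMask",
    "ProcessedSlice",
    "SnakeParams",
    "ROIExtractionError",
    "extract_roi_snake",
    "enhance_zscore",
    "resize_and_rescale",
    "resize_mask",
    "preprocess",
]

#: Output grid side length for processed slices.
PROCESSED_SIZE = 256


class ROIExtractionError(ValueError):
    """Raised when no region of interest can be extracted from a slice."""


@dataclass(frozen=True)
class RawSlice:
    """One acquired axial slice with its physical geometry.

    Parameters
    ----------
    pixels : ndarray
        Square 2-D intensity matrix on the acquisition scale.
    pixel_spacing : tuple of float
        In-plane (row, column) spacing in millimetres per pixel.
    slice_thickness : float
        Slice thickness in millimetres.
    patient_id, slice_index :
        Identity of the slice within its series.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"slice pixels must be square 2-D, got {px.shape}")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask and the closed contour it came from.

    ``mask`` is exactly the rasterization of ``polygon`` (an ordered
    (row, col) vertex list), so the polygon can be re-rasterized at any
    resolution without drifting from the stored mask.
    """

    mask: np.ndarray
    polygon: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "polygon", np.asarray(self.polygon, dtype=float))


@dataclass(frozen=True)
class ProcessedSlice:
    """A 256x256 ROI-masked, z-scored, [-1, 1]-rescaled slice.

    Invariants: every pixel outside ``roi`` is exactly 0; within the ROI
    the minimum is -1 and the maximum is +1; no NaN/Inf anywhere.
    """

    pixels: np.ndarray
    roi: np.ndarray
    patient_id: str
    slice_index: int

    @property
    def slice_id(self) -> str:
        return f"{self.patient_id}:{self.slice_index:04d}"


@dataclass(frozen=True)
class SnakeParams:
    """Active-contour parameters.

    alpha is the elasticity (contraction) weight, beta the rigidity,
    gamma the explicit time step.  The snake starts as a circle at
    ``init_radius_frac`` of the half-image and contracts inward until the
    edge energy of the skull stops it.  Images larger than
    ``working_size`` are contoured at that size and the polygon is scaled
    back up, which changes the result only at sub-pixel level while
    keeping the evolution cheap.
    """

    alpha: float = 0.01
    beta: float = 1.0
    gamma: float = 0.002
    smoothing_sigma: float = 3.0
    n_points: int = 200
    max_iterations: int = 2500
    convergence: float = 0.1
    init_radius_frac: float = 0.95
    working_size: int = 256


def _as_array(image: RawSlice | np.ndarray) -> np.ndarray:
    if isinstance(image, RawSlice):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def extract_roi_snake(
    image: RawSlice | np.ndarray, params: SnakeParams | None = None
) -> ROIMask:
    """Delineate the skull outline with an active contour and return its
    interior as the region of interest.

    The contour is initialised as a circle enclosing nearly the whole
    frame and contracts (driven by its elasticity term) until the image
    edge energy of the bright skull holds it in place.

    Raises
    ------
    ROIExtractionError
        If the image is blank/constant so no contour can lock onto
        anything.  Callers that want a fallback may catch this and use a
        full-frame ROI.
    """
    params = params or SnakeParams()
    img = _as_array(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(img) == 0:
        raise ROIExtractionError("image is constant; no ROI can be extracted")

    full_shape = img.shape
    scale = 1.0
    if max(full_shape) > params.working_size:
        scale = max(full_shape) / params.working_size
        work = resize(
            img,
            (round(full_shape[0] / scale), round(full_shape[1] / scale)),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
    else:
        work = img

    smoothed = gaussian(work, params.smoothing_sigma, preserve_range=True)
    rng_span = np.ptp(smoothed)
    if rng_span == 0:
        raise ROIExtractionError("image is constant after smoothing")
    smoothed = (smoothed - smoothed.min()) / rng_span

    h, w = work.shape
    theta = np.linspace(0, 2 * np.pi, params.n_points, endpoint=False)
    r0 = params.init_radius_frac * min(h, w) / 2
    init = np.column_stack([h / 2 + r0 * np.sin(theta), w / 2 + r0 * np.cos(theta)])

    snake = active_contour(
        smoothed,
        init,
        alpha=params.alpha,
        beta=params.beta,
        gamma=params.gamma,
        w_line=0,
        w_edge=1,
        max_num_iter=params.max_iterations,
        convergence=params.convergence,
    )

    polygon = snake * scale
    mask = polygon2mask(full_shape, polygon)
    if not mask.any():
        raise ROIExtractionError("active contour collapsed to an empty region")
    return ROIMask(mask=mask, polygon=polygon)


def enhance_zscore(image: RawSlice | np.ndarray, roi: ROIMask) -> np.ndarray:
    """Z-score the intensities inside the ROI; zero everything outside.

    The standardisation uses the population (N) variance over ROI pixels
    only, so the output has within-ROI mean 0 and standard deviation 1.
    """
    img = _as_array(image)
    mask = roi.mask
    if img.shape != mask.shape:
        raise ValueError("image and ROI shapes differ")
    vals = img[mask]
    if vals.size < 2:
        raise ROIExtractionError("ROI contains fewer than 2 pixels")
    sd = vals.std()  # population convention (ddof=0)
    if sd == 0:
        raise ROIExtractionError("zero intensity variance inside ROI")
    out = np.zeros_like(img, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


def resize_mask(mask: np.ndarray, out_size: int = PROCESSED_SIZE) -> np.ndarray:
    """Nearest-neighbour resize for binary masks (keeps them binary)."""
    m = np.asarray(mask)
    if m.shape == (out_size, out_size):
        return m.astype(bool)
    return resize(
        m.astype(float), (out_size, out_size), order=0, anti_aliasing=False,
        preserve_range=True,
    ) > 0.5


def resize_and_rescale(
    matrix: np.ndarray,
    roi: ROIMask,
    *,
    patient_id: str = "",
    slice_index: int = 0,
    out_size: int = PROCESSED_SIZE,
) -> ProcessedSlice:
    """Bilinearly resize to the model grid, min-max rescale the ROI to
    [-1, 1], and force the background back to exactly zero."""
    img = np.asarray(matrix, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("input must be square 2-D")
    resized = resize(
        img, (out_size, out_size), order=1, anti_aliasing=True, preserve_range=True
    )
    roi_r = resize_mask(roi.mask, out_size)
    vals = resized[roi_r]
    if vals.size == 0:
        raise ROIExtractionError("ROI vanished after resizing")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ROIExtractionError("constant ROI after resizing")
    out = np.zeros((out_size, out_size), dtype=float)
    out[roi_r] = -1.0 + 2.0 * (vals - lo) / (hi - lo)
    return ProcessedSlice(
        pixels=out, roi=roi_r, patient_id=patient_id, slice_index=slice_index
    )


def preprocess(
    slc: RawSlice,
    snake_params: SnakeParams | None = None,
    roi: ROIMask | None = None,
) -> ProcessedSlice:
    """Full preprocessing chain for one slice.

    ``roi`` may be supplied to reuse a contour already extracted for the
    same patient (the skull does not move between slices of one series);
    otherwise the snake runs on this slice.
    """
    if roi is None:
        roi = extract_roi_snake(slc, snake_params)
    enhanced = enhance_zscore(slc, roi)
    return resize_and_rescale(
        enhanced, roi, patient_id=slc.patient_id, slice_index=slc.slice_index
    )
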