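"""Seeded head-phantom generator.

Produces per-patient axial slice stacks that emulate the geometry of a
post-contrast T1 head series: a bright skull annulus, a textured brain
interior, a dark noisy background, and 0-3 bright tumor blobs on a
minority of slices, together with exact ground-truth masks and lesion
volumes.  Also simulates the probability maps a bank of trained
segmentation models would emit for a slice, with a corruption whose
optimal binarization threshold is known by construction - which is what
lets the threshold-calibration stage be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .preprocessing import RawSlice

__all__ = [
    "PhantomConfig",
    "PhantomPatient",
    "Lesion",
    "Degradation",
    "DEFAULT_DEGRADATIONS",
    "SYMMETRIC_DEGRADATIONS",
    "generate_patient",
    "generate_cohort",
    "simulate_model_bank",
    "split_patients",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and sampling parameters of the phantom.

    Defaults mimic the acquisition the pipeline targets: 512x512 slices,
    3 mm thick, about 48 slices per patient of which about 20% carry
    tumor.  In-plane spacing defaults to 0.5 mm/pixel, giving a ~26 cm
    field of view; it is configurable because reported per-pixel scales
    for such series vary.  Tumor radii of 2-8 mm yield single-slice
    lesion volumes of roughly 0.04-0.6 ml, straddling the 0.15 ml
    clinical filter.
    """

    image_size: int = 512
    pixel_spacing: float = 0.5  # mm / pixel, isotropic in plane
    slice_thickness: float = 3.0  # mm
    slices_per_patient: int = 48
    positive_slice_fraction: float = 0.20
    tumors_per_positive_slice: tuple[int, int] = (1, 3)
    tumor_radius_mm: tuple[float, float] = (2.0, 8.0)
    skull_inner_radius: int = 210  # pixels
    skull_outer_radius: int = 232  # pixels
    background_mean: float = 0.0
    skull_intensity: float = 220.0
    brain_mean: float = 100.0
    brain_texture_sd: float = 10.0
    tumor_contrast: float = 80.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_slice_fraction <= 1.0:
            raise ValueError("positive_slice_fraction must lie in [0, 1]")
        if not 0 < self.skull_inner_radius < self.skull_outer_radius:
            raise ValueError("need 0 < skull_inner_radius < skull_outer_radius")
        if self.skull_outer_radius >= self.image_size / 2:
            raise ValueError("skull must fit inside the frame")
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be positive")
        r_lo, r_hi = self.tumor_radius_mm
        if not 0 < r_lo <= r_hi:
            raise ValueError("tumor_radius_mm must be a positive (lo, hi) range")
        if r_hi / self.pixel_spacing >= self.skull_inner_radius:
            raise ValueError(
                "degenerate geometry: tumor radius >= brain radius"
            )
        t_lo, t_hi = self.tumors_per_positive_slice
        if not 1 <= t_lo <= t_hi:
            raise ValueError("tumors_per_positive_slice must be a (lo, hi) range >= 1")


@dataclass(frozen=True)
class Lesion:
    """One simulated lesion and its exact rasterized volume."""

    slice_index: int
    center: tuple[float, float]  # (row, col) pixels
    radius_px: float
    pixel_count: int
    volume_ml: float


@dataclass
class PhantomPatient:
    """A generated patient: ordered slices, ground-truth masks, lesions."""

    patient_id: str
    slices: list[RawSlice]
    masks: list[np.ndarray]
    lesions: list[Lesion]
    config: PhantomConfig

    @property
    def positive_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.masks) if m.any()]


def _positive_flags(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli per-slice positivity, redrawn until the realised count is
    within +-2 slices of the expected count (keeps the class imbalance of
    every generated patient close to the configured fraction)."""
    n = config.slices_per_patient
    target = config.positive_slice_fraction * n
    for _ in range(200):
        flags = rng.random(n) < config.positive_slice_fraction
        if abs(int(flags.sum()) - target) <= 2:
            return flags
    # Extremely unlikely fallback: place exactly round(target) positives.
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=int(round(target)), replace=False)] = True
    return flags


def generate_patient(config: PhantomConfig, patient_seed: int) -> PhantomPatient:
    """Generate one patient's slice stack deterministically.

    All randomness derives from ``(config.seed, patient_seed)``, so the
    same pair always yields bit-identical pixels and masks.
    """
    rng = np.random.default_rng([config.seed, patient_seed])
    size = config.image_size
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    radius_map = np.hypot(yy - c, xx - c)
    brain = radius_map < config.skull_inner_radius
    skull = (radius_map >= config.skull_inner_radius) & (
        radius_map < config.skull_outer_radius
    )

    flags = _positive_flags(config, rng)
    slices: list[RawSlice] = []
    masks: list[np.ndarray] = []
    lesions: list[Lesion] = []
    pid = f"phantom-{patient_seed:04d}"

    for k in range(config.slices_per_patient):
        img = config.background_mean + rng.normal(0.0, config.noise_sd, (size, size))
        texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 4.0)
        t_sd = texture.std()
        if t_sd > 0:
            texture *= config.brain_texture_sd / t_sd
        img[brain] += config.brain_mean + texture[brain]
        img[skull] = config.skull_intensity + rng.normal(
            0.0, config.noise_sd, int(skull.sum())
        )

        mask = np.zeros((size, size), dtype=bool)
        if flags[k]:
            t_lo, t_hi = config.tumors_per_positive_slice
            n_tumors = int(rng.integers(t_lo, t_hi + 1))
            placed: list[tuple[float, float, float]] = []
            for _ in range(n_tumors):
                for _attempt in range(100):
                    r_mm = rng.uniform(*config.tumor_radius_mm)
                    r_px = r_mm / config.pixel_spacing
                    max_c = config.skull_inner_radius - r_px - 4
                    if max_c <= 0:
                        continue
                    rho = max_c * np.sqrt(rng.random())
                    phi = rng.uniform(0, 2 * np.pi)
                    cy, cx = c + rho * np.sin(phi), c + rho * np.cos(phi)
                    if all(
                        np.hypot(cy - py, cx - px) > r_px + pr + 2
                        for py, px, pr in placed
                    ):
                        placed.append((cy, cx, r_px))
                        rr, cc = draw_disk((cy, cx), r_px, shape=(size, size))
                        lesion_mask = np.zeros((size, size), dtype=bool)
                        lesion_mask[rr, cc] = True
                        img[lesion_mask] += config.tumor_contrast
                        mask |= lesion_mask
                        n_px = int(lesion_mask.sum())
                        lesions.append(
                            Lesion(
                                slice_index=k,
                                center=(float(cy), float(cx)),
                                radius_px=float(r_px),
                                pixel_count=n_px,
                                volume_ml=n_px
                                * config.pixel_spacing**2
                                * config.slice_thickness
                                / 1000.0,
                            )
                        )
                        break
            if not placed:  # could not place any tumor; slice is negative
                flags[k] = False

        pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        slices.append(
            RawSlice(
                pixels=pixels,
                pixel_spacing=(config.pixel_spacing, config.pixel_spacing),
                slice_thickness=config.slice_thickness,
                patient_id=pid,
                slice_index=k,
            )
        )
        masks.append(mask)

    return PhantomPatient(
        patient_id=pid, slices=slices, masks=masks, lesions=lesions, config=config
    )


def generate_cohort(
    config: PhantomConfig, n_patients: int, first_seed: int = 0
) -> list[PhantomPatient]:
    """Generate ``n_patients`` patients with consecutive patient seeds."""
    return [generate_patient(config, first_seed + i) for i in range(n_patients)]


@dataclass(frozen=True)
class Degradation:
    """Corruption applied to a truth mask to mimic one imperfect model.

    The simulated map is ``clip(blend_toward_half(blur(truth)) + bias +
    noise, 0, 1)``: tumor pixels sit near ``1 - blend/2 + bias`` and
    background pixels near ``blend/2 + bias``, with symmetric Gaussian
    noise around both.  By symmetry the optimal binarization threshold is
    ``t* = 0.5 + bias`` (exactly the midpoint of the two class means), so
    calibration can be checked by recovering it.
    """

    blend: float = 0.0  # lambda in [0, 1]: how far values shrink toward 0.5
    noise_sd: float = 0.0
    blur_sigma: float = 0.0  # pixels of Gaussian blur on the truth edges
    bias: float = 0.0

    @property
    def optimal_threshold(self) -> float:
        return 0.5 + self.bias


#: Moderate default corruptions for a four-model simulated bank.  Edge blur
#: mimics the boundary uncertainty of real segmentation models; because blur
#: moves mass asymmetrically, the fused-map F1 optimum sits somewhat below
#: the blend midpoint for these.
DEFAULT_DEGRADATIONS: tuple[Degradation, ...] = (
    Degradation(blend=0.20, noise_sd=0.04, blur_sigma=0.5),
    Degradation(blend=0.30, noise_sd=0.05, blur_sigma=1.0),
    Degradation(blend=0.35, noise_sd=0.06, blur_sigma=1.5),
    Degradation(blend=0.25, noise_sd=0.05, blur_sigma=2.0),
)

#: Blur-free symmetric corruptions whose optimal binarization threshold is
#: t* = 0.5 by construction (class-conditional distributions are mirror
#: images about the blend midpoint).  The noise is strong enough that the
#: pooled pixel classes overlap, so the max-F1 threshold is a unique
#: interior optimum rather than a plateau - this is the bank used to
#: validate calibration by parameter recovery.
SYMMETRIC_DEGRADATIONS: tuple[Degradation, ...] = (
    Degradation(blend=0.30, noise_sd=0.12),
    Degradation(blend=0.40, noise_sd=0.14),
    Degradation(blend=0.45, noise_sd=0.13),
    Degradation(blend=0.35, noise_sd=0.13),
)


def simulate_model_bank(
    truth_mask: np.ndarray,
    degradations: tuple[Degradation, ...] = DEFAULT_DEGRADATIONS,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Simulate one probability map per degradation for a truth mask.

    With an all-zero degradation the map equals the truth mask exactly
    (the identity case used to validate the downstream plumbing).
    """
    truth = np.asarray(truth_mask, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    maps = []
    for d in degradations:
        soft = gaussian_filter(truth, d.blur_sigma) if d.blur_sigma > 0 else truth
        base = (1.0 - d.blend) * soft + d.blend * 0.5 + d.bias
        if d.noise_sd > 0:
            base = base + rng.normal(0.0, d.noise_sd, truth.shape)
        maps.append(np.clip(base, 0.0, 1.0))
    return maps


def split_patients(
    patients: list,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
) -> tuple[list, list, list]:
    """Seeded patient-level split: no patient's slices straddle sets."""
    total = n_train + n_val + n_test
    if total > len(patients):
        raise ValueError(
            f"requested {total} patients but only {len(patients)} available"
        )
    order = np.random.default_rng(seed).permutation(len(patients))
    picked = [patients[i] for i in order[:total]]
    return (
        picked[:n_train],
        picked[n_train : n_train + n_val],
        picked[n_train + n_val :],
    )
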