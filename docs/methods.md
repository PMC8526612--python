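# Methods

## The two-stage ensemble

Slice-by-slice processing of an axial series assumes lesions are
delineated independently per slice; no 3-D continuity is modelled. Four
probability-map producers feed both stages. Stage one reduces each map
to its maximum — "how confident is this model that *some* pixel is
tumor" — and takes the median of the four maxima, which for an even
count is the mean of the two middle order statistics. The median is
robust to one over-confident and one under-confident model
simultaneously; the maximum makes the statistic sensitive to small
lesions that affect few pixels. Stage two fuses by pixelwise mean, which
averages away independent per-model noise, and binarizes.

Boundary semantics are strict and intentional: a slice whose score
equals `T_c` is **positive** (the negative branch requires
`score < T_c`), and a pixel whose fused value equals `Mask_c` is
**negative** (the positive branch requires `g > Mask_c`). Classification
gates segmentation — every pixel of a negatively classified slice is 0
in the final mask regardless of its map values. Raising either threshold
can only remove positives (monotonicity, property-tested).

The bank size is fixed at four, matching the score's definition; a
different count would change the median's breakdown behaviour and is out
of scope.

## Threshold calibration

Candidate thresholds are the **unique observed values**, not a fixed
grid, so both selections are exact argmaxes verifiable by exhaustive
search. The slice ROC uses the decision rule `score ≥ t` and the pixel
PR curve uses `value > t`, matching the two equations exactly.

- `T_c = argmax (TPR − FPR)` (Youden). Ties → smallest threshold: among
  equally good operating points, prefer the one that classifies the most
  slices positive, minimizing missed tumor slices.
- `Mask_c = argmax F1` on the pixel PR curve pooled over the positively
  *classified* validation slices (false-positive slices contribute
  background pixels, as they would in deployment). Ties → smallest
  threshold, the recall-favouring choice for the same reason.
- ROC AUC is the trapezoidal integral, which equals pairwise concordance
  with half credit for ties (asserted against an independent oracle and
  scikit-learn).

A lesion-level detection-rate curve (lesion found iff any of its pixels
exceeds the threshold) is provided as a secondary view
(`calibration.lesion_detection_curve`); pixel-level pooling is the
default because it is the quantity the final mask threshold acts on.

## Preprocessing

Order: ROI → z-score → resize → min–max rescale → re-zero background.
All four intensity maps are strictly increasing on the ROI, so the
within-ROI rank order of pixels is invariant (property-tested); the
choice of order therefore affects interpolation detail only.

- **Snake ROI.** `skimage.segmentation.active_contour` initialised as a
  circle at 95% of the half-image, contracting under its elasticity
  term (α = 0.01, β = 1.0, γ = 0.002, ≤ 2500 iterations, convergence
  0.1) until the skull's edge energy stops it. The image is smoothed
  (σ = 3) and, if larger than 256 px, contoured at 256 and the polygon
  scaled back — sub-pixel differences only, large constant-factor
  savings. On analytic disks of radius 40–100 px the extracted area is
  within 5% of πr²; on default phantoms ≥ 99% of skull-exterior pixels
  are excluded. A constant image raises an explicit no-ROI error rather
  than guessing.
- **Z-score** uses the population (N) convention over ROI pixels only;
  a two-pixel ROI {10, 20} maps to exactly {−1, +1}.
- **Resize** is bilinear for images, nearest-neighbour for masks (masks
  must stay binary). The min–max rescale pins the within-ROI extremes to
  exactly −1 and +1; the background is then forced back to exactly 0.
- In the pipeline the snake runs **once per patient** (middle slice) and
  the contour is reused across the stack — the skull does not move
  within one series. Per-slice extraction remains available.

## The phantom and what it does (not) show

The generator emulates the geometry and the class imbalance of a
clinical head series: 512×512 slices, 3 mm thick, 48 slices/patient,
~20% tumor-bearing, 0.5 mm/pixel in plane (configurable; reported
per-pixel scales for such data are inconsistent, and nothing downstream
depends on the default). Skull annulus at radii 210–232 px, brain
texture from smoothed Gaussian noise (sd 10 on a mean of 100), tumors as
bright disks (+80) of radius 2–8 mm — single-slice volumes of roughly
0.04–0.6 ml, deliberately straddling the 0.15 ml filter. Slice
positivity is Bernoulli per slice, redrawn until the realised count is
within ±2 of the expected count, so every patient's imbalance is close
to the configured fraction while slices stay exchangeable. Lesion
volumes recorded by the generator are computed from the rasterized
masks, so they round-trip exactly through `metrics.volume_from_mask`.

Simulated model maps are built from the truth mask:
`clip((1−λ)·blur(truth) + λ/2 + bias + N(0, σ²))`. With no blur and no
bias the tumor and background distributions are mirror images about 0.5,
so the optimal binarization threshold is **t\* = 0.5 by construction** —
this is what lets calibration be validated by parameter recovery. Two
presets are shipped: `SYMMETRIC_DEGRADATIONS` (λ 0.30–0.45, σ 0.12–0.14,
no blur) for recovery experiments — the noise is strong enough that the
pooled pixel classes overlap and the max-F1 optimum is a unique interior
point rather than a plateau — and `DEFAULT_DEGRADATIONS` (milder noise
plus edge blur of 0.5–2 px) as the "moderately corrupted" bank for
end-to-end runs; blur softens lesion edges the way real models do and
pulls the F1 optimum somewhat below the midpoint, so no t* recovery is
claimed for it.

What passing phantom tests do **not** show: performance on real MRI.
The phantom has no bias fields, no partial-volume effects, no T1
contrast physics, circular anatomy, and disk-shaped lesions; tumor
contrast is fixed rather than heterogeneous. The tests validate the
*machinery* — equations, calibration, metrics, plumbing — not clinical
accuracy.

## Tiny U-Net

PyTorch-free NumPy implementation: 3 resolution levels, base width 8,
one 3×3 conv + ReLU per block, 2×2 max-pool, nearest-neighbour
upsampling, skip concatenations, 1×1 output conv, sigmoid. Trained with
Adam (lr 3·10⁻³, batch 2) on a combined soft-Dice + 0.5·BCE loss — the
Dice term converges fast under extreme pixel imbalance, the BCE term
stabilises probabilities. The trainer enforces the imbalance-avoidance
rule: only tumor-bearing slices are fitted, tumor-free slices being the
classification stage's job. Everything is seeded; two runs with the same
seed produce identical loss traces. The network's role is to be a real,
trainable producer behind the bank interface (it overfits 20 phantom
slices to Dice ≥ 0.9 within 300 steps on one CPU), not a clinical
segmenter.

## Metrics and intervals

IoU = |∩|/|∪|, Dice = 2|∩|/(|A|+|B|), related by
Dice = 2·IoU/(1+IoU) (asserted exactly). Both-empty pairs score 1.0;
aggregate reports also expose the average restricted to slices where
prediction or truth is nonempty (the default headline), since the
all-slices average is inflated by trivially perfect empty slices.
Connected components use 8-connectivity in-plane by default (4 is
available). The volume filter is strictly greater-than: exactly 0.15 ml
is removed. Proportions get Wilson score intervals (95%); per-image
IoU/Dice means get a 2000-replicate seeded percentile bootstrap, since
they are not proportions.

## Problem sizes and numerical choices

Default experiment sizes — 30 patients (10/10/10 split) for the
end-to-end run, 4 patients × 24 slices per recovery seed, 20 slices for
the overfit check — are chosen so the whole suite runs comfortably on a
single CPU while keeping binomial/bootstrap error well inside the
asserted tolerances. Determinism everywhere: phantom streams derive from
`(config.seed, patient_seed)`; simulated producers derive per-(model,
slice) streams via CRC32 of the slice id, so results are identical
across processes. Degenerate inputs (constant images, single-class
validation sets, empty training sets, zero denominators) raise explicit
errors or documented sentinels rather than NaNs.
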