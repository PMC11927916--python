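# Methods

## Coordinate conventions

Rasters are 0-based, x rightward, y downward, with half-open pixel
intervals `[lo, hi)`. Angles are measured in **display convention**
(y up): the polar sweep is counterclockwise as a clinician would read a
fundus photograph, which is clockwise in raster row order. The angular
origin is the nasal direction of an OD-oriented image. Which image side
is nasal depends on the capture setup and is not derivable from the
image alone; the default is image right (`nasal_side="right"`) and it is
configurable everywhere it matters. Likewise the quadrant order met when
sweeping counterclockwise from nasal defaults to superior → temporal →
inferior (superior at the top of an upright image) and can be permuted
via `pie_augment.isnt_regions`.

Left eyes are mirrored horizontally before any angular processing
(`orient_for_eye`), so one angular layout serves both eyes.

## ONH crop

The crop window is centred on the centre of mass of the binary disc
mask and spans `w_max·(1+Δ) × h_max·(1+Δ)` where `w_max`/`h_max` are the
mask bounding-box extents and Δ defaults to 0.5. Bounds are
floored/ceiled outward so no disc pixel is lost; windows that exceed the
image are clipped to the image extent with a log message, and any
remaining out-of-bounds crop area is zero-filled (black), matching the
black padding visible in typical ONH crops.

CLAHE runs on the L channel of CIELAB. Without an OpenCV dependency the
kernel is `skimage.exposure.equalize_adapthist`, which takes a clip
limit normalized to (0, 1]; the module keeps the conventional
histogram-clip parameter surface (default `clip_limit=2.0`, 8×8 tiles)
and maps it internally as `clip_limit / 100`. A constant image passes
through unchanged.

## Polar transform

Output pixel `(i, j)` samples the source at radius
`r = i·r_max/(R_h−1)` and angle `θ = j·360/R_w` degrees from the nasal
origin; bilinear interpolation, zero fill outside the image. The angle
of a source pixel is computed with the two-argument arctangent, which
covers the full 360° unambiguously (an arcsine of `y_d/r` alone cannot
distinguish left from right half-planes). Defaults `R_h = R_w = 224`
match the transformer input; `r_max` defaults to half the crop's shorter
side, and the centre to the disc-mask centroid when a mask is available,
else the crop centre. The inverse transform wraps the angular axis
across the nasal seam before resampling so interpolation is continuous
at 0°/360°, and zeroes everything beyond `r_max`.

Bilinear resampling bounds the round-trip error by the second derivative
of the image; on smooth synthetic input the mean absolute
reconstruction error inside the disc is below 0.01 (unit intensity
scale), which is the tolerance the tests assert.

## Pie augmentation

A quadrant's columns are those whose angular span intersects its degree
intervals, computed in exact integer arithmetic; for any `R_w` divisible
by 8 the four quadrants partition the columns exactly. Exclusion is
masking in polar space (fill = black), not geometric resampling, so the
model input size is preserved. Augmented copies supplement rather than
replace the originals, and only training-split rows are augmented; each
copy records its source image and excluded region.

The default policies are themselves screening results, shipped as plain
data and fully overridable: unanimous-agreement (3/3) data excludes the
superior quadrant for all classes and additionally the nasal quadrant
for glaucoma suspects; majority-agreement (2/3) data excludes the
superior and temporal quadrants for all classes.
`evaluate_region_ablation` re-runs the underlying experiment (one model
per excluded region, Δ-metrics against a no-exclusion baseline) at any
scale via a user-supplied training callback.

## Classifier harness

The backbone is the small data-efficient vision transformer: 16×16
patches of a 224×224×3 input (14×14 grid), embed width 384, 12 pre-norm
blocks with 6 attention heads and a 4× GELU MLP, learned position
embeddings, class + distillation tokens, and single-logit sigmoid heads
on both tokens (21,667,202 trainable parameters ≈ 22 M; ≈4.6 G
multiply–accumulates per forward). Because no deep-learning framework
is a dependency, the stack is implemented on numpy with a compact
reverse-mode autodiff engine; gradients are validated against central
finite differences in the test suite, and a `tiny` preset (2 layers, 2
heads, width 64, 32×32 input) keeps the identical code path trainable on
a CPU in seconds.

Training defaults follow the screening recipe: focal loss with γ = 2 and
α set to inverse class frequency (balanced class weighting; explicit
weights can be passed), the LAMB optimizer at a constant learning rate
1e-3 with no warmup, batch size 32, 100 epochs, and 5 stratified folds
(per-class fold counts differ by at most one). Distillation from a
teacher model is soft: the distillation-token logit is matched to the
teacher's temperature-softened sigmoid output (temperature 3.0, weight
0.5, scaled by τ²) — standard teacher–student defaults, since tier-to-
tier fine-tuning details beyond "teacher guides student" are not
prescribed anywhere.

The two binary outputs are combined by probability chaining —
`p(N) = 1 − p(GS)`, `p(G) = p(GS)·p(G|GS)`, `p(S) = p(GS)·(1 − p(G|GS))`
— the simplest composition consistent with the two-task design; the
result is always a point on the 3-simplex.

Focal-loss probabilities at exactly 0 or 1 are clamped at 1e-12 (1e-9
inside the training graph) and the clamp is logged; at γ = 0, α = 1 the
loss is exactly binary cross-entropy.

## Attention maps

Per layer and head, the post-softmax attention matrix is multiplied
elementwise by the gradient of the chosen class score with respect to
those attention weights; negative products are clamped to zero
(class-discriminative saliency) and heads are fused by their mean.
Layers are combined by attention rollout: each fused map is
row-normalized (zero rows left zero), identity-augmented, row-normalized
again and multiplied across layers in network order. Row-normalizing
before the identity augmentation makes the final min–max-normalized map
exactly invariant to a global rescaling of the gradients. The
class-token row restricted to patch tokens (the distillation token is
dropped) is reshaped to the 14×14 grid and min–max normalized; an
all-degenerate map falls back to a uniform grid with a warning. A
"last-layer only" view is available by passing a single layer map to the
aggregator. Overlays upsample the grid bilinearly to the polar raster,
warp it through the inverse polar transform and alpha-blend a jet
colormap onto the reverse-polar image.

## Metrics

Accuracy, sensitivity, specificity and precision are the usual
confusion-count ratios in percent; F1 is the harmonic mean of precision
and recall. Multiclass evaluation binarises one-vs-rest per class.
Macro-averaged F1 is the unweighted mean, weighted-average F1 the
support-weighted mean, and micro-average F1 the F1 of pooled TP/FP/FN —
which for single-label one-vs-rest problems equals pooled accuracy, and
can therefore also be computed from per-class recalls and supports. ROC
AUC is trapezoidal integration of TPR against FPR over all score
thresholds; tied scores form a single ROC vertex, crediting half of each
tied pair, so the value coincides with the Mann–Whitney
correctly-ordered-pair fraction (asserted to 1e-12 in tests).

Values are kept at full precision internally and rounded half-up to two
decimals only at presentation. Metrics with zero denominators are
reported as explicit nulls, never as zero. One published table row for
the unanimous-agreement glaucoma class prints an accuracy of 94.71%
that is inconsistent with the counts implied by its own sensitivity
(93.02), specificity (95.00) and supports (86/120), which yield
(80 + 114)/206 = 94.17%; this implementation always reports the value
computed from the counts.

## Synthetic data

Each synthetic crop is built from an elliptical disc (horizontal
semi-axis 0.92 × vertical, mimicking the slightly vertically oval disc),
a cup boundary obtained by subtracting an angular rim-thickness profile
from the local disc radius, vessel-like wobbling curves radiating from
the centre, a low-frequency Gaussian illumination field (so CLAHE has
real work to do) and additive Gaussian pixel noise (σ = 0.015 intensity
units). The rim profile interpolates per-quadrant multipliers
(normalized to mean 1) periodically over angle; an optional Gaussian
notch deepens focal thinning. Masks are exact 0/255 fills of the same
boundaries; an OS sample is the bitwise horizontal mirror of the OD
sample with the same seed.

Class presets are configuration, not measured biology — no quantitative
per-class rim-thickness distributions are published for this population,
so values were fixed once at clinically plausible magnitudes: healthy
(N) CDR 0.40 with ISNT-ordered multipliers 1.30/1.10/0.90/0.70
(I/S/N/T); suspect (S) CDR 0.60 with a borderline superior-over-inferior
violation; glaucoma (G) CDR 0.75 with marked inferior thinning plus a
notch at 270° (depth 0.5, width 25°). Per-sample jitter: CDR ± 0.03 SD,
disc radius ± 10%, 3–6 vessels, random eye side. Cohorts default to
448-px crops (so a Δ = 0.5 crop lands near a 224-divisible size; a
full-frame 1,600×1,216 rendering is available via `frame_size`) and to
study-like split fractions 0.77/0.19/0.04 (train/val/test,
largest-remainder per class).

What passing tests on these images do show: the geometric plumbing
(crop, polar, pie, overlays) is exact, the training loop optimizes, and
class-separable signal is learnable end-to-end. What they do not show:
performance on real fundus photographs, which carry pathology,
pigmentation, illumination and camera variation the generator does not
attempt to model (no peripapillary atrophy, hemorrhages, or realistic
texture).

## Problem sizes used in the bundled checks

The automated checks run the tiny backbone on cohorts of a few dozen
32–224 px synthetic images and a 6-epoch training budget — sizes chosen
so the full suite runs on a single CPU in well under a minute of compute
per test while still exercising every code path at the real 224-px
DeiT-S scale where only construction (not training) is needed.
Full-scale replication of the screening performance would require the
original patient dataset and GPU training, and is explicitly out of
scope.

## Known limitations

- The numpy training loop is CPU-bound and float64; it is meant for
  desk-scale experiments and correctness, not for training the full
  backbone on thousands of images.
- The nasal-side and quadrant-order conventions are configurable
  defaults, not ground truth; deployments must set them to match their
  camera orientation.
- The three-class chaining assumes the two binary models are calibrated
  on their own conditionals; no joint calibration is performed.
- The synthetic generator's effect sizes are configuration (see above);
  absolute metric values on synthetic cohorts carry no clinical meaning.
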