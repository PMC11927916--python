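# glaupie

Glaucoma-screening toolkit built around three ideas from ophthalmic image
analysis:

1. **ISNT-aligned polar preprocessing.** The optic nerve head (ONH) is
   cropped from a fundus photograph by a centroid-padding rule around the
   segmented optic disc, contrast-enhanced with CLAHE, and resampled into
   polar coordinates `(r, θ)` about the disc centre with the **nasal**
   direction as the angular origin. Left eyes (OS) are mirrored first so
   the angular layout is consistent across eyes. In polar space the cup,
   the neuroretinal rim and the retina become horizontal bands, which
   matches both the clinician's ISNT reading of the rim (healthy rims
   order Inferior > Superior > Nasal > Temporal in thickness) and the
   row/column patch grid of a vision transformer.

2. **Pie-slice augmentation.** Each ISNT quadrant is a 90° angular
   sector — a column band of the polar raster (the nasal band straddles
   the seam: `[0°, 45°) ∪ [315°, 360°)`). Blanking one quadrant produces a
   pie-shaped cut and forces the classifier to learn from the remaining
   regions. Augmentation policies map *(agreement tier, class)* to the
   quadrants to exclude; the shipped defaults exclude the superior region
   for every class (plus nasal for suspects) on unanimous-agreement data,
   and superior + temporal on majority-agreement data.

3. **A data-efficient vision transformer (DeiT-S) harness.** Two binary
   sigmoid-head models — glaucoma-or-suspect (GS) vs. no glaucoma (N),
   and glaucoma (G) vs. suspect (S) — trained with focal loss, the LAMB
   optimizer, stratified 5-fold cross-validation, and optional
   teacher–student distillation through the DeiT distillation token. The
   two outputs chain into three-class probabilities:
   `p(N) = 1 − p(GS)`, `p(G) = p(GS)·p(G|GS)`, `p(S) = p(GS)·(1 − p(G|GS))`.
   Gradient-weighted attention maps (attention × class-score gradient,
   clamped, head-mean fused, rolled out across layers) are warped back
   through the inverse polar transform for clinician-readable overlays.

The transformer stack (reverse-mode autodiff, ViT, LAMB) is implemented
on numpy in `glaupie.nn`; gradients are verified against finite
differences in the test suite. A bundled synthetic ONH generator
(elliptical disc/cup, per-quadrant rim profiles that obey or violate the
ISNT rule, vessels, noise, both eye sides) makes every stage testable
without patient data.

## Worked example

Profile the DeiT-S backbone (12 layers × 6 heads, 16×16 patches of a
224×224 input → a 14×14 token grid plus class and distillation tokens):

```bash
$ glaupie profile
{
  "parameters": 21667202,
  "parameters_millions": 21.67,
  "macs_billions": 4.62
}
```

21,667,202 trainable parameters round to the canonical 22 M for this
architecture, and one forward pass costs ≈4.6 billion multiply–
accumulates.

Evaluation-table arithmetic, e.g. combining a suspect-class precision of
71.43% with a recall of 88.24% and averaging per-class F1 scores over a
{G: 86, S: 17, N: 103} test split:

```python
>>> from glaupie.metrics import averaged_f1, f1_from_precision_recall, round2
>>> round2(f1_from_precision_recall(71.43, 88.24))
78.95
>>> f1s = {"G": 93.02, "S": 78.95, "N": 95.05}
>>> round2(averaged_f1(f1s, mode="macro"))
89.01
>>> round2(averaged_f1(f1s, {"G": 86, "S": 17, "N": 103}, "weighted"))
92.87
```

An end-to-end desk-scale run (synthetic cohort → crop → CLAHE → polar →
pie augmentation → tiny-backbone training → evaluation → attention
overlay):

```bash
glaupie run            # default tiny configuration
glaupie run --config my_run.yaml
```

which writes manifests, checkpoints, `metrics.json`, an
`explanation_overlay.png` and a `reproducibility.json` (seed, config
hash, versions) under the output directory. The individual stages are
also exposed as subcommands: `synth`, `crop`, `polar`, `pie`, `train`,
`explain`, `evaluate`, `profile`.

## Layout

- `glaupie.synthetic_fundus` — synthetic ONH crops, masks, cohorts.
- `glaupie.onh_crop` — centroid-padding crop (Δ = 0.5 default), CLAHE.
- `glaupie.polar_transform` — nasal-origin polar resampling and inverse.
- `glaupie.pie_augment` — ISNT quadrant column bands, exclusion policies,
  region-ablation driver.
- `glaupie.classifier_harness` — DeiT-S/tiny backbones, focal loss, LAMB,
  stratified folds, distillation, three-class chaining, profiling.
- `glaupie.attention_maps` — gradient-weighted attention rollout and
  reverse-polar overlays.
- `glaupie.metrics` — confusion-based metrics, micro/macro/weighted F1,
  trapezoidal ROC AUC, report assembly.
- `glaupie.cli_io` / `glaupie.cli` — manifests, YAML config, pipeline,
  `glaupie` console entry point.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
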