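# Methods

This note documents the models, numerical choices and known limits of
the flytrap pipeline: what the synthetic scenes emulate, how detection
and classification are parameterized, and what the shipped tests do and
do not establish about real trap imagery.

## Synthetic scene model

A scene is a yellow panel (RGB ≈ (0.85, 0.78, 0.22) unit scale,
optionally inset on a grey surround) composed in floating point and
quantized to 8-bit at the end:

1. planted shapes are drawn (shadows first, as multiplicative
   darkening; then solid shapes);
2. a multiplicative linear illumination ramp with peak-to-peak relative
   range `illumination_gradient` (default 0.2) and random direction is
   applied to the whole scene;
3. optional day-level brightness/contrast jitter (sequences only);
4. additive Gaussian pixel noise with SD `noise_sd` (default 2.0 8-bit
   units), then clip/round to uint8.

All randomness comes from one `numpy` generator seeded by the scene
seed, so a fixed seed gives bit-identical images and annotations.

### Element morphology

| kind | geometry | intensity |
|---|---|---|
| olive fly | ellipse, full major axis 14–20 px, aspect 2.2–3.0, random orientation | near-black shade 0.04–0.10, plus a pale wing-spot mark (shade 0.72–0.88, ~0.3–0.4 of body size) kept inside the body |
| other fly | ellipse, full axis 8–30 px, aspect 1.2–2.0 | shade 0.14–0.24, no mark |
| attractant bag | axis-aligned rectangle 60–120 × 80–160 px | 0.30 grey-brown |
| panel hole | disk, radius 4–10 px | 0.05 |
| shadow | ellipse, semi-axis 20–50 px | multiplicative 0.78–0.88 (deliberately below detection contrast) |
| printed glyph | 2–4 thin strokes (3 px wide, 10–25 px long) | 0.15 |

The fly classes are a morphology *proxy*: no field morphometry was
available, so the separation (size, aspect, the wing-spot, and the
dark-vs-paler shade split) is a design choice made once to give the
classifiers a learnable signal, consistent with the olive fly's
distinctly dark body and marked wings. It is not a claim about real
*B. oleae* appearance, and accuracy numbers on synthetic crops do not
transfer to field images.

Placement is rejection sampling (200 attempts per element) under a
box-overlap constraint (default: no overlap); failure raises a
placement error naming the failing count. Ground-truth boxes are
0-based, half-open, row-major, computed from the rasterized footprint;
each element carries a stable id and its pixel area.

### Sequences

Multi-day series emulate a trap between panel replacements: elements
persist at fixed positions (per-day retention probability
`persistence`, removal permanent, default 1.0), new olive flies arrive
with a Poisson count at `arrival_rate` per day (drawn on every day,
including the first, from a dedicated substream so that day 1 with rate
0 is bit-identical to a single-scene render), and each day gets fresh
noise plus brightness (±0.06) / contrast (0.9–1.1) jitter. This is the
"organic augmentation" a real trap provides: the same fly seen under
different lighting.

## Detection

* **Panel segmentation** — HSV thresholding: hue in [0.07, 0.25],
  saturation ≥ 0.25, value ≥ 0.15; morphological closing (disk radius
  5); largest connected component; hole filling (insects are dark holes
  in the yellow mask but lie on the panel). If the mask covers < 5% of
  the frame, a "no trap found" error is raised.
* **Dark-element localization** — the darkness threshold on the value
  channel inside the mask is `dark_ratio` × median panel value
  (default 0.6), a relative rule that adapts to global lighting and
  returns nothing on an empty panel. An Otsu split of the in-mask
  values refines (lowers) the threshold only when it is at least half
  that ceiling: a raw Otsu threshold can land *between* two dark
  sub-populations (near-black vs merely dark insects) and silently drop
  the paler ones, which is why Otsu is the refinement rather than the
  rule. Components with area in [min_area, max_area] (defaults 30 and
  3000 px at 1600×1200, scaled by frame area) become boxes, sorted by
  (y, x). Touching insects merge into one component and yield one box;
  no watershed splitting is attempted.
* **Crop extraction** — a fixed 32×32 window centred on the box
  centroid, shifted inward at borders, never rescaled.

## Augmentation

Four binary, label-preserving techniques in a fixed order: vertical
flip, horizontal flip, one clockwise 90° rotation, and a joint
brightness/contrast change (contrast factor in [0.8, 1.2] about
mid-level, brightness shift in [−20, +20] 8-bit units, sampled
jointly). Treating the rotation and the brightness/contrast change as
single binary choices is what makes the combination count exactly
2⁴ = 16. The stochastic procedure draws k ~ uniform{0..max_new}
(default 10) new crops per sample and fires each technique with
probability 0.5; per-sample substreams are keyed by (seed, sample
index), so results are reproducible and insensitive to batching.
Augmentation is refused outside the training partition.

## Classification

Features are the flattened 32×32×3 patch divided by 255 (length 3072);
no descriptors, no standardization — the learners see the crop
directly. Defaults (the deployed values): RF with 3 bootstrap trees,
Gini splits, max depth 20, min samples split 5; SVM with polynomial
kernel, C = 0.1, γ = 1. The polynomial degree is set to 3 as the
conventional default. After every SVM fit the dual solution is checked:
0 ≤ αᵢ ≤ C and |Σ αᵢ yᵢ| < 10⁻⁶ (scikit-learn stores yᵢαᵢ, so αᵢ is
the magnitude); a violation raises.

Splitting is stratified per class with floor(count × 0.1) validation
samples and seeded shuffling. Grid search is exhaustive over declared
grids (RF trees {3, 10, 50} × depth {5, 10, 20} × min-split
{2, 5, 10}; SVM kernel {linear, poly, rbf} × C {0.1, 1, 10} × γ
{0.01, 0.1, 1}) scored by stratified 5-fold CV accuracy; ties go to the
simpler model (fewer trees, then smaller C), then grid order. Class
imbalance is left unweighted.

The ensemble verdict is the logical AND on the positive class, chosen
because a pest alarm should under-call rather than over-call: the
positives are exactly the intersection of the two models' positives,
which bounds the ensemble's false positives by each model's and its
false negatives from below by each model's.

## Evaluation

Scalar metrics are kept as proportions in [0, 1]; multiply by 100 when
reporting percent. Zero-denominator cases (precision with no positive
predictions, etc.) return 0.0 with a warning so that daily aggregates
stay defined. ROC curves sweep all unique scores (RF score = fraction
of trees voting positive; SVM score = signed decision value oriented
toward the positive class) and AUC is trapezoidal, equal to the
Mann–Whitney pairwise-concordance probability — the test suite checks
that equivalence against a brute-force oracle.

Detection matching is greedy one-to-one by descending IoU with
threshold 0.3 (crops are small and localization coarse; configurable).
Daily series report TP/FP/FN per model with fn defined as
true_count − tp, so tp + fn ≡ true_count by construction.

## Telemetry

Aberrant readings are those outside the sensor's physical range
(−40..80 °C, 0..100 %RH) or non-finite; they are excluded from the
hourly max/min/mean but counted, so n_valid + n_aberrant equals the
parsed rows per hour. Hours are half-open wall-clock buckets; an hour
with no valid readings reports n_valid = 0 and absent statistics.
Malformed CSV rows are skipped with a warning and counted, never fatal.

## Problem sizes in the shipped tests

The suite runs entirely on synthetic data generated at test time:
classifier tests use 1,000 crops (500 olive flies / 500 others, 9:1
split); detection-recall tests use 50 scenes at 800×600 with 12
elements each (shadows excluded there — they are deliberately
sub-threshold — and the bag covered by a wider max_area); augmentation
volume is checked at the 1,332-crop scale; Monte-Carlo checks use
200 seeds (arrivals) and 10,000 draws (augmentation counts). These
sizes keep the full suite under a minute of compute for everything but
model fits.

## Limitations

* Synthetic scenes have no JPEG artefacts, no optics blur or white
  balance drift, no occlusion between elements, and the fly classes are
  parametric shapes; passing tests demonstrate the pipeline's logic and
  its behaviour under the modelled variability, not field accuracy.
* Touching flies are counted as one element.
* The detector's colour band assumes a yellow panel; other trap colours
  need re-configuration.
* Arrival dynamics are homogeneous Poisson; real arrivals are
  weather-driven and clustered.
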