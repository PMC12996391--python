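# Methods

`spinesrh` implements a complete intraoperative diagnosis pipeline for
stimulated Raman histology (SRH) of spinal tumors and the evaluation battery
used to assess it. This note records the model, the design choices where the
design was genuinely open, the tunable parameters, and what the synthetic
benchmark does and does not establish.

## Imaging model and preprocessing

An SRH slide is a pair of co-registered 16-bit grayscale images at two Raman
shifts: 2845 cm^-1 (CH2 symmetric stretch, lipid-rich structures) and
2930 cm^-1 (CH3-rich protein/DNA regions). The classifier input is a
three-channel composite in the fixed order (CH3−CH2, CH2, CH3). How negative
difference pixels (CH2 > CH3) should be stored is not standardized; the
package clips them to zero by default — preserving the 16-bit range and the
protein-minus-lipid contrast intent — with a signed-offset mode available
(`compose_three_channel(..., negative_mode="signed")`).

Slides are tiled into non-overlapping 300 × 300 patches with a 300-pixel
stride, row-major, 0-based (row, col) anchors, half-open pixel blocks.
Trailing pixels that do not fill a complete window are dropped; tiling is
therefore a partition of the cropped image and reassembly is bit-exact.

Patch QC assigns each patch one of {tumor, normal, nondiagnostic}. External
labels (e.g., from a dedicated tissue segmentation model) always take
precedence. Without them a two-threshold heuristic stands in: a patch whose
CH3 variance is below 10^5 (16-bit units squared) is near-blank and
non-diagnostic; otherwise the high-frequency detail energy — the variance of
the residual after a Gaussian blur with sigma = 6 px — separates smooth
normal tissue (< 2×10^5) from structured tumor tissue. These constants were
calibrated once against the phantom generator's noise scales and recover its
block-level ground truth essentially exactly.

Slide inclusion: a slide enters analysis iff its non-diagnostic fraction is
at most 0.90 (inclusive), it has at least one tumor patch, and its
normal-tissue fraction is at most 0.50 (exclusion strict at > 0.50). The
normal fraction is measured over all patches of the slide.

## Self-supervised representation learning

Patch embeddings are learned without labels by an asymmetric student/teacher
scheme. The student is encoder f_θ → projector g_θ → predictor q_θ; the
teacher is encoder f_ξ → projector g_ξ, deliberately without a predictor.
For each patch two views are drawn independently from an augmentation pool
(flips, sharpness, Gaussian blur, Gaussian noise, autocontrast, solarize,
erasing, affine, resized crop). The loss is the normalized negative cosine
similarity L = 2 − 2·⟨p, z′⟩/(‖p‖‖z′‖) between the student prediction on one
view and the teacher projection of the other, symmetrized over the two view
orders. The student updates by Adam with cosine learning-rate decay; the
teacher only through the exponential moving average ξ ← τ_ema ξ + (1−τ_ema)θ
(default τ_ema = 0.996, constant) and never receives gradients. Only the
student encoder is kept.

Design choices in this module:

- **Numerics.** All networks run on an in-repo numpy reverse-mode autodiff
  core (`spinesrh.nn`); gradients are verified against central finite
  differences in the test suite to 1e-6 (conv stack) and 1e-4 (end-to-end
  attention head).
- **Encoder.** The default encoder is a compact convolutional network:
  block-mean pooling of the working-resolution input to a 30 × 30 grid, two
  3 × 3 conv/ReLU/average-pool stages (8 and 16 channels), a linear map to
  the embedding and one residual MLP block; embedding dimension k = 128.
  A full ResNet-50 is the natural scaled-up choice for production use but is
  far outside single-CPU training budgets; the encoder family is a config
  argument.
- **Working resolution.** `train_ssl` augments and encodes at a reduced
  working resolution (default 60 × 60, block-mean of the 300 × 300 patch).
  The augmentation operators themselves are resolution-preserving and honor
  the full 300 × 300 contract when applied to full-size patches.
- **Augmentation defaults.** The per-transform probabilities are package
  defaults: flips 0.5 each, resized crop 0.5 (scale 0.7–1.0), affine 0.25
  (±15°, ±8% translation, 0.9–1.1 scale), blur 0.3, noise 0.25
  (sigma = 2% of range), sharpness 0.2, erasing 0.10, autocontrast 0.05,
  solarize 0.05. The intensity-normalizing transforms (autocontrast,
  solarize) are kept rare deliberately: mean-intensity and contrast carry
  genuine class information in SRH-like data, and a representation trained
  to be invariant to them measurably loses class signal (we observed
  cross-cohort patch accuracy dropping from ~0.85 to ~0.5 when they were
  applied at 0.2/0.1). All probabilities and ranges are config fields.
- **Monitoring.** 10% of patches, held out by slide, monitor the loss; they
  contribute no gradients.

## Embedding-token self-attention classifier

The frozen k-dimensional embedding is restructured into t = k/d contiguous
tokens of length d (default d = 16, so 8 tokens; concatenating tokens in
order reproduces the embedding exactly). A stack of 2 pre-norm residual
attention blocks (4 heads, d_k = d/h, 2× FFN) processes the token sequence;
Attention(Q,K,V) = softmax(QKᵀ/√d_k)V. Token outputs are mean-pooled (no CLS
token) and a single softmax layer maps to the four class probabilities in
the fixed order (meningioma, schwannoma, ependymoma, metastasis); every
probability vector in the codebase uses this order. Positional encodings are
off by default — the tokens are fixed embedding segments, so identity is
already positional — with a learned-positional option considered unnecessary
at this scale. Training minimizes cross-entropy against patient-level
labels, with a validation split grouped by patient and stratified by class
(at least one held-out patient per class); the checkpoint with the best
validation mean class accuracy is kept. Embeddings are standardized
(per-coordinate z-score on the training split); the statistics are stored
with the trained model. A linear softmax head with the identical training
protocol serves as the ablation baseline.

## Aggregation, calibration, confidence

Patch probability vectors are averaged into a slide vector (identical to
sum-then-renormalize; the identity is tested). Platt scaling is fitted
one-vs-rest on the *training* cohort's slide-level scores: for class c a
sigmoid a_c·logit(p_c) + b_c (implemented via unregularized logistic
regression on the logit scores), applied and renormalized. Calibrating at
slide level and then aggregating calibrated slide vectors to patients by
patch-count-weighted means keeps the per-slide confidence definition
(C_s = max calibrated probability) and the patient confidence
C_patient = Σ n_s C_s / Σ n_s internally consistent; patch-level calibration
is available behind a config switch. The per-class sigmoid is monotone, so
per-class rankings and AUROC are unchanged by calibration (pre-renormalization).

The empirical low-confidence threshold is τ_conf = (C_correct + C_incorrect)/2,
where each group mean is the patch-count-weighted mean confidence over all
slides of correctly (resp. incorrectly) classified patients. The weighting
is applied across all slides in the group (not per-patient first) — the most
direct reading of a patch-count-weighted group mean. Patients with
C_patient < τ_conf (strict) are flagged for additional tissue sampling or
repeat imaging; equality is not flagged. If the derivation cohort contains
no incorrect patient (common on well-separated synthetic cohorts), the
derivation raises and the pipeline falls back to a manual default (0.5) with
a warning. Argmax ties are broken by the canonical class order, with a
logged warning.

## Heatmaps

The probability heatmap H is height × width × 4; every pixel of a patch
block carries that patch's vector. Non-diagnostic blocks and margins hold
NaN sentinels — never fabricated probabilities — and render as plain image.
The overlay is V = (1−α)·I + α·Σ_c H[:,:,c]·C_map(c) in continuous mode; the
default discrete mode paints each block with its argmax class color at full
saturation (α default 0.4). Colors: meningioma yellow (the externally
anchored choice), schwannoma green, ependymoma blue, metastasis red. The
virtual-H&E rendering used under overlays is a deterministic two-color
lookup (difference channel → hematoxylin-like hue, CH2 → eosin-like hue),
for display only.

## Evaluation battery

Per-class one-vs-rest sensitivity, specificity, PPV, NPV, balanced accuracy
((sens+spec)/2), and rank-based AUROC with half-credit ties; macro averages
over the four classes (undefined markers — e.g., a class absent at one site
— are excluded with a warning). Confidence intervals are percentile
intervals from a cluster bootstrap: patients are resampled with replacement
and all their slides travel together; B = 1000 by default. The percentile
method (rather than BCa) was chosen for transparency; its coverage is
near-nominal for cohorts of ~100 patients per class and degrades to ~0.91
at 40 per class — a small-sample property of percentile intervals on
bounded, discrete statistics, verified in the coverage simulation.

Calibration: multiclass Brier score (mean over cases of Σ_c (p_c − y_c)²)
with per-class components, and per-class expected calibration error with 10
equal-width bins (the bin count is a package default). Decision-curve
analysis uses the standard net-benefit definition
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) with treat-all/treat-none references.
Prevalence sensitivity recomputes PPV/NPV by Bayes' rule under named
prevalence scenarios. Robustness analyses: a one-random-slide-per-patient
resampling of the macro balanced accuracy, and the patch-count effect
analysis (two-sided Mann-Whitney U on patch counts by correctness, plus a
univariate logistic regression of correctness on patch count reporting the
odds ratio, its CI, and percent-per-patch = (OR−1)·100; perfect separation
yields a partial report with warnings). Stratified reports are generic over
any grouping column; the head ablation reports per-class and macro
balanced-accuracy differences with a paired cluster bootstrap.

## Synthetic phantom cohorts

The generator emulates the *structure* of an SRH cohort, not Raman physics:
two-channel 16-bit slides, a patient → slides → patches hierarchy, and four
texture motifs chosen to echo named histologic features — filled circular
high-CH3 blobs (psammoma-body/whorl-like) for meningioma, oriented
fascicle-like stripes (35° ± 6°) for schwannoma, annular rosette-like rings
for ependymoma, and coarse high-variance speckle (20 px cells) for
metastasis — plus smooth lipid-rich (CH2-dominant) normal-tissue texture and
near-blank background. Regions are allocated on the 300 × 300 block grid
(defaults: 25% non-diagnostic, 15% normal), so every patch has exact ground
truth. CH3 exceeds CH2 on average in all cell-rich textures. Default slide
size is 900 × 1200 (12 patches) to keep CPU budgets small. A global cohort
seed expands to per-slide seeds via `SeedSequence([seed, slide_index])`, so
any slide regenerates independently; identical seeds are bit-identical.

Two invariants make the benchmark meaningful: handcrafted variance/
orientation-energy features linearly separate the four motifs at ≥ 95% patch
accuracy (so the learning stack has signal to find), and non-diagnostic
blocks fall below the QC variance threshold (co-designed constants).

What passing the synthetic recovery does **not** show: robustness to
instrument variation, staining-free artifacts, intra-class morphological
heterogeneity, site effects, or class imbalance of real cohorts. The
phantom's classes are far better separated than real histology; the
end-to-end benchmark validates the *mechanics* (information flow, seeding,
calibration, thresholding, reporting), not clinical performance.

The probability fixture (`make_probability_fixture`) draws (label,
probability-vector) pairs whose stated top-class confidence follows a
prescribed reliability profile exactly in expectation, giving closed-form
oracles for Brier/ECE/DCA tests.

## Study conditions for the end-to-end benchmark

Defaults in `PipelineConfig`: 8 patients per class in each of two
independently drawn cohorts (train and test), 1–2 slides per patient, 20
self-supervision epochs, 15 classifier epochs, working resolution 60,
bootstrap B = 300 in reports (B = 1000 remains the module default for
standalone evaluation). On these conditions the pipeline reaches ≥ 90%
patient-level macro balanced accuracy (3-seed median; typically 98–100%),
and the permutation control — training on permuted labels and scoring
against independently permuted test labels — sits at the four-class chance
level of 25%. Problem sizes were chosen to keep a single run within a
couple of minutes on one CPU.

## Known limitations

- The numpy networks are desk-scale; no GPU path, no ResNet-50 weights.
- The QC heuristic is a stand-in calibrated to the phantom generator; on
  real data external segmentation labels should be supplied.
- Platt slopes can be negative when scores are uninformative for a class;
  monotonicity guarantees assume informative fits.
- Percentile bootstrap CIs undercover below ~50 clusters (see above).
- The virtual-H&E rendering is a display-only lookup table, not a validated
  stain transform.
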