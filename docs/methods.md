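# Methods

`petnodule` implements a complete volumetric deep-learning experiment for
discriminating benign from malignant solid pulmonary nodules on FDG-PET,
from data synthesis to statistical evaluation and saliency explanation.
This note records the models and procedures, the parameters that matter,
the numerical conventions, and the design choices made where more than one
reasonable option existed.

## The classification problem

Each subject contributes one solid, indeterminate pulmonary nodule
(8–30 mm) imaged with 2-[18F]FDG PET.  The input to the classifier is a
single-channel 40×40×40 tensor: a 60 mm cube of SUV intensities at 1.5 mm
isotropic spacing, centred on the nodule.  The target is the binary
malignancy status.  The baseline biomarker is SUVmax, the maximum SUV in
the nodule sphere; the experiment asks whether a 3D CNN trained on the
full cube discriminates better than SUVmax alone.

## Phantom cohorts (`petnodule.phantom`)

Real cohorts of this kind are private, so the package ships a seeded
phantom generator whose defaults reproduce the statistical structure the
analysis assumes: 113 subjects, 45.1% malignant prevalence (51/62 split),
nodule diameters log-normal with median 13 mm and IQR 5 mm truncated to
(8, 30] mm, isotropic 1.5 mm target resolution.

A phantom is built on an anisotropic native grid (default 2.0×2.0×3.0 mm
over a 90 mm field, emulating scanner-native spacing) as:

1. uniform physiological background (1.0 SUV);
2. one ellipsoidal nodule near the volume centre (jitter ≤ 3 mm,
   mirroring the centre-of-crop convention), per-axis radii jittered ±20%
   around diameter/2, filled with `background × contrast` where the
   contrast ratio is log-normal with median 4.0 (malignant) or 1.5
   (benign) and log-sd 0.35, clipped below at 1;
3. `n_distractors` (default 3) peripheral Gaussian hot spots emulating
   physiological uptake, at least 15 mm from the nodule;
4. Gaussian point-spread blur of 6 mm FWHM — typical reconstructed PET
   resolution — which produces the realistic partial-volume contrast loss
   for small nodules;
5. additive Gaussian noise (sd 0.1 SUV) truncated at zero, matching the
   additive-Gaussian noise model used elsewhere in the pipeline rather
   than Poisson counting noise.

The log-normal size-law sigma comes from the closed form
`IQR = median·(t − 1/t)`, `t = exp(q₇₅σ)`, so the printed median/IQR are
matched before truncation; truncation at 8 mm shifts the realised median
up by ≈0.3 mm, well inside the acceptance band.  The class-contrast
defaults make the task learnable but imperfect: the implied latent AUC of
ideal peak-uptake reading is ≈0.97, and the empirical SUVmax AUC on
phantom cohorts is ≈0.93.  No published SUV distribution underlies these
values; they are the package's own study conditions, fixed once.

What the phantoms do **not** emulate: CT anatomy, attenuation or
reconstruction artefacts, respiratory motion, textural or shape cues of
malignancy, non-solid nodules.  A passing end-to-end test therefore shows
that the pipeline recovers an uptake-contrast signal at realistic size,
noise and prevalence — not that the networks would reach any particular
performance on clinical data.

Determinism: the cohort seed spawns independent per-subject
`SeedSequence` streams, so cohorts are reproducible to the byte and each
subject's volume is invariant to cohort ordering.

## Preprocessing (`petnodule.preprocess`)

* **Resampling** to 1.5 mm isotropic voxels by trilinear interpolation
  (SimpleITK).  The output grid keeps the input origin and chooses its
  size so every sample lies inside the input (extent preserved within one
  voxel, no extrapolation).
* **Cropping**: a 60 mm cube (40 voxels) centred on the voxel nearest the
  annotated nodule centre; out-of-grid regions are zero-filled.  With an
  even side the centring tie is fixed: the nodule-centre voxel occupies
  index 20 on each axis.
* **Normalisation**: min–max to [0, 1] with *global scalar* statistics
  over every voxel of the fold's training tensors.  Per-volume scaling
  would erase inter-subject SUV contrast — the very signal of interest.
  Validation and test tensors reuse the training statistics and may fall
  outside [0, 1]; they are not clipped by default (information
  preserving), with a `clip` flag for sensitivity analysis.
* Statistics are fitted on original (pre-augmentation) training tensors
  and then applied to the augmented copies; fitting after augmentation is
  a one-line alternative the API permits but does not default to.

Coordinates are 0-based voxel indices, axis order (x, y, z) with z axial,
physical position = origin + index × spacing (voxel-centre convention).

## Augmentation (`petnodule.augment`)

Offline, class-balanced, one transform per augmented example, applied to
normalised tensors:

| transform    | minority (malignant) | majority (benign) | parameters |
|--------------|----------------------|-------------------|------------|
| translations | 20                   | 16                | integer shifts, each axis uniform in ±10 voxels (15 mm), zero fill |
| rotations    | 21 (7 per axis)      | 15 (5 per axis)   | one axis per example, angle uniform in ±45°, in-plane bilinear interpolation, zero fill |
| noise        | 20 (7, 7, 6)         | 16 (6, 5, 5)      | additive Gaussian, sd 0.1 / 0.3 / 0.5 on the [0,1] scale |

One minority original yields 61 augmented tensors, one majority original
47; a 41/49 training set grows to 41·62 + 49·48 = 4894 images, and the
post-augmentation minority fraction lands at ≈0.52.  Choices made here:
translations draw all three axis shifts jointly (the all-zero shift is
re-drawn); rotation angles below 1° are excluded to avoid near-duplicate
copies; noise sigmas are read on the normalised intensity scale, since
values of 0.3–0.5 SUV would be implausibly large relative to a 1 SUV
background but are natural fractions of the [0,1] range.  Rotations are
"composite" operations about the tensor centre (translate to centre,
rotate, translate back) realised by `scipy.ndimage.rotate` on the two
in-plane axes, which is exactly per-slice bilinear interpolation.
Per-subject augmentation streams derive from `plan.seed XOR
crc32(subject_id)`, so datasets are reproducible subject by subject.

## Architectures (`petnodule.models`, `petnodule.nn`)

Three 3D CNN families, all ending in a single sigmoid unit, He-initialised
(N(0, 2/fan_in) kernels, zero biases), LeakyReLU (α = 0.3) activations on
convolutions and hidden dense layers, L2 weight decay on kernels only
(penalising biases is uncommon and was left as an explicit toggle):

* **stacked3d** (the final-model family): conv(8)–pool–conv(16)–pool–
  conv(32)–pool–conv(64)–flatten–fcn(32, 16, 1); valid 3³ convs, 2³/2
  valid pools.  Spatial chain 40→38→19→17→8→6→3→1; flattened width 64;
  75 537 parameters.
* **vgg_like**: conv(8)–opool–conv(16)×2–opool–conv(32)×3–opool–flatten–
  fcn(1) with overlapping same-padded 3³/2 pools (ceil division).  Chain
  40→38→19→17→15→8→6→4→2→1; flattened width 32; 79 873 parameters versus
  191 921 for the unfactorised variant that replaces each 3³ pair/triple
  by one 5³/7³ conv of equal receptive field — the parameter saving of
  factorising convolutions is much larger in 3D than in 2D.
* **inception_like**: 3³ stem + pool, then standard–standard–reduction
  twice, global average pooling, fcn(1).  Standard modules run four
  branches — 1³ conv, 1³→3³ (factorised 5³), 1³→3³→3³ (factorised 7³),
  and 3³-pool→1³ — concatenated channel-wise; reduction modules use
  stride-2 same-padded branches plus a pooled passthrough and halve each
  spatial dimension (ceil).  Branch widths are (8,8,8,8) before the first
  reduction and (16,16,16,16) after; the exact widths are declared in one
  place (`INCEPTION_WIDTH_STAGE1/2`) so alternates are one-line changes.

The layers themselves are a compact NumPy implementation with explicit
backpropagation: im2col convolutions (the window matrix is cached and
reused for the weight gradient; the input gradient is accumulated by
per-kernel-offset matmuls, avoiding large windowed copies), argmax-cached
max pooling with TF-style asymmetric same padding, and float32 arithmetic
throughout.  Analytic gradients are verified against central differences
in the test suite.  Single-threaded execution makes training bit-
deterministic for a fixed seed.

Numerical conventions fixed here: valid pooling/convolution floors the
output size, same-padded ceils it; binary cross-entropy is computed in
its logit (softplus) form; the sigmoid is applied on top of the final
linear unit at prediction time.

## Training and cross-validation (`petnodule.training`)

* **Splitting**: five class-stratified partitions by largest-remainder
  allocation — per class, floor(n/5) everywhere and the remainder
  one-per-partition to the currently smallest partitions, largest class
  first.  For 51/62 this yields partition sizes {23,23,23,22,22} with
  class counts within one of proportional.  Partition 5 is the held-out
  test set; partitions 1–4 drive 4-fold cross-validation (train on
  three, validate on one).
* **Optimisation**: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7 — framework
  defaults; only the learning rate is treated as tuned) on BCE + L2,
  shuffling every epoch.  "Full-batch" resolves to the actual training
  set size.  Early stopping: minimum validation loss with patience 10,
  100-epoch cap, best-epoch parameters restored.  With a constant
  validation loss this stops after exactly 1 + patience epochs.
* **No leakage**: test subjects are asserted out of every training,
  validation, normalisation and augmentation computation; fold models are
  always evaluated on the original (never augmented) validation
  partition.
* **Repetition**: `repeat_cv` re-runs the CV with derived per-iteration
  seeds and averages fold-mean AUCs.  Because training here is
  deterministic, repetition is kept for protocol parity rather than as a
  GPU-nondeterminism mitigation; when several versions per fold exist the
  first iteration's model enters the ensemble, and the choice is
  recorded.
* **Ensembling**: the four fold models' probabilities are averaged with
  weights proportional to each fold's training-partition size (e.g.
  {67,67,68,68}/270); each fold model normalises test inputs with its own
  fold statistics.

## ROC statistics (`petnodule.roc_stats`)

Everything uses the "score ≥ threshold → positive" convention, in curve
construction and final classification alike.  The empirical ROC places
cutpoints at the observed scores; its trapezoidal area equals the
Mann–Whitney pair-counting statistic (ties ½) exactly, which the tests
assert on 500 random instances.

* **DeLong**: placement-value (midrank) structural components give the
  AUC variance, normal CIs truncated to [0, 1] (perfect separation yields
  a flagged, truncated CI), and the paired z-test from the covariance of
  the two scorers' components.  Verified against R pROC on a frozen
  fixture (identical AUC, CI, z and p).
* **Venkatraman–Begg**: the statistic E sums, over all rank cutpoints,
  the absolute difference in classification-error counts between the two
  modalities; the null exchanges the two modalities within subject with
  probability ½, re-jittering ties (uniform jitter below half the minimal
  score gap, re-drawn per permutation, the continuous-data variant) and
  re-ranking on every permutation; p is the fraction of permuted E at or
  above the observed E.  E matches pROC's `roc.test(method="venkatraman")`
  on the same fixture, and the type-I error at α = 0.05 is calibrated to
  [0.02, 0.08] under the null (300 replicates × 200 permutations, n=60).
* **Dispatch**: the paired comparison uses DeLong when one curve
  uniformly dominates on the union FPR grid and Venkatraman–Begg when
  the curves cross (sign change beyond 1e-9).
* **Thresholds**: the Youden rule maximises J = sens + spec − 1 over
  observed scores, ties (within 1e-12, absorbing float noise between
  algebraically equal J values) broken toward the lower threshold —
  higher sensitivity, consistent with the asymmetric-cost stance that a
  missed malignancy outweighs a false alarm.  The constrained rule
  maximises specificity subject to sensitivity ≥ 95% on the selection
  data.  Per-fold thresholds are computed on each fold's validation
  partition and averaged (arithmetic mean of the four) before applying to
  ensemble test probabilities.

## Grad-CAM (`petnodule.explain`)

Classic Grad-CAM on the pre-sigmoid logit: channel weights are the
spatial average of ∂logit/∂feature-map, the map is the rectified weighted
channel sum, trilinearly upsampled to the input grid and max-normalised
to [0, 1] (zero maps pass through).  Two choices deserve note:

* **Source layer**: the deepest convolutional output with spatial extent
  above 1³.  For stacked3d the final conv map is 1³ — spatially uniform
  after upsampling, hence uninformative — so the penultimate conv layer
  (6³) is the default there.
* **Upsampling alignment**: a valid-convolution feature map does not span
  the full input extent (the 6³ stacked3d map covers input positions
  8.5 + 4i, i.e. 8.5–28.5 of 0–39).  Upsampling therefore composes each
  layer's kernel/stride/padding into an affine index map and places each
  feature voxel at its receptive-field centre, clamping the periphery;
  naive corner-aligned zooming misplaces peaks by several voxels.

Known limitation, measured on phantom models: because the channel
weights are *global* spatial averages of gradients with mixed signs,
classic Grad-CAM is not guaranteed to peak inside the nodule even when
the model's decision is driven by nodule uptake — on trained phantom
models the rectified map is frequently zero over the nodule and maximal
in the background rim.  This is the documented faithfulness failure of
global-weight CAMs on small feature maps.  The localisation test
therefore uses a hand-constructed intensity-detector network (one
positive averaging channel chained through the stack), for which the
heatmap provably must peak in the nodule — and does, within the nodule
sphere dilated by 2 voxels.  For trained models the galleries remain
descriptive, as in the original presentation (one heatmap per fold model
per row, ten 4-slice-averaged thick axial slices, grayscale PET fused
with a red-dominant overlay whose opacity applies only where the map is
non-zero, so a zero map shows pure PET).

## Experiment runner and problem sizes

`run_experiment` executes simulate → preprocess → split → (augment) →
cross-validate → ensemble → single test evaluation (AUC with DeLong CI,
both threshold rules, confusion metrics) → SUVmax comparison with
crossing dispatch → Grad-CAM galleries, writing a versioned,
seed-annotated `summary.json`; identical seeds reproduce identical
summaries.  All randomness derives from one global seed (cohort = seed,
split = seed+1, training = seed+2, permutation test = seed+3).

The default end-to-end evaluation trains the stacked3d family on a
113-phantom cohort with mini-batches of 16 at learning rate 0.001 and
L2 0.00098 for up to 25 epochs (patience 10) — a per-fold problem of
~68 training tensors.  At these sizes the 4-fold CV takes roughly five
minutes on one CPU, the ensemble reaches held-out AUC ≥ 0.9 with a clear
margin over a label-shuffled control, and the full acceptance script
(including the permutation-test calibration at 300 × 200 permutations)
completes in well under twenty minutes.  The 100-epoch regime of the
protocol is available by raising `max_epochs`.

## Known limitations

* Phantom realism is deliberately minimal (uptake contrast only); none
  of the results here transfer quantitatively to clinical PET data.
* The NumPy training core is single-threaded and CPU-bound; it is meant
  for cohort-scale experiments (10²–10³ tensors), not for large-scale
  training.
* Inception branch widths are plausible defaults, not a published
  configuration; they are declared in one place for easy substitution.
* Classic Grad-CAM's global channel weighting limits spatial faithfulness
  on these small feature maps (see above).
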