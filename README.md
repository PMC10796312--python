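# petnodule

3D convolutional neural networks for classifying solid pulmonary nodules
in 2-[18F]FDG PET volumes — as a complete, reproducible experiment on
synthetic phantom cohorts.

Indeterminate solid lung nodules (8–30 mm) are routinely characterised
with FDG-PET, conventionally by reading the nodule's maximum standardised
uptake value (SUVmax).  `petnodule` implements the full deep-learning
alternative end to end for researchers in medical image analysis: the
input is a 40×40×40 single-channel tensor X (a 60 mm cube of SUV values
at 1.5 mm isotropic spacing, centred on the nodule), the target Y is the
binary malignancy status, and a 3D CNN approximates the mapping
f: X → Y.  Because cohorts of this kind are private, the package includes
a seeded phantom simulator that reproduces the statistical structure of
such a study (113 subjects, 45.1% malignant, median nodule diameter
13 mm with IQR 5 mm, higher tracer uptake in malignant nodules with class
overlap, PET-like blur and noise), so every stage is testable without any
download.

What is inside:

* **`petnodule.phantom`** — seeded phantom PET cohorts (NRRD + CSV
  manifest) and the SUVmax biomarker.
* **`petnodule.preprocess`** — trilinear isotropic resampling, 60 mm
  nodule-centred cropping, fold-wise min–max normalisation.
* **`petnodule.augment`** — offline class-balanced 3D augmentation:
  ±10-voxel translations, ±45° single-axis centre rotations, Gaussian
  noise at σ ∈ {0.1, 0.3, 0.5}; a minority-class original yields 61
  copies, a majority one 47.
* **`petnodule.models` / `petnodule.nn`** — three architectures (a
  stacked conv/pool network, a VGG-like network with factorised 3³
  convolutions and overlapping pooling, an Inception-v2-like network)
  built on a compact NumPy layer library with explicit backpropagation,
  He initialisation, LeakyReLU(0.3) and L2 weight decay.
* **`petnodule.training`** — stratified 5-way splitting, Adam + early
  stopping (patience 10), 4-fold cross-validation, repeated CV, and a
  probability ensemble weighted by fold training-set size.
* **`petnodule.roc_stats`** — nonparametric ROC/AUC, DeLong confidence
  intervals and paired test, the Venkatraman–Begg permutation shape test
  with crossing-based dispatch, Youden and sensitivity-constrained
  (≥95%) decision thresholds, confusion metrics.
* **`petnodule.explain`** — 3D Grad-CAM with receptive-field-aligned
  upsampling, ten thick axial slices, PET/saliency fusion overlays.
* **`petnodule.pipeline` + the `petnodule` CLI** — the end-to-end runner
  with a re-runnable run-directory layout and a machine-readable summary.

The scientific background, all modelling conventions and the numerical
choices are documented in [`docs/methods.md`](docs/methods.md).

## A worked example

`examples/04_roc_comparison.py` compares two scoring rules over the same
60 subjects with the package's paired-ROC machinery:

```text
scorer A: AUC 0.8889 (95% CI 0.8001-0.9777)
scorer B: AUC 0.6089 (95% CI 0.4639-0.7539)
Youden threshold 0.732 (sens 0.87, spec 0.83)
95%-sensitivity threshold -0.620 (sens 0.97, spec 0.27)
  -> sens 96.7%, spec 26.7%, acc 61.7%
curves cross: False -> delong test, p = 0.0014
```

Scorer A separates the classes well (AUC 0.89, DeLong 95% CI excluding
0.5); the Youden threshold balances sensitivity and specificity, while
the 95%-sensitivity rule accepts many false positives to miss almost no
disease — the trade-off preferred when a missed malignancy costs more
than an extra work-up.  Because neither empirical ROC curve crosses the
other, the comparison dispatches to DeLong's paired area test, which
rejects equality (p = 0.0014).

The other example scripts walk through cohort simulation
(`01_phantom_cohort.py`), preprocessing and augmentation
(`02_preprocess_and_augment.py`), cross-validated training with
ensembling (`03_train_crossval.py`) and Grad-CAM explanation
(`05_gradcam.py`).  The full experiment runs from the shell:

```bash
petnodule run-all --outdir runs/exp1 --seed 11 --arch stacked3d --epochs 25
```

writing volumes, fold checkpoints, metrics, Grad-CAM galleries and
`summary.json` under `runs/exp1/`; the individual subcommands
(`simulate`, `preprocess`, `split`, `augment`, `train`, `evaluate`,
`compare-suvmax`, `explain`) re-run single stages of the same directory.

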