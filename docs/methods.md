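# Methods

## The classification problem

The package models a case-control neuroimaging study: distinguish patients
with left medial temporal lobe epilepsy from healthy controls using a single
2D coronal grey-matter density slice per subject. Grey-matter maps are
bounded in [0, 1] (tissue probability after segmentation), and the
discriminative signal is a left-lateralized intensity/volume reduction in
medial-temporal structures, strong enough to see by eye in roughly half the
patients ("lesional") and subtle in the rest ("non-lesional"), with a weaker
distributed extra-hippocampal component. The clinically meaningful question
the protocol answers is not "can a model match radiologists on obvious
atrophy" but "does the image carry diagnostic signal beyond what visual
inspection uses" — hence the emphasis on the non-lesional subgroup and on a
rigorous permutation null.

## Synthetic cohort generator

Real cohorts of this kind are not publicly distributable, so the generator
is a first-class module rather than a test fixture. It emulates:

* **anatomy** — a procedural template per study: elliptical cortical ribbon
  (density ≈ 0.68), central subcortical nuclei (≈ 0.55) and bilateral
  medial-temporal blobs rendered as the densest compact structure (≈ 0.85,
  consistent with how closely packed mesial temporal grey matter appears on
  smoothed probability maps), plus a seeded low-frequency texture (±0.03);
* **pathology** — multiplicative intensity reduction on the left
  medial-temporal ROI (defaults: 0.35 lesional, 0.12 non-lesional; chosen so
  the lesional effect is visually obvious at the default noise level while
  the non-lesional one is not), an optional erosion term for volume loss,
  and a 0.05 distributed neocortical/subcortical reduction in all patients;
* **nuisance** — per-subject integer translation of up to 2 px (residual
  misregistration / sulcal variability), additive Gaussian noise with
  SD 0.06, clipped to [0, 1], and per-site global intensity factors
  (1.00 / 0.98 / 1.02) across three sites with the study's site allocation;
* **composition** — 95 patients (48 lesional, of whom 29 seizure-free after
  surgery; 47 non-lesional, 28 seizure-free) versus 202 controls. One
  report of the control count as 203 exists; 202 is used and the count is
  configurable.

What it deliberately does **not** emulate: MRI physics (bias fields,
contrast, scanner-specific artefacts), true 3D anatomy (volumes are a 2D
slice modulated by a smooth symmetric anterior-posterior profile),
registration and segmentation error structure, and age/sex covariates.
Passing tests therefore demonstrate that the *pipeline machinery* behaves
correctly and that the protocol recovers planted effects; they say nothing
about classification accuracy on real MRI data.

## Preprocessing

Gaussian smoothing uses σ = FWHM / (2√(2 ln 2)) scaled by the voxel size,
with reflective boundaries (constants preserved, mass approximately
conserved; the discrete kernel is normalized, so an interior unit impulse
keeps total mass 1). Smoothing at 0 mm is the identity. Both smoothed and
unsmoothed maps flow through the pipeline. Smoothing acts on whichever
representation it is given (2D slice or 3D volume); the order relative to
slice extraction is the caller's choice. Coronal plane indices are 1-based
throughout, matching radiological convention ("plane 113 of 156").

## SMOTE for images

The displacement form implemented by default is
`X_s = X_m + (X_m − X̂) · R_d` with `R_d` uniform with mean 0 and SD 1,
realized as U(−√3, √3) — the unique uniform with those moments. Note this
*extrapolates away* from the neighbour for positive R_d, unlike classic
SMOTE, which interpolates toward it; the classic variant
(`X_m + (X̂ − X_m)·R_d`, R_d ~ U(0,1)) is available via `rd_mode` and both
are logged per sample. Outputs are clipped to [0, 1] because the inputs are
density maps. Neighbours are the k = 5 nearest minority samples by Euclidean
distance on flattened pixels, ties broken by ascending index. When more
synthetics are needed than there are minority samples, parents are cycled
round-robin (a random-parent mode exists); the round-robin default keeps
each minority sample equally represented. Balancing is restricted to
training data after the train/test split — validation folds and the test
set are never oversampled.

## Classifiers

Both networks use three convolution stages with stride equal to the kernel
size and no padding, so stage output size is floor((n − k)/k) + 1 and every
convolution is a partition of its input into non-overlapping patches. This
makes the engine exact linear algebra (reshape + matmul), cheap on one CPU,
and bit-reproducible. The DAG variant projects the first stage's channels
through a learnable 1×1 map to the third stage's channel count, resamples
them to the third stage's grid by nearest neighbour, and adds them to the
third stage's output before the classifier; zeroing the projection
reproduces the plain CNN path exactly.

Points the architecture family leaves open were fixed as standard defaults:
ReLU after each convolution, softmax + cross-entropy, SGD with momentum 0.9,
batch size 16, He initialization. `validation_frequency` means "validate
once every N epochs". The reported optimal parameter sets are available as
spec defaults (CNN: 40×20², 10×10², 15×20², lr 6e-4, 160 epochs; DAG:
10×30², 40×15², 20×15², lr 4e-4); under the stride-equals-kernel rule these
kernel chains only fit very large inputs, so the working configuration for
64-pixel synthetic slices is a scaled chain (8×4², 8×2², 8×2², lr 0.05,
15 epochs) — the package's own reduced problem size. The ambiguity between
a 20×20 and a 15×15 third-layer kernel in the source material is resolved
in favour of the parameter list (20×20); any chain is configurable.

## Evaluation protocol

* Stratified 80/20 split with per-class test counts floor(n_class × 0.2)
  (95/202 → 19 + 40).
* 10-fold stratified grid search on the training+validation portion; SMOTE
  is applied inside each fold's nine training folds only. The (combination,
  fold) pair with maximal validation accuracy wins; ties resolve to the
  first in the fixed enumeration order; unbuildable combinations are
  skipped and logged.
* Step 4 is read as *retraining* on the full, balanced training+validation
  set with the optimal parameters (reusing the winning fold model is a
  switch).
* Metrics: ACC, SEN, SPC, PPV, NPV from the 2×2 confusion matrix (TLE
  positive); AUC by rank concordance of predicted TLE probabilities with
  ties counted ½ (scikit-learn's estimator; an independent all-pairs oracle
  backs it in the tests). Ratios with zero denominators are reported as
  explicit undefined markers, excluded from distribution means with a
  count — never silent zeros.
* Subgroup metrics restrict the test split to all controls plus one patient
  subgroup (lesional, non-lesional, seizure-free, non-seizure-free).
* The permutation null re-draws the split each repeat (the correct and null
  pipelines are independent), permutes training+validation labels, runs the
  10-fold CV at fixed parameters, selects the best random fold model and
  evaluates it *directly* on the test split (no retraining — the null
  mirrors "select the highest performing random model").
* p-values are plain proportions of null values ≥ the correct mean, no
  continuity correction.
* Per-repeat generators are `default_rng([seed, stream, repeat])`
  (stream 0 correct, 1 null, 2 visualization), making any repeat resumable
  in isolation.

Test-set leakage is guarded twice: by construction (splits are disjoint
subsets; SMOTE only sees training folds) and by an audit log of subject IDs
(test vs trained-on vs SMOTE parents) asserted in the tests.

## Visualization

Activation maps are the pre-ReLU convolution outputs, so responses can be
negative; the absolute value is applied first, then per image and layer the
map with the largest total is selected, normalized by its maximum
(an all-zero map is flagged, not divided), summed across test images and
repeats, and renormalized. Coarse maps are upsampled by nearest-neighbour
block expansion aligned to the stride grid, and peaks are reported at block
centers (a coarse cell is evidence about its whole receptive block, not its
top-left pixel).

On a bilaterally symmetric anatomy the max-total selection is left-right
symmetric, so localization is assessed against the medial-temporal ROI of
either hemisphere (2-px dilated): with a strong planted effect the
aggregated layer-3 peak falls inside it in ≥ 80% of seeded runs when maps
are aggregated across a few repeats, which is how the procedure is defined
(aggregation across test images *and* repeats). Single-model maps are
noticeably noisier — filter initialization can dominate a lone model's
selected map.

## Problem sizes and numerical choices

The default test and calibration scale is 64×64 slices, cohorts of 20-40
patients vs 30-80 controls, 15-epoch training and 5-10-fold CV; the null
calibration uses 50-60 repeats. These are the package's chosen desk-scale
conditions; the protocol itself supports the full 1000-repeat, 10-fold
configuration unchanged. Clipping to [0, 1] after noise, SMOTE and
smoothing keeps everything in the density domain. All tolerances asserted
in tests are stated there (e.g. null AUC within ±0.05 of 0.5; Monte-Carlo
ROI reduction within ±0.03 of nominal).

## Known limitations

* The generator's effects are multiplicative intensity changes on fixed
  masks; real atrophy deforms anatomy.
* Stride-equals-kernel convolutions cannot express the overlapping-window
  variant of the architecture, so the published full-size kernel chains are
  only buildable on proportionally large images.
* The permutation null at small repeat counts has visibly discrete p-values
  (1/repeats resolution).
* Site effects are global intensity factors only; no site-specific noise
  spectra or harmonization.
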