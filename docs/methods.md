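# Methods

This note records the model, the conventions, and the design decisions
behind `ennseg`, in the order the pipeline uses them.

## Task framing

Tumor segmentation is treated as independent binary 2D segmentation of
axial slices; 3D volumes are only containers. Training and evaluation use
exactly the slices whose reference mask contains at least one tumor voxel
(inference on all slices is supported, tumor-bearing is the default so
training and testing statistics are computed over the same population).
Slice indices are 0-based, the axial plane is addressed (row, col) =
(y, x), and NIfTI affines are consulted for voxel spacing only — the
per-slice task is orientation-agnostic, which is a documented limitation,
not an oversight.

Raw stored intensities (16-bit range) are preserved through I/O; the only
intensity preprocessing is per-slice standardization to zero mean / unit
variance, applied inside the model pipeline at both training and inference.

## Data splits

Patients — not slices or phase volumes — are the unit of splitting, so both
contrast-phase volumes of a patient always land in the same set. Set sizes
follow largest-remainder rounding of the (0.8, 0.1, 0.1) fractions (639
patients give 511/64/64). The split is a seeded permutation of the sorted
patient ids, hence deterministic and invariant to input order. With very
few patients the validation set can legitimately be empty; member selection
then falls back to the training loss.

## Ensemble

* Members are identical networks trained independently; member k derives
  its RNG stream from (base_seed, k) via `numpy` SeedSequence, which
  guarantees reproducibility and inter-member diversity simultaneously.
* Hyperparameter defaults: M = 10, 20 epochs, batch 64, SGD with learning
  rate 0.1 and momentum 0.9, soft Dice loss with smooth = 1. Desk-scale
  runs use smaller M (2–3); nothing in the method depends on M beyond
  fusion averaging.
* The soft Dice loss uses the squared-denominator form
  1 − (2Σpt + s)/(Σp² + Σt² + s), computed per sample and averaged over
  the batch; on binary predictions it coincides with 1 − Dice. The
  analytic gradient is unit-tested against finite differences.
* Augmentations (composition is configurable and recorded in the run
  config): horizontal/vertical flip with p = 0.5 each, rotation uniform in
  ±15°, multiplicative intensity jitter in [0.9, 1.1]. Geometric
  transforms are applied identically to image and mask (nearest-neighbour
  for the mask, so it stays binary); intensity jitter touches the image
  only, and is applied after standardization so it is not cancelled by it.
* Model selection keeps the weights of the epoch with the best validation
  soft Dice; the full per-epoch loss log is persisted with the checkpoint.
* Fusion is the equal-weight elementwise mean of the member sigmoid maps.
  The binary mask is fused probability ≥ 0.5; the tie at exactly 0.5
  rounds to foreground. Fusing M copies of one member reproduces that
  member exactly.

### Backbone

The member architecture is pluggable; the method (independent seeding,
sigmoid-average fusion, entropy confidence) does not depend on it. The
default `tiny_unet` backbone is a three-layer fully-convolutional network
(3×3 conv → ReLU → 3×3 conv → ReLU → 1×1 conv to a logit) whose final
layer also receives the standardized input directly. That input skip makes
an almost-threshold-separable foreground learnable within the few dozen
SGD updates that 20 epochs over a few hundred slices provide, while the
convolutional stages contribute local-context smoothing. Forward and
backward passes are implemented in numpy (im2col + einsum), so training is
bit-reproducible from the seed and runs in seconds per epoch at 64×64 on
one CPU. A large pretrained encoder–decoder would raise accuracy on real
CT but is out of scope for a CPU-scale reference implementation.

## Confidence score

The "average foreground entropy" score is implemented as: binary Shannon
entropy in **bits** of the fused probability at each
voxel, averaged over the voxels of the *predicted* foreground. Bits (log₂)
are the right unit because the score then lives on [0, 1] with maximum at
p̄ = 0.5. An empty predicted foreground has no voxels to average; it is
assigned entropy 1.0 and flagged — inside this tool every evaluated slice
contains reference tumor, so an empty prediction is a maximal failure and
must sort with the low-confidence cases. A documented alternative computes
the entropy from the per-voxel fraction of members voting foreground
instead of the fused probability (`assess(..., member_vote_entropy=True)`).

Success is Dice strictly greater than 0.8. Calibration builds the
empirical ROC of entropy against success with low-score-positive polarity:
candidate cutoffs are the observed entropy values plus a sentinel above
the maximum, and the positive call at cutoff θ is entropy < θ — the same
strict inequality later applied to new data, so the calibration operating
point is exactly reproducible at assessment time. A prediction with
entropy equal to the cutoff is flagged for review (ties go to the safe
side). AUC is the Mann–Whitney pairwise concordance with ties counted ½
(identical to the trapezoid area); the Youden cutoff maximizes
sensitivity + specificity − 1, with ties broken toward higher sensitivity,
then the lower cutoff. Both are verified exactly against brute-force
oracles and scikit-learn on randomized instances.

Granularity: confidence classification operates per slice by default;
per-patient reporting uses the voxel-pooled Dice over all of a patient's
tumor slices (large slices weigh more than small ones — deliberately
different from averaging per-slice Dice) and the mean slice entropy.

Dice conventions: both masks empty → 1 (needed for totality, never
triggered on tumor-bearing slices); exactly one empty → 0.

## Phantom generator

The generator emulates just enough structure for every pipeline stage to
be testable: a bright body ellipse on a darker surround, smoothed-noise
texture (sd 150 around a soft-tissue mean of 2000 on a 12-bit subrange of
the 16-bit scale), 1–3 ellipsoidal organ distractors with contrast from
−450 to +400 (the bright tail approaches tumor contrast, so some cases
contain a genuinely confusable structure — the "wrong bright organ"
failure mode), and one tumor per patient: a wobble-perturbed ellipse
spanning a contiguous slice run with spherical-cap area profile. An
in-plane Gaussian point-spread blur (σ = 0.8 px) softens edges so boundary
voxels are genuinely ambiguous, and white noise (sd 80) is added per
phase. Default tumor contrast is +700 over the background.

These defaults were chosen so that a trained desk-scale ensemble produces
a realistic *mixture* of successful and inadequate slice segmentations —
without such a mixture the confidence analysis would be vacuous. Phase 2
(pseudo-nephrogenic) applies a monotone affine intensity remap and an
independent noise draw to the same geometry, which is exactly the
situation that makes patient-grouped splitting necessary. Slices per
patient are uniform in [5, 20].

What the phantoms do **not** model: anatomy, Hounsfield calibration,
scanner spectra, 3D tumor shape statistics, cystic or infiltrative
lesions. Passing phantom tests demonstrates that the pipeline's mechanics
and statistics are correct, not that the bundled backbone reaches clinical
accuracy on real CT.

Two training-free oracles provide graded prediction quality:
`degrade_mask` (erode / dilate / shift / drop / wrong_region, with
expected Dice monotone in severity and wrong_region giving Dice 0) and
`simulate_soft_prediction`, which shifts the reference (localization
error) and applies boundary blur so that falling quality simultaneously
raises foreground entropy and lowers thresholded Dice.

## Numerical conventions

* Entropy uses 0·log 0 := 0; probabilities are validated to [0, 1].
* Probability maps round-trip through float32 NIfTI (max error < 1e-6).
* Fusion averages in float64; permutation invariance holds to 1e-14
  (floating-point summation order).
* Summary statistics are median and IQR (25th–75th percentile, linear
  interpolation).
* All randomness flows from explicit integer seeds; the CLI fans a single
  global seed out to the phantom, split and ensemble seeds via fixed
  offsets. Gzip NIfTI output carries no timestamps, so reruns are
  byte-identical.

## Problem sizes

Desk-scale defaults: 64×64 slices, 30-patient two-phase cohorts
(~480 training slices), 3-member ensembles, 20 epochs — the full pipeline
runs in a few minutes on one CPU, and the same code path scales to
512×512 clinical volumes and M = 10 unchanged. The KiTS-layout reader
ingests real cohorts directly (`case_XXXXX/imaging.nii.gz` +
`segmentation.nii.gz`, tumor = label 2, kidney label dropped, unknown
labels rejected by name; the label mapping is overridable).

## Known limitations

* No DICOM ingestion, resampling or registration; orientation metadata
  beyond spacing is ignored.
* The bundled backbone is intentionally small; clinical-grade accuracy
  requires swapping in a GPU-scale architecture behind the same interface.
* Confidence calibration is a single scalar cutoff; voxelwise uncertainty
  calibration (e.g., temperature scaling) and conformal methods are out of
  scope.
* The entropy score cannot detect confident-but-wrong segmentations (low
  entropy, low Dice) — e.g., a cleanly segmented wrong structure; this
  failure mode is visible in per-patient scatter reporting.
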