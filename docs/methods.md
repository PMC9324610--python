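# Methods

## Problem setting and model

Human activity recognition from body-worn inertial sensors suffers from
inter-subject heterogeneity: sensor placement, limb geometry, movement vigor
and cadence all vary across people, so a classifier trained on one
population can be unreliable on a new individual. `perhar` implements
*personalized* inference: a shared embedding function `f(x)` is trained
across subjects, but classification of a subject's test windows happens by
nearest-neighbor search against that subject's own labeled reference
embeddings. The embedding only has to separate activity classes *within*
each subject's transformed signal space — a strictly weaker requirement than
aligning all subjects into one decision geometry.

### Embedding core

Three 1D convolution blocks (conv → batch norm → ReLU → dropout, unit
strides, 'same' padding), global average pooling over time, an optional
dense projection when the embedding width differs from the last filter
count, and row-wise L2 normalization. Global average pooling makes the
representation tolerant to temporal shifts of quasi-periodic motion within a
window; L2 normalization confines embeddings to the unit hypersphere, which
stabilizes triplet training (distances are bounded by 2) and makes the
margin interpretable. The default kernel sizes (7, 5, 3) fix the receptive
field of last-layer units at 1 + Σ(kᵢ − 1) = 13 samples, i.e. 260 ms at the
50 Hz working rate — roughly one quarter of a movement cycle at typical
exercise cadence. Filter defaults are (128, 256, 128); the test suite and
desk-scale examples use a reduced core (32, 64, 32) with a 32-dimensional
embedding, which is ample for the synthetic benchmark's five classes.

The network, backpropagation, Adam, and global gradient-norm clipping are
written directly in numpy. The backward pass is validated against central
finite differences in `tests/test_nn_gradients.py`. All randomness
(initialization, shuffling, dropout masks, triplet draws) derives from
explicit seeds; training is bit-reproducible.

### Training objectives

* **Cross-entropy** (impersonal FCN / PDF embeddings): Adam, learning rate
  0.001, batch size 64, gradient norm clipped at 1.0, 150 epochs by default.
* **Triplet loss** (PTN): hinge on squared Euclidean distances with margin
  α = 0.3, same optimizer and clipping, learning rate reduced to 0.0002.
  An epoch draws N triplets (N = number of training segments), resampled
  fresh every epoch to cover more of the triplet universe. Anchors and
  positives must not overlap temporally in their source recording. In
  *subject* mode all three members come from one subject; *mixed* mode
  (default) draws half subject triplets, half unconstrained ones. Samplers
  use rejection sampling from the uniform distribution over valid triplets,
  with an exact feasibility pre-check so impossible configurations fail
  loudly. No online hard-negative mining is performed: subject-constrained
  selection is the mechanism under study, not an addition to mining
  heuristics.

### Personalized inference

Per test subject, each activity's time series is split along the temporal
axis (first `reference_fraction` = 0.5 to the reference side) *before*
sliding-window segmentation, so reference and test windows can never share a
source sample; every experiment run audits this pairwise. Classification is
k-NN with k = 3, Euclidean metric, uniform votes. Vote ties (possible only
as 1-1-1 splits) are broken by the smallest summed neighbor distance, then
the lowest class identifier — both deterministic. Nearest-centroid
classification is provided as the O(#classes) alternative. OOD scoring uses
the mean distance to the 3 nearest in-distribution reference embeddings
(monotone in unfamiliarity, threshold-free; consumers compute AUROC); a
local-outlier-factor scorer is available behind a switch for comparison.

### Engineered-feature baseline (PEF)

Eleven per-channel statistics (mean, median, absolute energy, standard
deviation, variance, min, max, skewness, kurtosis, mean spectral energy,
mean crossings) — 66 features for a 6-channel IMU. Conventions chosen where
the quantities are ambiguous: biased moment estimators; excess kurtosis;
skewness/kurtosis defined as 0 on zero-variance windows; mean spectral
energy is the mean one-sided periodogram power excluding the DC bin (the DC
bin duplicates the mean feature); mean crossings counts strict sign changes
of the mean-subtracted signal, skipping samples exactly at the mean.
"Scaling to unit norm and zero mean" is implemented as per-feature
standardization on the training set (zero mean, unit standard deviation;
constant features are clamped to scale 1 and map to zero) — the conventional
reading for feature columns — and the fitted transform is reused verbatim on
test data.

## Preprocessing

Recordings are resampled to a common rate (50 Hz) by per-channel cubic
splines on the original time grid; labels map to the nearest original
sample (inconsequential except at activity boundaries, which are rare
relative to run lengths). Sliding windows of `W = round(window_seconds ×
rate)` samples advance by `step = max(1, round(W·(1 − overlap)))` within
each maximal run of constant label; windows spanning a label change — or a
sample-index discontinuity introduced by temporal splitting — are discarded.
The default window is 4 s with overlap 0.8 (step 40 samples at 50 Hz), the
overlap doubling as data augmentation. All intervals are 0-based half-open;
window-level per-channel z-scoring is available but off by default.

## Evaluation protocols

* **Subject-grouped k-fold CV** (default 5 folds): seeded shuffle, folds
  balanced to ±1 subject; the identical plan object is consumed by every
  model kind in a comparison and its hash is recorded in each result.
  Accuracy statistics aggregate over *subjects*, not folds (mean and
  sample standard deviation, ddof = 1). A reporting flag marks two results
  as separated when their means differ by more than two standard deviations.
* **OOD experiment**: models train on a seeded 70% subset of classes
  (fold-indexed seed, shared across model kinds); test subjects are scored
  on all classes and per-subject AUROC of in- vs out-of-distribution is
  aggregated. The FCN baseline scores 1 − max softmax.
* **Generalization experiment**: the embedder trains with 30% of classes
  withheld; reference stores enroll *all* classes, and accuracy is measured
  over the full class set (withheld-class accuracy reported separately).
  The impersonal FCN is excluded — its softmax width is fixed at training.
* **Embedding-size sweep**: deep kinds vary the dense projection width; PEF
  keeps the top-n features by Gini importance from a seeded 250-tree
  extremely-randomized-trees classifier.
* **Reference-size sweep**: the embedder trains once per fold; each budget n
  keeps the first n reference segments in *enrollment order* — segments
  sorted by (temporal rank within class, class id), i.e. the earliest
  example of every class in turn — and reuses the identical test set.
  This round-robin convention mimics a short enrollment session and means a
  budget below the class count drops whole classes (the regime where
  accuracy collapses), rather than exhausting the budget on one activity.

## Synthetic data generator

The generator emulates the heterogeneity regime the method targets, with
analytic ground truth. Each class template is a sum of 2–4 sinusoidal
motifs; motif frequencies are drawn from a small pool (0.5–5 Hz) *shared
across classes*, so classes are distinguished mainly by how energy and phase
are distributed across channels rather than by frequency alone. This is the
deliberate design: per-subject random rotations of the channel space
(applied within consecutive sensor triads, emulating IMU re-orientation)
then scramble exactly the cue an impersonal classifier must rely on, while
leaving within-subject class structure intact. Per-subject distortions —
log-normal amplitude scale, log-normal frequency (cadence) multiplier, triad
rotations, per-channel offsets — are drawn once per subject and applied to
all of that subject's classes, plus white observation noise. One seed fixes
the dataset bit-exactly.

Defaults: 8 subjects, 5 classes, 6 channels, 50 Hz, 120 s per
(subject, class) — enough that the 50/50 temporal split at 4 s windows with
overlap 0.8 leaves ≥ 24 reference segments per class, the upper end of the
reference-budget sweep. The two packaged benchmark levels are `easy` (zero
heterogeneity, noise SD 0.2 — any competent classifier saturates) and
`heterogeneous` (rotation SD 1.2 rad, scale SD 0.4, offset SD 0.5,
frequency jitter 0.05, noise SD 0.3 — impersonal accuracy collapses on
unseen subjects while personalized inference is unaffected). Heterogeneity
SDs were chosen to put the impersonal classifier clearly but not floor-level
below the personalized ones; they are configuration, not fitted values.

What the generator does **not** emulate: non-stationary motion, gravity and
orientation drift, sensor saturation and dropout, label noise, transitions
between activities within one recording, and repeated sessions separated by
re-donning the sensor. Consequently, passing tests demonstrate the
machinery and the heterogeneity mechanism, not field performance on real
wearable data; on real data the reference/test split from a single session
likely overstates accuracy for all personalized methods equally.

## Desk-scale test conditions

The test suite exercises the full pipeline with the reduced core
(32/64/32 filters, 32-dim embedding, 20 epochs, 128 triplets per epoch) on
fixtures of 5–6 subjects, 3–5 classes, and 16–30 s per (subject, class) —
sizes chosen so the complete suite runs in minutes on one CPU while leaving
the directional phenomena (personalization advantage, impersonal spread,
OOD separation, unseen-class generalization, reference-budget collapse)
comfortably reproducible. Five seeded replicates back each directional
comparison.

## Numerical and design choices

* Kernel sizes (7, 5, 3) rather than the classic (8, 5, 3): the receptive
  field is pinned at 13 samples, which forces Σkᵢ = 15 under unit strides;
  (7, 5, 3) is the minimal change to the cited architecture and keeps the
  'same' padding symmetric (odd kernels).
* Layer order conv → BN → ReLU → dropout, the standard order for this
  architecture family.
* Dropout rate defaults to 0.2; batch size to 64 (both configurable).
* The dense projection to the embedding width exists only when d ≠ f₃,
  placed after pooling and before L2 normalization.
* Batch triplet loss is the *sum* over triplets; with Adam and norm
  clipping the scale choice does not affect the optimization direction.
* Degenerate inputs fail loudly: recordings shorter than 4 samples cannot
  be cubically resampled; overlap ≥ 1, single-class training sets,
  stores smaller than k, and infeasible triplet configurations all raise.
* Model checkpoints are single `.npz` archives (weights, batch-norm running
  statistics, config, class order, format version); reloading reproduces
  predictions bit-identically.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for training on full public HAR datasets.
* Real-dataset adapters (MHEALTH/WISDM/SPAR layouts) are format
  translations only and are tested against synthetic stand-ins of those
  layouts, not the actual downloads.
* The WISDM adapter surfaces a duplicate-timestamp report but deliberately
  does not exclude subjects; published exclusion rules for corrupted
  readings are not fully specified, so the decision is left to the caller.
* OOD scores are unitless distances; no calibration to probabilities is
  attempted, and thresholding is the caller's responsibility.
* With 11 features per channel the engineered baseline is 66-dimensional
  for 6-channel data; other channel counts scale as 11 × C uniformly.
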