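# Methods

`endotex` classifies confocal laser endomicroscopy (CLE) frames of the
mouse colon wall into three health states — healthy, inflammation, cancer
(dysplasia) — and provides the training/evaluation machinery that the
clinical use cases require.  This note documents the models, the synthetic
data the package is validated on, the numerical choices, and what the
tests do and do not show.

## The classification problem

CLE produces video-rate grayscale micro-texture images (here 290 rows x
292 columns, 8-bit) of the mucosa.  Healthy mucosa shows a quasi-regular
field of vesicular crypts: dark round lumens with bright fluorescent rims,
one crypt spanning roughly an 8x8-pixel patch.  Inflammation enlarges and
distorts the lumens and raises background fluorescence; dysplastic tissue
shows disordered, elongated and fused structures.  Because the probe moves
slowly at video rate, consecutive frames are near-duplicates, and a
fraction of frames are non-informative (sensor saturation, signal loss,
occlusions).

Two evaluation regimes correspond to two clinical questions:

* **cross-subject** — train and test cohorts share no subjects; measures
  whether a pre-trained model generalizes to unseen individuals.
* **cross-sample** — frames are split at random within the cohort (never
  the same frame on both sides, but subjects may span the split); measures
  semi-automatic annotation of a known cohort, optionally with stratified
  7-fold cross-validation.

Cross-subject prediction is the harder problem; the package's evaluation
harness keeps the two regimes explicit and guards against split leakage
(`SplitLeakageError`).

## Informative-frame QC

Non-informative frames are removed by a one-statistic test: the population
Fisher-Pearson skewness g1 = m3 / m2^(3/2) of the frame's gray-level
distribution, computed over raw pixel values (identical to count-weighted
histogram moments, without binning choices).  Frames are kept iff g1 is
defined and strictly greater than a threshold, default -5.  Saturated
frames (nearly all mass at 255 with a thin dark tail) have g1 well below
-5 and are discarded.

Two deliberate conventions:

* **Zero-variance frames** have undefined g1 and are discarded with reason
  `zero_variance`: a constant frame carries no diagnostic texture.
* **Underexposed frames** have strongly *positive* skewness and therefore
  pass the literal keep-rule, although they are equally non-informative.
  The rule is implemented exactly as stated (keep iff g1 > -5); the
  asymmetry is a property of the published rule, not of this
  implementation.  Callers who need to remove dark frames can use a
  symmetric band (e.g. |g1| < 5) via the `threshold` parameter and a
  second pass, but no such band is applied by default.

## LBP + linear SVM

The handcrafted-feature route uses the original 8-neighbor local binary
pattern: each interior pixel is encoded by thresholding its eight 3x3
neighbors against the center value (ties count as 1) and packing the bits
with weights 2^n.  The neighbor order is frozen as clockwise from the
top-left neighbor, n = 0..7; any fixed order carries the same information,
but one must be pinned for codes to be reproducible.  The code map is
computed globally (so patch-boundary pixels see their true neighbors) with
border pixels skipped — padding would fabricate comparisons.

The feature vector concatenates per-patch 256-bin histograms of the code
map, tiled into non-overlapping N x N patches (default N = 8, about one
healthy crypt), remainder rows/columns dropped, patches in row-major
order.  A 290x292 frame yields a 288x290 code map, 36x36 patches, and a
331,776-dimensional vector.  Histograms are raw counts: interior patch
counts are constant (N^2), so any normalization is a scalar rescale that
the SVM absorbs.

Classification uses a one-vs-rest linear SVM (hinge loss, C = 1).  The
dual coordinate-descent solver is seeded and run with stopping tolerance
1e-2; on the synthetic benchmark the solution is identical to tol 1e-3
while fitting several-fold faster, and the solver's iteration count — not
the tolerance — is what varies with problem size.

## The scratch CNN

The representation-learning route is a deliberately small convolutional
network: five 3x3 convolution layers with 64, 128, 256, 512, 512 filters,
each followed by ReLU and 2x2 max pooling; a 1024-unit fully connected
layer with ReLU and dropout p = 0.5; and a 3-class softmax output.
Training minimizes mean cross-entropy with Adam at learning rate 0.001
(batch size 32 by default), keeps the best-validation-loss weights, and
early-stops on validation loss (patience 10 by default; an optional
validation-accuracy target allows earlier exit on easy problems).

The network, backpropagation and Adam are implemented directly on numpy
(im2col convolutions over BLAS matmuls, float32).  All randomness —
initialization, shuffling, dropout — flows through one seeded generator,
so training runs are bit-reproducible; this is also what makes the
freezing and determinism contracts exactly testable.

Input geometry: frames are resized (anti-aliased) to a square input that
must be divisible by 2^5 so five pooling stages divide evenly.  The
default is 288 (the nearest multiple of 32 to the native frame size,
within 1.4% of the native aspect ratio).  The test-suite and the
reproduction script run at 32x32: on one CPU this trains in minutes rather
than hours, and the synthetic classes remain separable at that scale.
Grayscale inputs are replicated to three channels only for
ImageNet-shaped backbones.

## Transfer scaffold

`build_transfer_model` provides the classical freeze-and-fine-tune
protocol on a VGG16-style stack (13 conv layers in blocks of 2/2/3/3/3
with pooling between blocks): the 1000-way head is replaced by a fresh
3-class head, the first `n_frozen_conv_layers` conv layers (default 3)
are excluded from gradient updates, and optionally a linear SVM is fitted
on the penultimate feature layer (extracted in eval mode, so
featurization is deterministic) in place of the softmax head.  Freezing
counts *conv layers*, not blocks, so the full sweep 0..13 is expressible.
Pretrained weights are an optional user-supplied `.npz`; none are bundled
or downloaded, and the scaffold is validated structurally (freezing
contract, head shape, trainable-parameter accounting) under random
initialization.  Only the VGG16 layout is provided; residual and
densely-connected backbones are out of scope for this package.

## Sample selection

To exploit temporal redundancy, each candidate training frame is reduced
to four first-order statistics of its raw pixels — standard deviation,
mean, variance, skewness.  Variance is kept alongside std deliberately,
matching the feature list as defined; the redundancy doubles that
direction's weight in the metric, which is benign.  Features are z-scored
per dimension (otherwise variance, scale ~1e3, would swamp skewness,
scale ~1), clustered per class with seeded k-means (scikit-learn, 10
restarts), and one uniformly random member of each cluster is selected.
Constant frames (undefined skewness) are excluded from clustering.  Test
data is never clustered or selected.

## The synthetic data generator

No public frame corpus exists for this protocol, so the package ships a
procedural simulator that reproduces the *statistical* structure the
methods depend on, not the optics:

* **Class texture**: a lattice of anisotropic Gaussian lumens (dark
  center, bright rim) on a uniform background.  Healthy: spacing ~12 px,
  small round lumens, background ~125.  Inflammation: spacing ~15 px,
  enlarged irregular lumens, background raised to ~152.  Cancer: heavy
  positional disorder and 2.5-4x elongation at ~13 px spacing, background
  ~112.
* **Subject effects**: per-subject brightness offset (+-18), lattice
  spacing multiplier (0.85-1.20) and lattice rotation (0-180 deg), drawn
  once per subject.  These make cross-subject generalization strictly
  harder than cross-sample, mirroring the qualitative gap between the two
  regimes on real data.
* **Temporal redundancy**: frames come in groups of 5 sharing one base
  scene, differing by a translation of at most 2 px and fresh additive
  Gaussian noise (sd 8).
* **Artifacts**: ~5% of frames are saturated (>=95% of pixels >=250, a
  few dark blobs) or underexposed (the mirror), with ground truth stored
  in the manifest so QC operating characteristics are computable without
  human labels.

Default campaign size is 9 subjects per class x 75 frames (~2,000
informative frames) — large enough for stable accuracy estimates, small
enough that the full pipeline (generation, QC, featurization, both SVM
fits and CNN training) runs on one CPU in minutes.  Frame size defaults
to 290 rows x 292 columns; the row/column assignment is a convention of
this package.

Everything is driven by `numpy` seed sequences: identical config + seed
gives bit-identical frames, manifests and PNG files.

What the simulator does **not** model: fluorescein pharmacokinetics,
probe optics and vignetting, respiratory motion, occlusions by mucus or
residues, intra-subject disease heterogeneity (each synthetic subject has
one class), and realistic inter-class texture overlap.  Passing the
synthetic benchmarks therefore demonstrates that the implementations are
correct and that the pipeline's orderings hold under controlled
conditions (cluster selection >= random selection at small budgets;
cross-subject <= cross-sample accuracy); it does not certify accuracy
levels on real endomicroscopy data.

## Evaluation conventions

* Confusion matrices are oriented **rows = predicted, columns = true**;
  note many toolkits default to the transpose.
* Accuracy is reported in percent, trace/total x 100.
* Subject-level labels are the majority vote over the subject's frame
  predictions; exact ties break by clinical severity (cancer >
  inflammation > healthy) — a conservative, documented convention.
* Repeated runs re-seed every seed-dependent stage (splits, training) and
  report mean +- sample standard deviation (ddof = 1), 10 runs by default.
* Stratified splits use per-class floor rounding for the test side with
  the remainder to train, so split sizes are bit-reproducible.
* For cross-sample deep-learning runs the validation set is carved from
  the training split (1/6 of it by default), never from test.

## Degenerate inputs and tie-breaks

* Frames smaller than 3x3 (LBP) or with fewer than 2 pixels (skewness)
  raise; code maps smaller than one patch raise.
* k-means selection with k equal to the usable frame count returns every
  frame (no clustering run); k outside [1, usable] raises.
* Max-pool ties take the first maximum (argmax convention); LBP ties take
  bit 1 by the s(x >= 0) convention.
* lr = 0 is allowed and performs no updates (useful as a control).

## Known limitations

* The numpy CNN is CPU-bound and desk-scale; it is not intended for
  training at native 288x288 resolution on large corpora.
* Only the VGG16-layout transfer backbone is implemented, randomly
  initialized unless the user supplies weights.
* The skewness rule passes underexposed frames (see above) — inherent to
  the rule itself.
* Synthetic separability is by construction; accuracy numbers on the
  simulator say nothing quantitative about real tissue.
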