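# Methods

## Problem and model

Each subject is a *bag* of 20 two-dimensional 20×20 slices cut from a
20×20×20-voxel VOI in the left middle frontal gyrus, with a binary group
label (0 = math, 1 = non-math).  The workflow has three stages.

**Stage 1 — representation learning.**  An encoder *F* (ResNet-style
bottleneck trunk, batch norm after every convolution, ReLU) and a projection
MLP *G* are trained self-supervised.  Each training step samples a minibatch
of slices, draws two augmented views per slice from one augmentation family
(random resized crop with area fraction 0.6–1.0, horizontal flip p = 0.5,
multiplicative intensity jitter SD 0.1, optional blur; vertical flips are off
because anatomical up/down is meaningful), and minimizes

    L = L0 + rho * L1

over the 2N projections.  L0 is the NT-Xent loss with cosine similarity and
temperature tau (default 0.5, the SimCLR reference value), averaged over all
2N anchors, each anchor's denominator running over the other 2N−1
embeddings.  L1 is the subspace penalty on each positive pair, averaged over
the N pairs so that rho's meaning is independent of batch size.

The penalty's default form is the *maximal absolute coordinate* of z_i −
z_j (the Chebyshev/ℓ∞ distance): minimizing the largest coordinate gap
forces the two views' projections to concentrate on the same coordinates,
i.e. into a shared subspace.  A conventional sum-of-absolute-values ℓ1 mode
is available (`subspace_norm: sum`); the two coincide in direction but not
in magnitude.  The ℓ∞ subgradient routes through the first coordinate
attaining the maximum — a fixed tie-break that keeps training
bit-reproducible.

**Stage 2 — slice classification.**  Projections are frozen; twenty sigmoid
MLPs H_1..H_20 are trained by full-batch Adam on mean squared error, each on
its own slice ID's instances only, labels inherited from the student.  The
hard slice label is 1 iff H(z) ≥ 0.5 (ties to 1).

**Stage 3 — voting.**  A student is labeled 1 iff strictly more than half
of the 20 slice labels are 1 (> 10).  The vote fraction (sum/20) is the
student's ROC score: it is the only monotone scalar consistent with that
rule, exceeding 0.5 exactly when the vote fires.  For a true class-1 student
it equals the fraction of correctly classified slices; for a true class-0
student, one minus it.

## Architectures

* Paper scale: stem 3×3 conv 1→64 (stride 1); bottleneck stages of 3/4/6/3
  blocks reaching 256/512/1024/2048 channels (each block 1×1 reduce, 3×3,
  1×1 expand); stride-2 downsampling at stages 2–4 takes the 20×20 plane to
  10→5→3 so the map never collapses before the global average pool; G is
  2048-2048-128 (ReLU hidden); H is 128-64-1, sigmoid throughout.  The
  stride-1 stem and the stride placement are the minimal adaptation needed
  to push a deep residual trunk through 20×20 inputs.
* Tiny scale (tests, desk runs): same block structure at stem width 8, one
  bottleneck per stage (16, 32 channels), G 32-32-16, H 16-8-1.

All layers are numpy with manual backpropagation (no deep-learning framework
dependency); gradients of every layer and of both loss terms are checked
against central finite differences in the test suite.

## Cross-validation protocol

Subjects (never slices) are partitioned into k = 5 balanced random folds.
Per fold: one contrastive model is trained on all training-fold slices
pooled across slice IDs (a single mapping F), then the 20 classifiers are
trained on training-fold projections, then every held-out student is voted.
Each subject is tested exactly once; a leakage audit records per-fold
train/test subject sets and checks their disjointness.  All randomness
(fold assignment, initialization, minibatch sampling, augmentation) descends
from one pipeline seed via `numpy.random.SeedSequence` spawning, making a
run bit-reproducible at a fixed thread count, and making the rho = 0 run
bit-identical to a plain SimCLR run at the same seed.

Default iteration counts follow the study protocol (2000 contrastive steps,
1000 classifier steps, rho = 0.01); optimizer (Adam, lr 1e-3, contrastive
batch 128 pairs, full-batch classifiers) is this package's choice, as is
"iteration" = one optimizer step on one minibatch.  The desk-scale preset
(`tiny_config`) uses 200 contrastive steps at batch 32 and 800 full-batch
classifier steps at lr 3e-3 — the classifier stage is cheap at this size and
under-training it leaves the per-slice votes miscalibrated even when the
representation ranks students almost perfectly.

## Synthetic cohort

The generator emulates the *structure* of the study data, not MR physics:
per subject, a smooth random background field (white noise smoothed with a
3-voxel Gaussian kernel, rescaled to SD 0.5) plus unit-SD white noise;
class-1 subjects additionally receive a fixed-position 2D Gaussian bump
(sigma 3 voxels, centered at (12, 8) in-plane) added to every slice, scaled
by a per-slice-ID effect profile.  The default profile plants a strong
signal (amplitude 3.0) at slice IDs 13–19, none at IDs 1, 2, 9, 20, and an
intermediate 1.5 elsewhere, reproducing the observed pattern of easy and
hard slices; cohort sizes default to 72/51.  Amplitudes were fixed once in
a design pilot so that the desk-scale pipeline lands in the study's
qualitative regime (easy slices ≈ 0.9 accuracy, hard slices ≈ chance,
student level ≈ 0.9).

What passing tests on this cohort do show: the full pipeline — contrastive
pretraining, per-slice classifiers, voting, cross-validation — extracts a
planted, slice-dependent class signal from noisy images without label
leakage.  What they do not show: anything about real MRI contrast,
between-scanner variation, registration error, or the anatomical truth of
the MFG effect; the generator's classes differ only by the planted bump.

## Numerical and degenerate-case conventions

* Per-slice z-normalization (mean 0, SD 1; constant slice → zeros) before
  both training stages; the slicing axis is configurable because the
  anatomical direction of the 20 planes is an input, not a derived fact.
* Crop windows are half-open, 0-based; center voxel c maps to
  [c − edge/2, c − edge/2 + edge); out-of-bounds windows raise rather than
  pad.
* Cosine similarity raises on zero vectors; NT-Xent requires an even,
  non-empty batch; N = 1 gives loss 0; identical embeddings give
  log(2N − 1).
* Undefined metric ratios (zero denominators) are NaN with a warning, never
  silent zeros.  Accuracy is (TP+TN)/total.  The paired t-test reports NaN
  on zero-variance differences.
* The rho sensitivity grid is {0, 0.01, 0.02, 0.1, 0.3, 0.5}.
* t-SNE uses perplexity 30 (reduced automatically for very small inputs so
  the embedding exists); the linear probe is logistic regression on the 2D
  coordinates, reporting training accuracy as a separability score.

## Limitations

* The numpy implementation is CPU-bound; paper-scale training (ResNet-50
  trunk, 2000 iterations at batch 128) is supported by construction and
  smoke-tested for correctness of shapes and gradients, but desk-scale runs
  use the tiny variant.
* MSE on sigmoid outputs (the classifier objective) converges more slowly
  than cross-entropy; the classifier stage compensates with full-batch
  training and more steps.
* The synthetic effect profile is a fixture — effect sizes on real data are
  unknown; only the qualitative easy/hard ordering is claimed.
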