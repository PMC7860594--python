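# Methods

## Problem and model

Quantitative analysis of neuronal morphology in large optical-microscopy
volumes (Nissl-stained MOST, GFP-labeled fMOST) needs every cell body
(soma) localized and delineated individually. The hard cases are *touching*
somata: adjacent cell bodies of similar brightness whose interface blurs
away, so that any purely intensity-based foreground extraction merges them
into one connected component.

`somaseg` treats the task as contour-aware multi-task dense prediction. A
3D U-shaped fully convolutional network with two sigmoid output heads
predicts, per voxel, the probability of (a) belonging to a soma *interior*
and (b) belonging to a soma *boundary*. The two training targets are
derived from instance labels so that they partition the foreground: the
boundary target is the set of foreground voxels with a 6-neighbor carrying
a different label (another instance or background), dilated by the radius-1
Euclidean ball (the 7-voxel cross) and clipped to the foreground; the soma
target is the remaining foreground. Because the boundary shell is removed,
the soma targets of distinct instances are disconnected — the network is
explicitly taught the separation that thresholding cannot provide.

### Architecture

Encoder/decoder with two resolution levels (the somata are only ~10 voxels
in radius, so deeper pyramids would collapse them spatially):

- blocks of two 3×3×3 convolutions, each followed by batch normalization
  and ReLU;
- down-sampling by 2×2×2 stride-2 convolutions that double the channel
  count (24 → 48 → 96 from a root of 24 features);
- up-sampling by 2×2×2 stride-2 transposed convolutions that halve it;
- skip connections gated by an additive spatial attention module and merged
  with the decoder stream by channel concatenation;
- two 1×1×1 convolution + sigmoid heads (no BN) sharing the final feature
  maps.

The attention gate computes, at the gating (coarser) resolution,
`α = σ(ψ(ReLU(W_x·skip↓ + W_g·gating)))`, where `W_x` is a stride-2 1×1×1
transform bringing the skip tensor to gating resolution and channel count,
`W_g` a 1×1×1 transform preserving the gating channels, and `ψ` a
single-channel 1×1×1 projection; `α` is upsampled by nearest interpolation
and multiplied into the skip features. The gate transforms carry neither BN
nor ReLU. The default configuration has 983,572 trainable parameters
(~0.98 M); the per-block depth and skip-merge operator admit small
variations, so the count is checked as a band, not a point.

The network and its optimizer are implemented directly on numpy arrays: a
small layer library with explicit forward/backward passes (im2col + GEMM
convolutions assembled by contiguous slab copies, analytic batch-norm and
attention-gate gradients, Adam with bias correction). Backprop correctness
is guarded by a finite-difference gradient check in the test suite. The
model is small enough (<1 M parameters, 32³–80³ patches) that BLAS matrix
products on one CPU core train the desk-scale benchmark in minutes.

### Loss

Each branch is trained with `L = L_ce + (1 − D_soft)`: mean binary
cross-entropy plus the soft-Dice loss, with the coefficient
`D_soft = (2Σyp + s) / (Σp + Σy + s)`, smoothing `s = 1e-6` (an empty
prediction against an empty target scores 1). The Dice term counteracts
the extreme class imbalance of the thin boundary target. The total loss is
the sum over the two branches. Probabilities are clamped to
`[1e-7, 1 − 1e-7]` inside the log terms. Within a mini-batch the loss is
computed per sample and averaged — the Dice sums run over one patch's image
space — so a patch whose boundary target is sparse keeps its full gradient
weight instead of being diluted by larger masks elsewhere in the batch;
this materially improves how well the rare touching-interface voxels are
learned.

### Training protocol

Adam (lr 0.001, β₁ 0.9, β₂ 0.999), mini-batch 4, 100 iterations per epoch
(the synthetic benchmark scales this to batch 2 × 20 iterations).
Mini-batches are sampled with replacement from the pool of cropped patches;
the fixed iteration count decouples epochs from dataset size. On-the-fly
augmentation: each spatial axis flipped independently with probability 0.5
(image and targets together), and affine intensity jitter
`x → a·x + b`, `a ~ U(0.9, 1.1)`, `b ~ U(−0.1, 0.1)` on the normalized
image only. Early stopping monitors the validation total loss with
patience 10 (the monitored quantity is a design choice; the protocol names
only the strategy), ties broken by higher *touching-boundary recall* — the
recall of the binarized boundary prediction over ground-truth
instance–instance interface voxels (dilated by the radius-1 ball), the
minority subset that actually drives instance splitting. Validation runs
in evaluation mode without augmentation. All randomness flows from one
integer seed; training is reproducible bit-for-bit on a fixed BLAS.

### Pre- and post-processing

Intensities are z-score normalized with the pooled mean and population
standard deviation of all training-set voxels; the statistics are persisted
in the checkpoint and reused at prediction time. Volumes are cropped into
80³ patches with stride 48 (32-voxel overlap); the final origin per axis is
clamped so the last patch abuts the border, and axes shorter than the patch
are symmetrically zero-padded.

At inference, patch predictions are mosaicked by *center-region ownership*:
a patch owns `[origin + m, origin + patch − m)` per axis with
`m = (patch − stride)/2` (16 at defaults), border patches extending to the
volume edge; overlaps from the clamped final origin resolve in favor of the
later patch. Both probability maps are thresholded at 0.5 (ties count as
foreground). The boundary mask is subtracted from the soma mask, the result
is opened with the radius-1 ball, and 26-connected components of at least
27 voxels (~a 3³ speck; configurable) become watershed markers. The
watershed floods the negated soma probability (optionally the negated
distance transform) from the markers over the union of soma and boundary
masks — the object region together with the subtracted gap it must refill.
Instance centroids (unweighted voxel means) are the localization output.

Feeding ground-truth targets through this stage recovers phantom instance
counts exactly with per-instance Dice ≥ 0.99, which isolates post-processing
correctness from network quality in the test suite.

### Evaluation

Predicted and ground-truth centroids are matched one-to-one, greedily in
ascending Euclidean distance, accepting pairs strictly closer than the mean
soma radius Rc (11 voxels Nissl, 13 GFP, 7 for the synthetic phantoms).
Precision, recall and F1 follow from the match counts; the Dice coefficient
`2|A∩B| / (|A| + |B|)` is computed for matched instances only, and fold
results are aggregated by arithmetic mean (greedy matching equals the
optimal assignment on randomly placed centers; adversarial crossing
configurations where it would not are accepted as documented behavior).

## Synthetic phantoms

No public volume ships with the package; every stage is exercised on
generated phantoms that reproduce the *structure* of the problem: randomly
oriented ellipsoids (axis ratios 0.75–1.3, volume-preserving) with a
low-frequency radial deformation (≤ 15% of radius) emulating irregular
soma shapes; a configurable fraction (default 0.3) placed in touching
clusters of 2–3 with center distance equal to the sum of the *deformed*
directional radii minus 1–2 voxels, overlap voxels owned by the instance
with the smaller normalized ellipsoid distance; per-soma brightness jitter
(foreground 200 ± 30 over background 60); a partial-volume seam at
instance–instance contacts (intensity attenuated 25% on the 2-voxel
interface shell, emulating the unstained membrane gap between abutting
cell bodies — without it an interface between equal-brightness somata
would carry no signal at all); Gaussian blur (σ = 1 voxel) that smears the
seam below the noise floor per-voxel; additive Gaussian noise (σ = 10).
The seam amplitude is set so that global thresholding still merges
touching clusters (interface intensity ≈ 0.75 × foreground stays far above
the foreground/background Otsu threshold), keeping the touching-soma
problem genuinely present — a property the test suite asserts. Default
geometry is 64³ voxels with radii 5–9 (mean 7 — a scaled-down analog of
the 11-voxel Nissl mean radius at 285×285×86).

What the phantoms do **not** model: Nissl texture inside somata, neurites
and vessels (the bright distractors of the GFP data), anisotropic PSF,
slice-to-slice brightness jumps, and annotation noise. Passing the
synthetic benchmark therefore demonstrates that the pipeline's mechanics —
target transformation, multi-task learning, boundary-driven splitting,
assembly, scoring — are correct and that the model can learn blurred-
interface separation; it does not certify accuracy on real stacks.

## Desk-scale benchmark

`somaseg.benchmark.run_synthetic_benchmark` generates 12 phantoms (6–12
somata each), splits them 9 train / 1 validation / 2 test, trains a root-8
model on 32³ patches (stride 24) for up to 60 epochs × 20 iterations at
batch 2 (validation is scored on whole 64³ volumes in one fully
convolutional pass), and evaluates the full inference pipeline on the
held-out phantoms at Rc = 7. Reported quantities: pooled localization
precision/recall/F1, mean matched-instance Dice, and the fraction of
touching pairs — merged by plain 26-connected-component labeling of the
binarized object region (soma ∪ boundary), the boundary-unaware baseline —
that the splitting stage separates. The run takes on the order of ten
minutes on one CPU core; sizes were chosen so a complete
train-plus-evaluate cycle stays desk-scale while leaving the touching-soma
problem genuinely present (thresholding merges at least one cluster in
every default phantom).

## Numerical and degenerate-case choices

- Population (denominator-N) standard deviation for normalization; all-equal
  training voxels raise a degenerate-input error rather than dividing by 0.
- Probability clamp 1e-7, Dice smoothing 1e-6.
- Binarization tie rule: `p ≥ threshold` is foreground.
- Watershed ties resolve by skimage's deterministic flooding order; outputs
  are reproducible.
- Instances too small to retain a soma core after boundary subtraction are
  dropped by the marker-size filter (boundary-only evidence is not counted
  as a detection); the phantom minimum radius of 3 voxels guarantees a
  non-empty core in the ground truth.
- Detection radius comparisons are strict (`< Rc`); distances exactly at Rc
  do not match.
- Checkpoints store weights, architecture configuration, BN running
  statistics and normalization statistics in one versioned npz container.

## Known limitations

- The backend is CPU-only and single-threaded by design of the environment;
  80³-patch inference with the default 24-feature model takes ~10 s per
  patch forward, so whole-brain-scale runs would need a GPU port.
- Boundary recall on *touching* interfaces remains the weakest link (as in
  the underlying method): a missing interface segment under-segments that
  cluster. The benchmark's false negatives come from this mode.
- Greedy matching is 1-to-1 and order-deterministic but not globally
  optimal in adversarial configurations.
- The phantom generator's brightness heterogeneity is a free parameter; it
  is not calibrated against any measured dataset.
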