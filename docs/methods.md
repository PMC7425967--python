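# Methods

This note records the modelling choices, defaults, numerical conventions,
and limitations of the package. It documents what the code does and why;
every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Model

### Attention (CSAM)

The attention module gates a feature map `F ∈ R^{C×H×W}` along both the
channel and the spatial dimension, in parallel, each branch with a residual
connection, aggregated by summation:

    F′ = (F + F ⊗ M_C) + (F + F ⊗ M_S)  =  2F + F ⊗ (M_C ⊕ M_S)

(⊕ is the broadcast sum). The channel gate pools the map spatially into
mean and max descriptors and passes both through a *shared* one-hidden-layer
MLP before summing and applying the sigmoid:
`M_C = σ(MLP(avg) + MLP(max))`. The alternative reading — summing the
descriptors before a single MLP application — would make the weight sharing
vacuous; shared-MLP-then-sum is the construction implemented. The hidden
width is C/r with reduction ratio r = 16 by default (configurable); the
hidden activation is ReLU. The spatial gate stacks the channel-pooled mean
and max maps into two channels and applies a 1×1 convolution (2→1), then
7×1 and 1×7 convolutions with "same" zero padding and no intermediate
nonlinearity, then the sigmoid. No normalisation layer is used inside the
module. Biases are zero-initialised; weights are Kaiming-normal from an
explicit seeded generator.

Useful exact consequences, used as oracles: all-zero parameters give both
gates ≡ 0.5 and hence `F′ = 3F` exactly; a constant input makes the two
channel descriptors equal, collapsing the gate to `σ(2·MLP(v))`.

### Multi-scale dense block

Each building block applies pre-activation BN–ReLU–1×1 convolution to
width k (the growth rate, default 32, necessarily divisible by 4), splits
the result contiguously into four subsets of g = k/4 channels, and runs the
hierarchical residual recursion `y_1 = X_1`, `y_i = K_i(X_i + y_{i−1})`.
Each `K_i` is BN–ReLU–3×1 conv–BN–ReLU–1×3 conv (g→g, same padding); the
factorised pair costs 6g² weights against 9g² for a full 3×3. Subset paths
therefore see 0, 1, 2, and 3 convolution pairs respectively, growing the
receptive field subset by subset. CSAM is applied once, to the
concatenation of y1..y4, and the gated k-channel map is the block's new
features. Dense connectivity concatenates each layer's new features with
everything before it, so a block with L layers adds L·k channels and
contains L(L+1)/2 connections.

Transitions between blocks are BN → 1×1 convolution halving the channels →
2×2 average pooling halving the spatial size. The canonical backbone uses
a 7×7/stride-2 stem convolution, a 3×3/stride-2 max pool (padding 1), five
dense blocks of 6, 12, 24, 32, 16 layers with four interleaved transitions,
a final BN–ReLU, and an 8×8 global average pool. Depth is counted as
1 (stem) + 2 per building block + 1 per transition + 1 (classifier), which
gives 186 for the canonical configuration; the convention is audited by
`count_depth` and exercised on reduced variants. Stem width is 64 (= 2k),
the usual choice for 7×7 stems in densely connected networks; the growth
rate itself is a convention-based default since the four-way split only
fixes its divisibility. The pooled feature vector is exposed raw (no extra
activation after pooling).

### Two-view fusion and cascade

The CC and MLO branches share architecture but never weights — each view
has its own statistics worth modelling (the MLO carries the pectoral
muscle). Branch vectors are concatenated, passed through a 1024-unit
affine + ReLU fusion layer and a 2-class softmax head. Missing views are a
hard error: the canonical model has no single-view fallback. The screening
and diagnosis stages are fully independent models (no shared backbones);
the cascade thresholds stage 1 at P(abnormal) ≥ 0.5 (configurable) and
forwards only abnormal calls to stage 2.

## Training protocol

Momentum SGD with lr 0.001, momentum 0.9, weight decay 1e-4 (classic
L2-coupled form), mini-batch 16, 300 epochs — all defaults overridable for
desk-scale runs; the loss is cross-entropy on the softmax. Phase 1 trains
each branch with its own temporary 2-way head on single-view images.
Phase 2 excludes every branch parameter from the optimizer and runs the
branches in evaluation mode, so batch-norm statistics are frozen too —
"not updated" is read strictly. Because frozen branches are deterministic
feature extractors, phase 2 precomputes branch features once; this is
mathematically identical to running the frozen branches in the loop and is
verified by a byte-exact freeze audit. The learning-rate schedule is
constant; no class re-weighting is applied. Batch statistics use the
biased variance in the normalisation and the unbiased estimate in the
running averages, with momentum 0.1.

## Preprocessing and augmentation

The preprocessing chain is fixed in order: CLAHE contrast enhancement
(clip 2.0 in the OpenCV per-256-bin convention, 8×8 tiles), bilateral
filtering (window 9, σ_color 75 on a 0–255 intensity scale, σ_space 75 px),
per-image min–max normalization to [0, 1], bilinear resize to 512×512
without aspect-ratio preservation. Normalization is per-image (a
dataset-global alternative would couple cases; per-image is the simplest
contract compatible with downstream batch norm). A constant image is
pinned to all-zero rather than dividing by a zero range.

Single-view augmentation emits exactly 50 variants per image, each built
from 1–2 geometric operations (up-down flip, left-right flip, random crop
of 85–100% per side, random down-scale in [0.8, 1.0] with zero padding
back to size, translation by 10% in one of four directions) followed by
1–2 photometric operations (gamma contrast in [0.8, 1.2], Gaussian noise
σ = 0.01 in [0, 1] units, rotation in [0°, 180°]), clipped back to [0, 1].
"One or two of each step" is the design reading of a randomized
combination: it honours the two-step structure while keeping outputs
label-preserving and diverse. Everything is reproducible from the config
seed.

Two-view augmentation only flips, to preserve the CC/MLO correlation: a CC
up-down flip leaves the MLO unchanged; a left-right flip applies to both
views jointly. The default closure emits 4 pairs (identity, each rule, and
their composition); it can be restricted to the two explicit rules.

## Synthetic phantoms

The generator renders what the pipeline needs, not radiographic physics: a
half-elliptical bright breast region against a dark background with
smoothed Gaussian-noise texture (amplitude 0.05), a pectoral wedge in the
MLO view, and optional lesions. Cross-view consistency is modelled as a
shared normalized (depth, lateral) coordinate mapped into each view's
geometry — there is no projection model, which is sufficient to exercise
the premise that the two views carry correlated information. Masses are
Gaussian-profile blobs (radius 3–5.5% of the image side), spiculated with
8 radial spikes when malignant; calcification clusters plant exactly
`n_calcifications` (default 6) separated 1–3 px bright specks, compact and
isotropic when benign, stretched along a line when malignant. Lesion
contrast (default 0.40 added intensity) is monotone by construction and
verified by test. Per-case seeds derive from a master seed via
`SeedSequence`, so datasets are bit-reproducible.

What passing tests on phantoms shows: the architecture trains, the fusion
benefits from two views being present, saliency localizes planted lesions,
and the protocol's invariants hold. What it does not show: performance on
clinical mammograms, robustness to density categories, positioning
variation, or real lesion morphology.

## Numerical choices

The networks run in float64 on a small in-package reverse-mode autodiff
engine (im2col convolutions, tie-splitting max reductions, composite
batch norm). Double precision keeps the analytic oracle tests at tight
tolerances; the models used in tests are small enough that the cost is
irrelevant. Determinism: identical seeds give bit-identical weights,
batches, and losses within a fixed BLAS. Degenerate inputs are rejected
with validation errors (non-finite feature maps, odd transition inputs,
mismatched shapes); a single-class label vector yields AUC = None, never a
silent 0. ROC curves sweep the unique scores from above; the trapezoidal
area then equals the tie-aware Mann–Whitney pairwise statistic exactly.
Grad-CAM uses the last dense block by default (configurable), ReLU-rectifies
the gradient-weighted activation sum, upsamples bilinearly, and min–max
normalizes with the constant-map-to-zero guard.

## Problem sizes in tests

The suite and the acceptance script run reduced variants chosen as the
smallest configurations that still exhibit each property: 64–96 px inputs,
two dense blocks of two layers, growth rate 8, stem 8, reduction ratio 4,
fusion width 16–32; training runs use 8–60 cases and tens of epochs. The
full-depth 512×512 backbone is built and run forward once to audit the
canonical architecture. The ten-fold and AUC oracles run at n ≤ 200.

## Known limitations

- No GPU or mixed-precision path; the engine is single-threaded NumPy with
  BLAS-backed matmuls. Canonical-scale *training* is out of reach by
  design; the canonical forward pass runs in seconds.
- The phantom generator's benign/malignant cues (spiculation, cluster
  anisotropy) are simplistic; diagnosis-task difficulty on phantoms is not
  calibrated to clinical difficulty.
- Augmentation is materialized offline by the CLI; an online per-epoch mode
  exists at the library level (call the augmenter inside a training loop)
  but the offline path is the canonical one.
- Ten-fold results aggregate as mean over folds with per-fold values
  retained; pooled aggregation is not implemented.
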