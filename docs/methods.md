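# Methods

## Scope and design

`cagsnet` implements a 3D encoder–decoder segmentation network whose two
distinguishing components are (a) adjacent-context encoder fusion and (b)
channel attention gates on the skip connections, together with the hybrid
generalized-Dice + cross-entropy loss, BraTS-style evaluation metrics,
preprocessing, and a synthetic phantom generator. Everything is pure
Python/numpy/scipy: the network runs on a small reverse-mode autodiff engine
(`cagsnet.autodiff`) written for this package, with hand-derived
forward/backward passes for 3D convolution (arbitrary stride and padding,
accumulated one kernel offset at a time to avoid materialising im2col
buffers), separable linear interpolation (trilinear upsampling and its exact
transpose), 2×2×2 max pooling, and the usual elementwise/reduction
operators. All math is float32; the engine is single-threaded and fully
deterministic, so identical seeds give bit-identical training trajectories.

## The channel attention gate

Inputs are two equally shaped feature maps: appearance features `x` from an
encoder level and semantic features `y` from the adjacent deeper decoder
level, upsampled to the skip's grid before entering the gate. Both are
projected by learned 1×1×1 convolutions with bias and a leaky ReLU (leakage
μ, default 0.01) into `f` and `g`. The channel correlation δ = f·gᵀ is a
C×C Gram matrix over all N voxels; a row-wise softmax (max-subtracted for
stability) turns it into row-stochastic attention coefficients α. The gate
signal h = W_h(f + g) mixes the spatially fused maps through a third 1×1×1
projection; the response r_i = Σ_j α_ij h_j is a convex combination of the
fused maps, and ω = sigmoid(r) (pre-activation clamped to ±50) gives
per-voxel gate weights strictly inside (0,1) — the gate can only attenuate,
never amplify, which the tests pin as |f⊗ω| ≤ |f|. The gated map is merged
with `y` by channel concatenation (summation selectable via
`merge_mode="sum"`).

Resolved ambiguities, taken as this package's design choices:

* δ lives in R^{C×C} (spatial inner product) and the softmax runs over the C
  channel indices — the only reading consistent with r_i summing j over
  channels; the per-voxel C×N alternative is not implemented.
* The gate signal fuses f(x) + g(y) (not g(x)).
* The projections are 1×1×1 convolutions with C output channels and biases,
  fan-in (He) initialised — the standard attention-gate realisation, which
  preserves N.
* No extra projection is applied between r and the sigmoid.

A classical additive spatial attention gate (a single-channel sigmoid map
ψ multiplying `x`) and an ungated merge are included as ablation arms
(`gate_type="ag"` / `"none"`), sharing the identical config scaffold.

## Backbone

Five resolution levels (configurable); channel widths double from
`base_channels` (default 16; tests and desk-scale experiments use 8), capped
at 256. Each level's context block stacks `n` Conv3×3×3 + LeakyReLU +
GroupNorm units, n = (2, 2, 3, 3, 4) from shallow to deep, with an identity
residual path around the block (1×1×1 projection when widths differ).
Adjacent-context fusion takes the shallower level's output, downsamples it
with a strided 3×3×3 convolution to the current width and grid, adds it
elementwise to the current context features, and applies two serial 3×3×3
convolution units. Channel dropout (default rate 0.2) follows each encoder
level. GroupNorm uses 8 groups, clipped to the channel count — appropriate
at batch size 1, where batch statistics are meaningless.

Decoder levels upsample trilinearly (half-voxel aligned; nearest-neighbour
selectable), project channels with a 1×1×1 convolution, pass the skip pair
through the gate, and fuse with two serial convolution units. The top three
decoder levels carry independent 1×1×1 output heads whose *logits* are
summed after upsampling to full resolution; one sigmoid is applied at the
end (summing logits rather than probabilities keeps the fusion a single
well-calibrated pre-activation). Head biases initialise at −2 so an
untrained network leans toward background (sigmoid(−2·k) < 0.5 for any
number of active heads k ≥ 1).

Unstated operator choices made here: strided-conv downsampling (max-pool +
projection selectable), trilinear-then-1×1×1 upsampling (transposed
convolution not implemented), doubling channel progression.

## Loss

`L = L_gdl + L_bce`, unweighted. BCE is the mean over all class-voxel
entries with predictions clamped to [1e−7, 1−1e−7]. The generalized Dice
loss uses inverse-square class weights ω_j = 1/(count_j + 1e−5)²; the eps
keeps empty classes finite (the standard stabilisation). The loss is
1 − 2·Σ_j ω_j Σ_i P_ij T_ij / Σ_j ω_j Σ_i (T_ij + P_ij), which is 0 at
perfect overlap and 1 at a complete miss — a stray leading 1/N factor seen
in some statements of the loss is not applied, since it would break the
perfect-prediction fixed point. All-empty truth with an all-zero prediction
returns 0 by convention. Class counts come from the ground truth only, so
the weights are constants on the gradient tape.

## Training

Adam (β = 0.9/0.999), lr₀ = 4e−5, decay factor R = 0.5, patience 100. The
plateau schedule (default) multiplies the rate by R when validation loss
has not improved for `patience` epochs; a periodic mode implements
lr_t = lr₀·R^⌊t/τ⌋. Both visit exactly the geometric sequence lr₀·R^k,
which the tests pin. Batch size 1 (group norm makes this stable); datasets
with more than one case split 80/20 train/validation under the config seed;
a single case trains and validates on itself (the overfit regime). A NaN
loss aborts and restores the best weights. Checkpoints are single `.npz`
files with the architecture config embedded as JSON, so loading needs no
external file.

Inference thresholds each class's sigmoid map at 0.5 and resolves
overlapping positives by nested-region priority — enhancing tumor (4) over
necrotic/non-enhancing core (1) over edema (2) — then pastes labels back
onto the native grid through the recorded crop offset. Threshold and the
priority convention are package choices, exposed as parameters.

## Preprocessing

Per-modality z-scoring over *nonzero* (brain) voxels only, background left
at zero — including the overwhelming zero background in the statistics
would swamp the brain signal. Cropping centers a fixed window (default
160×192×128, the standard window for 240×240×155 native volumes; phantoms
use smaller windows) on the nonzero bounding-box centroid, zero-padding when
the box sits near an edge, and refuses to truncate if the brain exceeds the
window. Labels are one-hot encoded per class with no background channel
(the heads are independent sigmoids). Augmentation applies a shared
small-angle rotation (≤10°), shear (≤0.1) and integer shift (≤10 voxels) to
image (linear interpolation) and labels (nearest neighbour), seeded; a pure
integer shift takes an exact path so foreground counts are conserved.
Optional N4 bias-field correction delegates to SimpleITK and is skipped for
phantoms, which have no bias field unless one is requested.

## Synthetic phantoms

A phantom is a brain ellipsoid (radius fraction 0.42 of the volume) with
nested tumor ellipsoids: edema shell (label 2) ⊃ enhancing rim (label 4) ⊃
necrotic center (label 1). Intensities are piecewise constant per
tissue/modality plus Gaussian noise (sd 0.05 against tissue means of order
1), chosen to reproduce the qualitative radiology: enhancement bright in
T1ce relative to T1 (1.8 vs 0.9), edema brightest in FLAIR (1.9), necrosis
dark in T1ce (0.5). Randomized datasets jitter the tumor center by ±8% of
the volume and draw subregion sizes within nesting-safe ranges. Default
test shape is 64³ (32³ for training experiments) to keep runtimes in
seconds-to-minutes; full 240×240×155 generation is a parameter away.

What the phantoms do *not* model: MRI physics (partial volume, texture,
coil inhomogeneity), irregular lesion shapes, multifocal disease, or
inter-scanner variation. Passing tests therefore demonstrate correctness of
the implementation and the learnability of clean nested structure — not
clinical-grade performance, which requires real multi-institutional data
and full-scale training outside this package's scope.

## Metrics

DSC = 2TP/(2TP+FN+FP), sensitivity = TP/(TP+FN), PPV = TP/(TP+FP) over the
nested regions ET = {4}, TC = ET∪{1}, WT = TC∪{2}. Degenerate conventions,
test-pinned: both masks empty → 1; exactly one empty → 0. The 95HD is
symmetric (max of the two directed 95th percentiles — the directed-only
variant is not used, matching challenge practice), measured between
boundary voxels (mask minus its 6-connected erosion) with exact Euclidean
distance transforms honouring anisotropic spacing, so values are in mm when
spacing is. Both masks empty → 0; exactly one empty → a sentinel (image
diagonal by default) with a warning.

## Verification strategy and problem sizes

Every gate equation and the composed forward are checked against an
independent all-loops float64 oracle (C ≤ 4, N ≤ 27, tolerance 1e−5);
the 95HD against a brute-force all-pairs oracle on ≤10³-voxel masks; losses
and overlap metrics against hand-computed closed forms; gradients of each
autodiff operator against central differences. The capacity check overfits
one 32³ phantom with the full-depth network at base width 8 and lr 4e−4
(the default rate scaled ×10, appropriate for a single-sample memorisation
run), stopping once every region's DSC exceeds 0.9 — typically 50–90 steps,
one to two minutes on a CPU. Dropout is 0 in that experiment, as usual for
a capacity check; the training default remains 0.2. The end-to-end CLI
chain runs on three 32³ phantoms with a few epochs — it verifies plumbing
and report schema, not segmentation quality.

## Known limitations

* CPU-only and single-sample: no batching, no GPU, no mixed precision —
  full-scale (240×240×155, base 16+) training is out of reach here by
  design; the architecture is faithful but experiments are desk-scale.
* Sliding-window inference is not implemented; volumes must fit the network
  whole (spatial dims divisible by 2^(levels−1)).
* Transposed-convolution upsampling and per-component (lesion-wise) metrics
  are not implemented.
* The float32 sigmoid saturates to exactly 0/1 for |r| ≳ 17, so the strict
  ω ∈ (0,1) bound holds up to floating-point resolution.
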