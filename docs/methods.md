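# Methods and design notes

## Problem and scope

The package classifies preprocessed volumetric gray-matter maps into
normal controls (NC, label 0) and mild cognitive impairment (MCI,
label 1). Inputs are assumed to be spatially normalized
tissue-probability volumes (the canonical full-scale grid is
84 × 102 × 84 voxels at 1.5 mm); skull stripping, segmentation,
registration, modulation and smoothing are upstream concerns and out of
scope. Because clinical MCI cohorts are access-restricted, the package
ships a phantom generator so the entire pipeline — including its
statistical behaviour — is testable on synthetic cohorts with known
lesion geometry.

## Network

**Backbone.** A 3D residual network in the 18-layer pattern: a 3³
stride-1 stem convolution, 2× max pooling, then four stages of two
basic blocks (two 3³ convolutions with an identity shortcut; the first
block of stages 2–4 downsamples by stride 2 with a 1×1×1 projected
shortcut). Stage widths are (1, 2, 4, 8) × `base_channels`
(default 64; the tests and demo use 8 to keep CPU runs short). Four
downsamplings require every input axis to be ≥ 16 voxels; smaller
grids are rejected with the minimal admissible size in the message.

**Normalization.** Residual blocks use group normalization (groups of
up to 8 channels, per-sample statistics). Batch statistics are noisy
and create a train/inference mismatch at the batch sizes volumetric
training permits (8 here); per-sample statistics make inference
deterministic and batch-composition independent, which the
reproducibility contracts of the training loop rely on.

**Initialization.** All convolution and fully connected weights are
truncated-normal with sd 0.1 (samples redrawn outside ±2 sd); all
biases start at zero. Two builds from the same seed are bit-identical.

**Attention gates.** The deepest stage output g (the gating signal)
carries coarse contextual evidence about where the discriminative
signal lives. For stage-2 and stage-3 feature maps x, a gate computes
one coefficient per coarse location: x is brought onto g's grid by
applying W_x as a *strided* 1×1×1 convolution (per-axis stride
⌈n_x/n_g⌉, validated against the resulting extent), W_g maps g with a
1×1×1 convolution, and

    q = ψᵀ ReLU(W_xᵀ x + W_gᵀ g + b_xg) + b_ψ,   α = σ₂(q).

σ₂ defaults to a softmax over the flattened spatial positions of each
sample, so the coefficients are non-negative and sum to exactly 1; an
elementwise sigmoid is available (`sigma2: sigmoid`) since
softmax-normalized coefficients necessarily shrink as the gating grid
grows. α is resampled to x's grid by trilinear interpolation
(align-corners convention) and applied multiplicatively across all
channels. One structural consequence of the softmax: a constant shift
of q leaves α unchanged, so the scalar bias b_ψ is provably inert in
softmax mode (its gradient is identically zero); it is kept for
fidelity to the gate's standard parameterization and is trainable in
sigmoid mode. The gradient-flow test therefore runs the gate in
sigmoid mode.

**Dilated convolution and the pyramid.** The dilated convolution
evaluates y(m) = Σ x(m + r·i − pad) w(i) with taps spaced r voxels
apart and "same" zero padding, so output grids equal input grids and
rate 1 reproduces ordinary convolution exactly (this is asserted
against a brute-force loop oracle). The effective per-side extent is
k + (k−1)(r−1). The pyramid (ASPP) runs one 3³ branch per rate —
default rates (1, 2, 3) — plus a 1×1×1 branch, concatenates along
channels and projects with a 1×1×1 convolution; no global-pooling
branch is included. Branches are linear (activation follows the
projection), which keeps the single-rate configuration exactly
reducible to a plain convolution for testing.

**Fusion and heads.** `baseline`: global average pool of stage 4 →
linear → 2 logits. `ag`: the two gated maps are adaptive-average-pooled
onto g's grid, concatenated with g along channels, projected by a 1×1×1
convolution with ReLU, pooled, classified. `ag_aspp`: identical except
the gated maps pass their pyramids before fusion. Parameter counts are
strictly ordered baseline < ag < ag_aspp.

## Training

Two-class cross-entropy on the logits (the standard choice for a
softmax classifier). Mini-batches of 8; optimizer selectable among
adam (default), sgd, momentum, rmsprop; base learning rate 1e-3 with
step decay ×0.1 every 10 epochs; 50 epochs by default (the scaled-down
test experiments use 10). A subject-level validation portion (default
20% of training subjects, at least one per class) is carved out before
any augmentation; the checkpoint with the best validation accuracy is
returned (ties to the earlier epoch; training accuracy is the criterion
when no validation split is requested). All stochastic components —
shuffling, the validation split — draw from generators derived from the
config seed, and a non-finite loss aborts with a diagnostic rather than
silently continuing. Identical configs produce identical histories.

## Phantoms

A phantom volume is

    clip( background(grid) × gain_subject × lesion(label) + ε, 0, 1 )

where `background` is a fixed superposition of anisotropic Gaussian
bumps (deterministic given the grid, spanning [0, 0.95] like a
gray-matter probability map), `gain_subject` = 1 + N(0, subject_effect_sd)
is shared by all of a subject's longitudinal scans,
`lesion` multiplies the intensity inside two off-center ellipsoidal
regions (radii ≈ 6% of each axis, mirrored across the midline,
hippocampus-like loci that sit on strong background signal) by
`atrophy_factor` when the label is 1, and ε is i.i.d. N(0, noise_sd)
voxel noise. Defaults: atrophy_factor 0.6, noise_sd 0.05,
subject_effect_sd 0.05 — a clearly separable but non-trivial contrast
(the in-lesion intensity drop is ~8× the voxel noise, while the
subject gain perturbs overall intensity by ±5% so absolute intensity
alone is not a perfect classifier). Randomness is hashed from
(seed, subject id, scan index) into independent substreams, so cohorts
are reproducible and extensible scan by scan.

What the phantom does *not* emulate: anatomical texture, registration
error, scanner effects, partial-volume boundaries, heterogeneous lesion
topography across subjects (every class-1 subject shares the same mask
geometry). Passing phantom experiments therefore demonstrates that the
pipeline learns and localizes a small multiplicative lesion signal
under noise and subject variability — not clinical-grade MCI detection.

## Augmentation

A fixed 25-entry catalogue: identity, 3 single-axis flips, 12 rotations
(±5°, ±10° about each axis, trilinear interpolation, zero padding —
gray-matter maps are zero outside the brain), and 9 additive-Gaussian
noise variants (sd ∈ {0.01, 0.02, 0.03} × 3 draws seeded per catalogue
entry and scan). Entry 0 is always the identity, so the expansion
factor counts the original volume. Augmentation never changes label,
subject id or grid, and is meant for the training side only, after the
subject split. Rotation round-trips (+θ then −θ) recover smooth
content to interpolation accuracy; sharp lesion edges and voxel noise
do not round-trip, which the tests respect by checking inversion on the
smooth class.

## Evaluation

MCI is the positive class. SEN = TP/(TP+FN), SPE = TN/(TN+FP),
ACC = (TP+TN)/total, F1 = harmonic mean of precision and SEN; ratios
with zero denominators are reported as NaN with a warning — silent
zeros would corrupt fold averages. Predictions are the argmax of the
logits; ROC curves sweep all thresholds of the class-1 softmax score
(no intermediate-point dropping) and AUC is the trapezoidal area, which
the tests pin to an O(n²) pair-counting oracle including tie handling.
Evaluation is per scan; splitting and fold assignment are per subject,
class-stratified, so the four-fold cross-validation holds every subject
out exactly once.

## Grad-CAM and localization

Channel weights are the spatial averages of ∂score/∂activation at a
chosen stage (default: stage 4, the deepest convolutional output); the
map is ReLU(weighted activation sum), trilinearly upsampled to the
input grid and peak-normalized. On phantoms the localization score —
mean CAM weight inside the lesion mask over mean outside — quantifies
whether evidence concentrates on the simulated atrophy; it is invariant
under positive rescaling and returns +inf for an exactly
mask-supported map. The pipeline computes CAMs for each scan's
*predicted* class by default: on a well-trained model the class-1 map
of a confident NC scan is legitimately all-zero (no positive evidence
for MCI), so explaining the actual decision is the informative choice.

## Problem sizes in the tests

The statistical acceptance experiment uses a cohort of 40 subjects per
class, one scan each, on a 32 × 40 × 32 grid, atrophy 0.6, noise 0.05,
a 75/25 subject split, and the `ag_aspp` variant at base_channels 8
trained 10 epochs with Adam at 1e-3 (batch 8) — sizes chosen so the
full study runs in minutes on one CPU while leaving the learning
problem non-trivial. The ablation check averages three seeds of
`ag_aspp` and `baseline` on the same cohort and asserts
non-inferiority of the attention variant within two percentage points;
unit tests use 16-voxel-scale grids and 2–4 channel models.

## Known limitations

- The numpy engine is CPU-only and single-volume-scale; full-resolution
  (84 × 102 × 84, base_channels 64) training is expressible but slow.
- Softmax-normalized attention coefficients scale like 1/(spatial
  positions); for much larger gating grids the sigmoid mode is the
  practical choice.
- Checkpoint selection by best validation accuracy is coarse on small
  validation sets (ties are frequent); histories expose the full curves
  for inspection.
- The phantom's lesion geometry is shared across subjects, so
  localization scores overstate what heterogeneous real lesions would
  yield.
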