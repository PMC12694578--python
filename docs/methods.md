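# Methods

`voxsal` implements an explainability pipeline for 3D convolutional
classifiers of structural brain MRI: a truncated residual network built by
2D-to-3D weight inflation, k-fold training with harmonization augmentation,
gradient-weighted class activation mapping (GradCAM) on held-out subjects,
probabilistic-atlas regional scoring, and group-level correlation and
network statistics. Because the class of data it targets (patient MRI
cohorts) is access-restricted, the package ships a synthetic cohort
generator that plants known regional, network and clinical structure, so
every stage of the analysis is exercised and tested end to end without any
download.

## The classifier

The model is a 3D residual network in the basic-block style. The reference
architecture is truncated to 12 learnable layers — a single-channel
7×7×7 stem (64 channels, stride 2) with 3×3×3 max-pooling, stages of
[2, 2, 1] basic blocks at 64/128/256 channels, spatial dropout (p = 0.4),
global average pooling and a 256→2 fully connected head — totalling
4,711,746 trainable parameters (4.7M). The untruncated 18-layer variant
([2, 2, 2, 2] blocks at 64–512 channels, 512→2 head) has 33,161,026
(33.2M). "Learnable layers" counts the stem convolution, two convolutions
per basic block, and the fully connected layer; projection shortcuts are
excluded from the layer count but included in parameter counts. Both
totals were verified by hand enumeration of every weight, normalization
scale/shift, and bias array; single-channel input is the only channel
convention consistent with both printed budgets.

**Weight inflation.** A 2D kernel block of shape (k, k, C_in, C_out) is
replicated along a new depth axis to (k, k, k, C_in, C_out); each depth
slice equals the source kernel, multiplying the parameter count by k. An
optional 1/k rescaling preserves the activation scale of a depth-constant
input. Inflation is plain replication by default, matching the transfer
convention it models. No pretrained weights ship with the package; the
default initialization is seeded Glorot-uniform with zero biases, and
`build_model(..., init="inflated-from-2d")` accepts user-supplied 2D
kernels.

**Training.** Adam with mini-batch 10, 20 epochs, static learning rate
3.0e-4, L2 regularization 5.0e-4 folded into the gradient, shuffling each
epoch, a 5× learning-rate multiplier on the fully connected head, and
inputs rescaled from [0, 255] to [0, 1]. Each training volume is
re-augmented every epoch with the harmonization chain: Gaussian blur with
sd ~ U(0, 1.5) voxels, a 2% global intensity drop, then per-voxel uniform
noise in [0, 5] — randomness injected exactly in the domains where
mixed-scanner data varies without carrying class information. Folds are
class-stratified random partitions (sizes within ±1 overall and per
class); each subject is tested exactly once.

**Batch-norm recalibration.** With only ~100 optimization steps per fold,
the exponentially averaged batch-norm statistics lag the final weights far
enough to corrupt deterministic-eval predictions (we observed 93% train
accuracy under batch statistics against chance-level accuracy under the
running averages). After training, the running mean/variance of every
normalization layer is replaced by exact aggregates computed over the
clean (un-augmented, rescaled) training volumes with frozen weights. This
is the standard recalibration practice for short training runs; statistics
are computed on clean volumes because evaluation inputs are clean.

## Saliency

For class channel h, GradCAM channel weights are the spatial mean of the
gradient of the pre-softmax class score with respect to the designated
feature maps, W_c = (1/N) Σ_xyz ∂y^h/∂A^c; the map is
M = ReLU(Σ_c W_c A^c), trilinearly upsampled (corner-aligned) to the input
grid. Design choices: the gradient target is the class score, not the
loss (prediction-mirroring of misclassified subjects is only coherent
under that reading; a `grad_target="loss"` option preserves the
alternative); rectification is applied once, to the weighted sum, not to
the weights; the designated layer is the output of the final residual
stage — the deepest layer with spatial extent, before dropout and
pooling. Each subject's map comes from the fold where that subject was
held out, computed on the channel the model predicts for them.

Maps are normalized to mean 1 over the brain mask by default so that
regional group statistics compare shapes rather than per-subject,
per-fold response scales; raw maps are available on request. This
convention is an assumption, not a fact about the source procedure; see
"Known limitations" for how it interacts with the phantom.

## Regional scoring and statistics

Regional saliency is the probability-weighted average
score_a = Σ_v p_a(v) M(v) / Σ_v p_a(v): the only convention under which a
constant map scores that constant for every area. Areas are scored
independently; overlapping probabilistic support is legitimate; a
map/atlas grid mismatch is an error (inputs are assumed co-registered).
Lobe profiles take the unweighted mean over member areas per subject,
then the class mean. All 95% intervals are mean ± 1.96·SEM.

Group analyses run over correctly classified subjects only (per-class
exclusion reports are produced). Pairwise area correlation uses Kendall
tau-b (exact two-sided p for n ≤ 10 without ties, normal approximation
otherwise); the per-area node score is the signed sum of significant
(p < alpha, default 0.05, unadjusted) coefficients with all other areas.
Network contrast compares each area's mean tau with same-network areas
against its mean tau with all areas, summarized per network; signed tau
over all pairs is the default, with `use_abs` and `significant_only`
covering the alternative readings. Clinical associations (motor score,
cognition, medication dose, disease duration) are Pearson (t-distribution
p, n−2 df) and Kendall per area, pairwise-complete over non-missing
values, dose restricted to medicated subjects; no multiplicity correction
by default (a Benjamini–Hochberg flag exists but is off, matching the raw
p < 0.05 filtering convention the pipeline models).

## The synthetic cohort generator

Phantoms, not brains. A phantom atlas places Gaussian-blob probability
fields (unit peak at a voxel-aligned center) with mutually distinct
centers; voxels where the stacked probability exceeds 1 are renormalized.
Areas receive round-robin synthetic lobes and functional networks;
hemisphere follows the blob center's x-coordinate.

Each subject volume is: shared template (smooth random field, sd 10
intensity units) + subject texture (smooth random field, sd 8, correlation
length 2.5 voxels) − planted deficit + blur + noise, clamped to [0, 255].
For patients, intensity in each effect area a is reduced by
δ·(s_i + f_{i,net(a)} + ε_{i,a}) weighted by the area's probability field,
with s_i ~ log-normal(median 1, σ = 0.4) the latent severity (positive and
right-skewed, like real early-disease cohorts), f a per-network factor
(sd 0.3) that makes same-network areas co-vary, and ε per-area expression
jitter (sd 0.3) so no two sites are clones. Scan-quality heterogeneity is
emulated by per-subject Gaussian blur with sd ~ U(0.5, 1.5) and additive
uniform noise with amplitude ~ U(1, 5). Clinical scores couple linearly
to severity: motor score 15·s + N(0, 4) floored at 0; cognition
28 − 4·s − N(0, 1.5) clamped to [0, 30]; disease duration 2.3·s +
N(0, 0.8); 36% of patients are medicated with dose 300·s + N(0, 100).
Controls carry no clinical scores (all group analyses run over patients),
and 10% of motor scores are set missing to mirror per-metric n variation
in real tables. Every output is a pure function of (spec, seed).

Free parameters that no external source fixes (atlas size and network
count, effect size, jitter scales, texture and template amplitudes, the
desk-scale classifier width) were calibrated in pilot runs so that the
phantom is neither degenerate nor impossible: the planted effect must be
detectable (pooled accuracy comfortably above 0.8) while subjects differ
by anatomy-scale texture and no planted site duplicates another. Two
early degeneracies are worth recording because they generalize: (i) with
near-zero per-area jitter all planted sites are statistically redundant,
so a classifier provably needs only one of them and "saliency covers
every planted site" is unidentifiable; (ii) with near-zero subject
texture, phantom subjects are nearly identical, classification is
unrealistically easy, and saliency maps have no background mass — which
makes the mean-1 normalization cancel the severity signal out of every
effect area. The shipped defaults avoid both.

## What the phantom does and does not show

Passing tests on the phantom demonstrate that the pipeline's mechanics
are correct (oracle-verified gradients and statistics, exact bookkeeping)
and that planted regional/clinical/network structure is recoverable by
the full train→explain→score→correlate chain under favorable conditions.
They do not show that a real MRI cohort would yield the same result:
phantoms have no anatomy, no registration error, no scanner-site
structure beyond blur/noise, and the desk-scale classifier is three
orders of magnitude smaller than the reference architecture.

Measured limits at desk scale (60 subjects, 32³ grid, printed
hyperparameters, five seeds): pooled hold-out accuracy 0.77–0.88; every
planted area reaches the top 20% of patient-class saliency in 3/5 seeds
(a small CNN trained ~100 steps concentrates evidence on a subset of
redundant sites — one planted site per failing seed lags); the pooled
planted-area association with the motor score is positive in 5/5 seeds
but reaches p < 0.05 in 0/5 (batch normalization makes the converged
classifier largely depth-invariant, so severity reaches saliency only
through spatial extent; at n ≈ 25 retained patients the resulting
ρ ≈ 0.3–0.4 is below the significance threshold); the intra-network
contrast is positive in 3/5 seeds. The statistics-layer tests recover
all three properties cleanly when fed generator-derived deficit maps,
locating the attenuation in the classifier/saliency transduction, not in
the analysis code.

## Numerical choices

Convolutions are evaluated as offset-major im2col matrix products in
float32; gradients were verified against central finite differences.
Batch-norm uses eps 1e-5, momentum 0.1, with the recalibration pass
described above. Adam uses β = (0.9, 0.999), eps 1e-8; L2 is
gradient-coupled (not decoupled weight decay) and skips normalization
parameters and biases. Kendall p-values switch from exact enumeration to
the normal approximation above n = 10 or in the presence of ties;
constant columns produce NaN with a warning rather than an error.
Trilinear upsampling is corner-aligned. Atlas renormalization leaves a
1e-6 headroom so float32 rounding cannot push a voxel's probability sum
above 1. Degenerate inputs (all-zero saliency maps, zero-mass areas,
constant metrics, singleton networks, single-class training partitions)
warn or raise as documented on each function.

## Problem sizes used by the test suite

Unit tests run on 4³–16³ grids with 4–12 areas and up to 120 subjects
(statistics only). The end-to-end recovery test uses the reference
desk-scale conditions — 60 subjects at 32³, a 30-area/10-network atlas,
the reduced classifier (3³ stem, 8 channels; stages of one block at 8 and
16 channels with one stride-2 downsampling; ~17k parameters), 4-fold
training with the printed hyperparameters — five seeds, about 100 s per
seed on one CPU. The acceptance script builds the two full-size
architectures (no training) and completes in seconds.
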