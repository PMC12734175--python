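# Methods

## The model

`leafgate` implements a three-branch hybrid classifier for leaf-disease
images with Gated Scale-Attention Fusion (GSAF):

* **Detail branch** — a shallow CNN with minimal downsampling (two 3×3
  stride-1 convolutions, one 2×2 max-pool, one 3×3 stride-2
  convolution, two residual blocks; batch norm + ReLU after every
  convolution). Output: `detail_channels` feature channels at 1/4 of
  the input resolution (64 channels in the full preset). Its input is
  high-pass filtered (image minus a Gaussian blur, σ = input_size/64
  pixels), so the branch carries high-frequency evidence — speckles,
  lesion edges, thin streaks — and is blind to smooth large-area
  discoloration by construction. This makes the multi-scale division of
  labour between branches structural rather than an accident of
  training.
* **Global-context branch** — a ResNet-style stack on a 2× downsampled
  copy of the image: 7×7 stride-2 convolution, then 3×3 convolutions
  alternating with 2×2 pools, with dilation 2 in the final stage.
  Output: `global_channels` channels (128 in the full preset) at 1/32
  of the input resolution. Sub-pixel texture is invisible to it; what
  remains is whole-leaf structure such as large discoloured areas.
* **Transformer branch** — a ViT encoder over 16×16 patches projected
  to `vit_dim`-wide tokens with learned positional embeddings and a
  prepended CLS token; pre-norm blocks with multi-head self-attention
  (`softmax(QKᵀ/√d_k)V`) and a 4× GELU MLP. The full preset is
  ViT-Base: 12 layers, 12 heads, 768-wide tokens (256 patch tokens for
  a 256×256 input). The CLS embedding after the final layer summarises
  long-range structure.

**GSAF.** Each branch output is projected to a common width C (1×1
convolutions for the CNN maps, a linear map for the CLS embedding) and
globally average-pooled to descriptors z_d, z_g, z_t ∈ R^C. A tiny MLP
maps the concatenation u = [z_d; z_g; z_t] through a GELU hidden layer
of width h to three logits s, and the gate is g = softmax(s/τ) with
temperature τ > 0 (default 1). The fused embedding is the convex
combination Φ = g_d φ_d + g_g φ_g + g_t φ_t, followed by a single
linear classification head. The gate has 3Ch + h + 3h + 3 trainable
parameters — 9 267 at the default C = 256, h = 12, under the 10 k
budget the architecture targets. The output layer of the gate MLP is
zero-initialised so the gate starts exactly uniform and sharpens only
as evidence accumulates; without this the randomly-initialised gate
saturates before the objective can shape it.

Alternative fusion heads used in ablations: score-based attention
fusion (per-branch projections to a 256-wide space, a small shared MLP
scoring each projected vector, softmax weights α, output Σ α_i f_i),
static concatenation and static averaging, optional single-head
cross-attention between the three pooled branch tokens (off by
default), and single-branch heads. Only the submodules a strategy needs
are constructed, so per-strategy parameter counts are honest.

**Objective.** L = L_C + λ·E[H(g)], with L_C cross-entropy (focal loss
with γ = 2 optional, for class imbalance) and H(g) = −Σ g_i log g_i the
gate entropy, estimated by the within-batch mean. λ (default 0.10) is
zero during a warm-up phase (default 5 epochs) and constant afterwards;
during warm-up the regularizer is not added at all, so its gradient
contribution is exactly zero. Optimisation is SGD with momentum 0.9 and
weight decay 5·10⁻⁴ at learning rate 10⁻³ (Adam available), batch size
32. Evaluation uses stratified 5-fold cross-validation with identical
folds for all model variants; augmentation (rotation ±30°, flips,
additive Gaussian noise σ = 0.05, reflect-padded bilinear rotation) is
applied on the fly to training folds only. Paired model comparisons use
McNemar's test on pooled held-out predictions from identical folds
(exact binomial when b + c < 25, chi-square with continuity correction
otherwise).

## Numerical core

No deep-learning framework is used: the package ships a small
reverse-mode autodiff engine over numpy arrays (`leafgate.nn`) with
exactly the operations the model needs (im2col convolution, pooling,
batch/layer norm, batched matmul, softmax, fused cross-entropy).
Every operation's gradient is validated against central finite
differences in float64; the engine is deliberately minimal and
CPU-oriented. Parameters are float32; all weight initialisation,
shuffling, augmentation and synthetic-data randomness derive from one
root seed through named substreams, so any run is reproducible from a
single integer in a fixed-threads configuration.

## Synthetic data

The generator renders an elliptical leaf (faint midrib and symmetric
lateral veins, low-frequency mottle, fine grain) on textured soil, then
places disease cues that differ in *spatial arrangement*, not in colour
chemistry:

* `speckle` — many ~1.4 px two-tone pustules (dark core, brighter rim);
  the rim/core balance keeps the spot-averaged colour near the shared
  lesion colour, so the cue is almost purely high-frequency;
* `blotch` — one large smooth-edged discoloration applied as an
  additive colour shift that preserves the underlying leaf texture:
  a purely low-frequency cue covering twice the streak/speckle area
  fraction, as large-area discoloration does in the field;
* `vein_aligned` — thin (≈1.2 px) lesions along three symmetric pairs
  of lateral veins: fine, long-range structure;
* `healthy` — base texture only; `mixed` — one of the three cues drawn
  per image, forcing image-adaptive gating.

The three lesion cues share the lesion colour and (speckle/vein) area
fraction, so per-class mean channel values agree to < 0.01 and colour
alone cannot separate them. A model-free probe — multinomial logistic
regression on channel means plus log radial spectral band energies —
reaches 96–98 % held-out accuracy on the default 4-class set,
confirming the signal exists independently of any deep model. Images
are quantized to the uint8 grid so a PNG dump round-trips bitwise.

What the generator does **not** emulate: natural background clutter,
illumination and pose variation, within-class symptom progression,
camera noise statistics, and correlated label noise. Passing the
synthetic studies therefore demonstrates the *mechanisms* (gating,
sparsity, scale specialization) rather than field performance.

## Desk-scale study protocols

All behavioural studies (`leafgate.studies`) use the tiny preset
(64 px input, 16/32-channel CNN branches, 2-layer 2-head 64-wide ViT,
C = 32, h = 12) and run on one CPU in minutes. The learning rate is
raised to 0.03 (from the published 0.001, which is calibrated to
GPU-scale datasets) so training converges within the small step
budgets; batch size stays 32. Problem sizes: 200 images per class,
one 80/20 stratified fold for the entropy and specialization studies,
all five folds for the strategy comparison.

* **Entropy contrast** — 6 epochs, 2-epoch warm-up, λ ∈ {0, 1}, three
  paired seeds. The λ = 1 arm ends with (near-)zero mean gate entropy;
  the λ = 0 control keeps a visibly undecided gate. The λ = 1 arm may
  trade some accuracy for sharpness at this scale.
* **Specialization recovery** — the 3-class cue-per-branch set,
  12 epochs, 3-epoch warm-up, λ = 0.1. The expected routing is
  speckle → detail (only the high-pass branch sees pustules) and
  blotch → global (only the low-resolution branch retains the smooth
  discoloration); the vein class can legitimately fall to either the
  detail or the transformer branch at this scale. Across development
  seeds the designed branch wins for at least two of three classes in
  most runs; occasionally the gate assigns blotch to the detail branch
  (which can identify it by elimination in a 3-class closed world).
* **Strategy ordering** — GSAF vs static averaging, identical folds and
  seeds, 8 epochs with a 5-epoch warm-up so all branches are trained
  before the gate sharpens.

A known limitation: the randomly-initialised tiny transformer branch
learns very slowly at these step budgets (its loss can sit at the
uniform-prediction plateau for hundreds of steps), so the gate rarely
selects it. This mirrors the general observation that vision
transformers need pretraining or long schedules to compete at small
scale; the full-size architecture leaves a pretrained-initialisation
hook open.

## Numerical choices and degenerate inputs

* Zero-denominator precision/recall/F1 return 0 (logged), keeping macro
  averages defined; McNemar with b = c = 0 returns p = 1.
* Softmax and cross-entropy are computed with max-subtraction; focal
  loss clamps the true-class probability at 10⁻¹².
* 0·log 0 is treated as 0 in all entropies.
* Non-divisible input sizes raise shape errors naming the offending
  dimension; empty datasets, classes smaller than the fold count, and
  non-finite descriptors are rejected before training starts.
* Pooling layers require exact divisibility (kernel = stride); the
  batch-norm running statistics use momentum 0.1.

## Design choices made where the design was open

* The detail branch's exact layer stack and 1/4 output resolution, and
  the global branch's 1/32 resolution, follow the shallowest stacks
  consistent with the architecture's description.
* The global branch reads a 2× downsampled input copy (one of the two
  published options for rapid resolution reduction); the high-pass
  front-end of the detail branch is this package's complementary
  choice, making the branches' scale separation explicit.
* C = 256 with h = 12 honours both the 256-wide common projection and
  the < 10 k gate-parameter budget, which are incompatible at h = 64.
* Both bias vectors of the gate MLP are counted in the parameter
  budget.
* The ViT branch is randomly initialised; no weights are downloaded.
* Fusion operates on pooled per-image vectors; per-location gating is
  out of scope.
* The epoch count has no published value and is a per-experiment
  setting throughout.
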