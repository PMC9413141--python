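# Methods

## Problem and model

Nodule segmentation in B-mode ultrasound is hard for three reasons the
package's phantom generator reproduces deliberately: edges are weak
(acoustic interfaces blur the lesion boundary), contrast is low (a nodule
is only slightly hypoechoic relative to surrounding tissue), and lesion
size and position vary widely, including lesions clipped by the image
border.

The model is a U-shaped encoder–decoder over single-channel images with a
per-pixel two-class softmax head. Three bespoke blocks are inserted at
every pyramid level below full resolution:

**Backbone block.** A residual block whose feature extractor is a 7×1
convolution followed by a 1×7 convolution (both same-padded), then
batch-norm, a 1×1 convolution, Mish, a second 1×1 convolution, and an
element-wise residual sum with the input. The factorized pair covers the
same 7×7 receptive field as a dense large kernel with 2k/k² = 14/49 of the
weights — a reduction of ≈71.4%, "approximately 72%". Mish
(y = x·tanh(softplus x)) is used throughout the network because it is
smooth, avoids dead units, and is bounded below (≈ −0.309).

**Context-attention block.** Layer normalisation and three 1×1 convolutions
produce query/key/value embeddings with C′ channels (default C′ = C/2).
The query map is tiled into non-overlapping 8×8 windows (N1 = (H/8)(W/8)
after padding to a multiple of 8); key/value maps are cut into overlapping
10×10 windows moved with stride s (default 1; N2 = (⌊(P−10)/s⌋+1)² on the
padded map). Attention logits between every flattened query pixel (M1 =
64·N1) and every key-value window pixel (M2 = 100·N2) are q·k plus a
learned relative-position bias φ, scaled by 1/√C′; rows are softmaxed over
M2 and applied to the values. φ is a (2R+1)² table (R = 15) indexed by the
clipped 2-D offset between the query and key pixel, so the bias depends
only on relative position. Two residual stages close the block:
y′ = g(attn) + x and y = g₂(LN(y′)) + y′, both 1×1 projections, so the
output keeps the input shape.

Two scope modes are provided. *Global* evaluates the full M1×M2 problem.
Implementation note: with overlapping windows a key pixel contributes the
same logit from every window containing it, so the M2-softmax is computed
exactly as a dense softmax over unique pixels with log-multiplicity added
to the logits — an algebraic rewrite, verified in tests against the literal
M1×M2 enumeration to machine precision. Even so the cost grows with P⁴, so
global scope is used where the padded map is at most `global_attn_hw`
(default 16) and the *paired-window* mode — each 8×8 query window attends
to its own 10×10 key-value window (the window plus a 1-pixel halo) — serves
larger maps up to `attn_max_hw` (default 32). Above that, levels carry no
attention block. In the decoder the query comes from the same-level encoder
skip and key/value from the deeper decoder output, upsampled to the skip
resolution (nearest-neighbour) first.

**Nodule-adaptive convolution (NAC).** Four parallel branches — 1×1, and
3×3 with dilation 2, 3, 5; effective extents (k−1)d+1 = 1, 5, 7, 11 — each
followed by batch-norm and Mish. A head (global average pool → one fully
connected layer → softmax) predicts a convex weight per branch from the
input, so the weights are non-negative and sum to one by construction. The
weighted sum of branch outputs passes through a 1×1 fusion convolution,
batch-norm and Mish. The block sits at the end of the encoder (bottleneck).

**Loss.** The class-imbalance loss replaces the cross-entropy argument with
g(p) = p(1−p)² + p²/2 at the true-class probability p of every pixel:

    L = −(1/HW) Σ_{x,y} Σ_c R_{x,y,c} · log g(p_{x,y,c})

The (1−p)² factor damps well-classified pixels (the focal-loss mechanism),
and the p²/2 term keeps g strictly increasing (g′ = 3p² − 3p + 1 > 0).
Because g(1) = 1/2, the loss floor is log 2, not 0; the curve is offset but
the minimiser is unchanged, and the loss is implemented exactly as printed.
The trailing 2 is read as a denominator on the p² term only; the
alternative reading (the whole argument halved) is available as
`loss_variant="all_half"`. The log argument is clamped at 1e−7 so value and
gradient stay finite at p = 0. BCE and soft-Dice (smoothing 1.0 in
numerator and denominator, pooled over the batch) are provided for the loss
ablation.

## Numerical and engineering choices

- The network, autodiff and optimizers are built on numpy with the
  `autograd` package for reverse-mode differentiation. Convolution, 2×2 max
  pooling and 2× nearest upsampling are autograd primitives with
  hand-written vector-Jacobian products (stride-1 transposed convolution
  for the input gradient; per-tap tensordots for the kernel gradient).
- Both equations that combine a branch with its input ("⊕") are implemented
  as element-wise addition: the declared output shapes equal the input
  shapes, which concatenation would violate.
- Logits are scaled by 1/√C′ (the conventional choice; the printed formula
  is ambiguous between C′ and √C′).
- Padding for attention windows is reflect-style (symmetric), implemented
  as a differentiable index gather; outputs are cropped back.
- Batch-norm uses momentum 0.1 running moments; evaluation always uses the
  running statistics.
- Attention output projections are initialised at 0.1× He scale so a fresh
  block starts close to the identity (the residual path dominates); a
  `zero_output` hook makes it exactly the identity.
- Optimizers: SGD (momentum 0.9), Adam, and AdaBound implemented from its
  reference formulation — Adam moments with per-element step sizes clipped
  into a band that tightens toward `final_lr` (default 0.1, scaled along
  with any schedule) at rate γ = 1e−3. The cosine-annealing schedule spans
  the full run with no restarts. The training loop seeds initialisation,
  shuffling and augmentation from a single seed and keeps the
  best-validation-Dice checkpoint; training aborts with diagnostics if the
  loss becomes non-finite.
- Metrics with zero denominators (e.g. precision of an empty prediction)
  are reported as NaN and excluded from per-image means; overlap scores are
  percents, rate scores fractions. Default aggregation over a dataset is
  the per-image mean; a pooled mode (sum counts first) is also available.
- The 8:1:1 split takes ⌊0.8n⌋ for training and halves the remainder, the
  odd leftover going to validation: split_811(7288) → (5830, 729, 729).

## The phantom generator

Each phantom is: a smooth low-frequency background field (mean 0.55,
amplitude 0.06), minus `contrast_drop` (default 0.15) times the
Gaussian-blurred nodule footprint, all multiplied by gamma speckle with
unit mean — the standard multiplicative model of fully developed speckle,
under which the local variance scales with the squared local mean. The
nodule is a randomly oriented ellipse with low-frequency radial wobble;
size classes occupy disjoint area-fraction bands (small 0.5–2%, medium
2–8%, large 8–25%) enforced by rescaling, and placement is central, random,
or edge (the contour touches the image border, as clipped lesions do in
clinical crops). The ground-truth mask is the *unblurred* geometric
support: the weak edge is a property of the image only, mirroring how an
expert traces the lesion rather than the gradient.

Blur width and speckle grain are defined at the 256×256 working size
(σ = 2 px, gamma shape 4) and rescaled with resolution — σ ∝ size/256,
shape ∝ (256/size)² — because downsampling a physical image shrinks edge
widths and averages speckle cells. Without this, a 64×64 phantom is not a
smaller version of the task but a much harder one: a model-free
log-compress/smooth/threshold probe scores Dice ≈ 3 on small nodules with
unscaled noise versus ≈ 13 (and 75/97 for medium/large) with scaled noise.

What the phantoms do **not** model: anatomy (gland, trachea), acoustic
shadowing and enhancement, heterogeneous internal echotexture,
calcifications, multiple nodules, and scanner post-processing. Passing the
end-to-end checks therefore shows the pipeline can learn weak-edged,
low-contrast, variably-sized and -placed targets under speckle — not
clinical performance.

## Problem sizes for the single-CPU checks

The end-to-end checks run a "desk preset": a depth-4 network (widths
8/16/32/64) on 64×64 phantoms, 200 training / 50 validation / 50 test
samples, 30 epochs, batch 8, augmentation with probability 10/11 (rotation
θ ~ U(−10°, 10°), horizontal flip p = 0.5), AdaBound with initial lr 1e−3
and cosine annealing. These sizes were chosen so a full training run is a
few minutes of numpy on one core while still exercising every block;
full-scale defaults (depth 5, widths 16–256, 256×256, batch 16, 200
epochs) remain the package defaults.

## Known limitations

- Global attention cost grows as P⁴ with map size; it is capped at small
  padded maps by default and the paired-window mode covers mid-sized maps.
- No multi-head attention (a single attention map per block, as specified).
- No GPU or mixed precision; numpy float64 throughout.
- AdaBound's terminal rate and γ are package defaults, not published
  values.
- Table-scale absolute scores from the source datasets are out of scope:
  the published per-level channel widths and depth are unknown, and the
  datasets are not redistributable.
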