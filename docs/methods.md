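# Methods

## Detector

The detector is a fully convolutional one-stage network. An input RGB
image (resized to 600×400 by default and zero-padded so both sides are
divisible by 32) passes through:

1. **Backbone.** ResNet50 (GroupNorm variant, see *Numerical choices*)
   whose stage outputs C2–C5 sit at strides 4/8/16/32 with widths
   256/512/1024/2048. Every 3×3 convolution inside the bottleneck
   blocks of C3–C5 is a *modulated deformable convolution*: an
   auxiliary 3×3 convolution over the same input predicts, per output
   location, 2·3·3 sampling offsets (dy, dx per kernel point, shared
   across channels) and 3·3 modulation coefficients squashed to [0, 1]
   by a sigmoid. Sampling is bilinear; samples outside the map
   contribute zero. With zero offsets and unit modulation the operator
   equals a standard convolution — the offset branch is zero-initialized
   with the modulation bias at `logit(0.9999)` so training starts from
   (numerically) plain-convolution behavior.
2. **Pyramid.** A standard top-down FPN over C3–C5 with 1×1 laterals
   and 3×3 output convolutions, plus F6 and F7 from two stride-2 3×3
   convolutions on F5; all levels have 256 channels (strides
   8/16/32/64/128).
3. **LSC attention.** `n_blocks` (default 3) repetitions of
   level → spatial → channel attention, all shape-preserving:
   * *Level (M_L)*: per level, global average pool → 1×1 conv (C→1) →
     ReLU → hard-sigmoid `clamp((x+3)/6, 0, 1)`; the resulting scalar
     in [0, 1] rescales the level.
   * *Spatial (M_S)*: per level, offsets/modulation for a modulated
     deformable 3×3 conv are predicted from that level; the level and
     its neighbors (bilinearly resized to its grid) each pass through a
     deformable conv with those shared offsets and per-role kernels
     (finer/self/coarser, unshared by default), and the results are
     averaged over the available members — interior levels average 3,
     F3 and F7 average 2.
   * *Channel (M_C)*: global pool over levels and space → bottleneck
     C → C/4 → 4C → `2σ(x)−1` normalizer onto [−1, 1] → residual
     per-channel coefficients `a₁ = 1 + 0.5·n₁`, `a₂ = 0.5·n₂`,
     `b₁ = 0.5·n₃`, `b₂ = 0.5·n₄`; each element becomes
     `max(a₁x + b₁, a₂x + b₂)` (identity-slope/ReLU at initialization).
4. **Head.** Two parallel towers of four 3×3 conv + GroupNorm + ReLU
   layers (256 channels, parameters shared across levels): the
   classification tower ends in a 3×3 class predictor; the regression
   tower ends in two 3×3 branches — four box-edge distances and one
   center-offset logit. Distances decode as
   `exp(scale_l · raw) · stride_l` with a per-level learnable scalar,
   so they are positive and start at one stride. A location `(i, j)` on
   level `l` anchors at `(stride·(j+½), stride·(i+½))`; its box is
   `(x−l, y−t, x+r, y+b)` clipped to the image, scored by
   `s = σ(cls)·σ(ctr)`.

## Label assignment and loss

A location is a candidate for a ground-truth box iff it lies inside the
box, within `candidate_radius · stride` (default 1.5 strides,
Euclidean) of its center, and its level's regression range
((−1,64), (64,128), (128,256), (256,512), (512,∞) pixels on the max
edge distance) covers the location's max distance; ties go to the
smallest box. Candidates receive

    w_pos = t·e^{μt},  t = s·IoU^β         (μ = 5, β = 2)
    w_neg = P_neg(IoU)·s^γ                  (γ = 2)
    P_neg = clamp(19/9 − 20/9·IoU, 0, 1)    (1 below 0.5, 0 above 0.95)

with `s` the fused score and IoU measured between the *currently*
decoded box and the ground truth, recomputed every iteration. `w_pos`
is detached — a pure supervision strength — while `w_neg` stays inside
the autograd graph, so gradients flow through the live ranking signal.
The loss per image is

    L = L_cls + λ·L_reg,  λ = 1
    L_cls = Σₙ[−w_pos ln sₙ − w_neg ln(1−sₙ)] + Σₘ FL(sₘ, 0)
    L_reg = Σₙ w_pos·(1 − GIoU(bₙ, b′ₙ))

with focal parameters α = 0.25, η = 2.

**Normalization.** The raw sums grow with image size and must be
normalized for small-batch training. The w_pos-weighted sums (positive
classification term, regression term) are divided by the bare
`Σ w_pos` — a weighted mean. This matters: `w_pos ∝ s`, so early in
training every weight is minute, and any normalizer bounded below by a
constant freezes the positive supervision entirely; we verified that a
`max(Σw_pos, 1)` normalizer collapses from-scratch training to the
all-background solution. The negative terms (`w_neg` and the focal
background sum) are divided by the candidate count, the usual dense-
detector average factor.

**Stability.** All log-likelihood terms are evaluated from logits with
softplus identities (`ln σ(z) = −softplus(−z)`), never through clamped
probabilities — an epsilon clamp has zero gradient in saturation and
makes score collapse irreversible.

**LSC normalization.** Two GroupNorms stabilize the attention stack:
one normalizes the view of the level from which M_S predicts its
offsets, one normalizes the aggregated output. Without them the
pyramid magnitudes (unnormalized by construction) grow without bound
and the learned offsets drift off the feature map, after which every
sample is out of bounds and the attention output degenerates to a
constant; both effects were observed directly. The attention equations
are unchanged — the norms are the same stabilizers the dynamic-head
family of attention modules uses. The M_S self-role kernel is
initialized to a center delta (neighbor kernels at 0.1× scale) so an
inserted block starts near identity.

A plain-FCOS configuration (no deformable convs, no LSC, focal +
centerness-BCE + centerness-weighted GIoU loss) is retained as the
ablation reference.

## Training and inference

SGD with momentum 0.9 and weight decay 1e-4; base learning rate
0.00125 reached linearly from 0.001 over the first 1000 iterations;
batch size 2; 12 epochs with ×0.1 drops after 8 and after 11 completed
epochs. Augmentation is a seeded horizontal flip (p = 0.5) after
resizing to 600×400; images are normalized by the ImageNet channel
statistics and zero-padded to /32. At test time, per level, scores
below 0.4 are dropped and the top 1000 detections kept; levels are
pooled, class-wise greedy NMS at IoU 0.6 is applied, and the top 100
detections per image survive. Evaluation reports COCO-style AP/AR:
101-point interpolated precision averaged over IoU thresholds
0.50:0.05:0.95, with the standard small/medium/large area bins
(detections are evaluated at a 0.05 score threshold; 0.4 is the
deployment filter).

## Synthetic orchard scenes

The generator renders, in HSV, a textured green field (seeded low-pass
noise + vertical gradient, hue ≈ 100°), shaded fruit ellipses whose hue
is the background hue plus `fruit_hue_offset` (degrees — the single
knob controlling green-on-green difficulty), elongated darker-green
occluder strokes drawn above the fruit, a global lighting transform
(soft, strong, backlight ramp, or low light) and Gaussian distance
blur, then converts to RGB. Ground truth is COCO-format: each box is
the tight bound of a fruit's *visible* pixels (what an annotator could
draw), and fruits below `min_visible_fraction` (default 0.25) are not
annotated. Scenes are byte-reproducible: the per-image seed is
`seed + image_index`, so datasets extend without reshuffling.

What the generator does **not** emulate: real leaf texture and
specularity, perspective and 3-D occlusion geometry, camera noise, and
the long-tailed scale distribution of orchard photographs. Passing the
synthetic benchmark therefore demonstrates that the implementation
learns and localizes correctly end to end, not that it reaches any
particular accuracy on real orchard imagery.

## Desk-scale benchmark

The end-to-end benchmark (`run_smoke_benchmark`) uses easy scenes —
128×128 pixels, 2–4 fruits of radius 10–22 px, 40° hue offset, no
occluders or overlap, mild blur — with 64 training and 16 validation
images, and a reduced detector: backbone width ×0.25, 32-channel
FPN/head, one LSC block. Training runs 300 iterations at batch 2 from
random initialization (no pretrained weights exist for this stack), so
the benchmark uses its own optimizer setting: lr 0.02 with a 50-
iteration warmup from 0.004 and a ×0.1 drop at iteration 250 — the
published 0.00125 is a fine-tuning rate and is far too small to train
from scratch in 300 iterations. One run takes about a minute on one
CPU core.

At this budget the full model halves its loss and recovers most fruit
at IoU 0.5, but the plain-FCOS configuration still localizes more
tightly (higher AP over the strict IoU grid): both the attention stack
and the consistency-driven dual weighting are additions whose benefits
need training horizons far beyond 300 from-scratch iterations, and the
benchmark records this honestly rather than reproducing the sign of
the full-scale ablation.

## Complexity accounting

`complexity()` counts trainable scalars and the multiply–accumulates
of convolution and fully connected layers, evaluated symbolically at
the stated input size (no /32 padding), with one MAC counted as one
FLOP; normalization, activations, pooling and the deformable sampler's
interpolation arithmetic are excluded. Under this convention the
plain configuration lands at 32.1M parameters / 47.5 GFLOPs at
(600, 400) and the full configuration at 38.7M parameters. The full
configuration's FLOPs (≈69 G) *exceed* the plain ones: per-level LSC
attention adds deformable-convolution work at every pyramid level on
top of the unchanged backbone and head, and no parameter-consistent
reading of the architecture reduces compute below the baseline unless
the pyramid (and the head) is collapsed to the middle level's
resolution, which the per-level head design used here deliberately
avoids.

## Numerical choices

* GroupNorm everywhere (preferred 32 groups, at least 4 channels per
  group): batch-2 training makes batch statistics unusable, and the
  affine parameter count equals BatchNorm's, leaving the complexity
  figures unchanged. No pretrained checkpoint is bundled; weights are
  seeded He-normal.
* Classification predictor bias starts at `−log((1−π)/π)`, π = 0.01
  (the dense-detector background prior); modulation biases at
  `logit(0.9999)`; offset branches at zero.
* Bilinear resizing uses half-pixel alignment with clamped edges and
  is implemented as separable interpolation matrices (exact transpose
  in the backward pass). The FPN top-down upsampling is
  nearest-neighbor, the FCOS-family convention.
* The head towers run over all levels as one zero-padded, level-
  stacked batch with mask-corrected GroupNorm statistics — numerically
  identical (≤ 2e-5) to per-level application, and several times
  faster; the equivalence is asserted in the test suite.
* Ties: a location claimed by several ground truths goes to the
  smallest area; NMS suppresses at IoU strictly greater than the
  threshold; score sorts are stable.
* Degenerate inputs: empty ground truth yields a pure-background loss;
  empty detections are valid; evaluation with no ground truth and no
  detections is flagged undefined (NaN), never reported as 0.

## Limitations

* Training at the published scale (600×400, 12 epochs) is out of reach
  of a pure-CPU stack; all end-to-end evidence comes from the reduced
  benchmark above.
* The dual-weighting hyperparameters (μ, β, γ, λ) are not stated in
  the source description of the method; the defaults here follow
  common dual-weighting practice and are exposed in `AssignConfig`.
* The LSC block count is under-determined by its published parameter
  and FLOP deltas, which are mutually inconsistent; the default of
  three unshared blocks matches the parameter budget and treats the
  FLOP figure as unreliable (see *Complexity accounting*).
* Synthetic scenes are a stand-in: absolute accuracy numbers do not
  transfer to real orchard data.
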