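# fcoslsc — anchor-free green-fruit detection at desk scale

Detecting green fruit against green foliage is one of the harder
problems in orchard phenotyping and robotic harvesting: the target and
the background share hue, fruits overlap and hide behind branches, and
illumination swings from backlight to night lighting. `fcoslsc`
implements the FCOS-LSC detector for this problem — an anchor-free
dense detector built from:

* a **ResNet50 backbone with modulated deformable 3×3 convolutions** in
  stages C3–C5: each kernel point *n* samples the input at
  `p + p_n + Δp_n` (bilinear, zero outside the map) scaled by a learned
  coefficient `Δm_n ∈ [0, 1]`, so the receptive field adapts to fruit
  shape and background points can be switched off;
* a **feature pyramid (F3–F7, 256 channels)** refined by an **LSC
  attention stack** acting on the three axes of the pyramid tensor
  `X ∈ R^{L×S×C}`: level attention `M_L` (pooled 1×1 conv →
  hard-sigmoid weight per level), spatial attention `M_S` (each level's
  neighbors are resized to its grid and aggregated through modulated
  deformable convolutions with offsets predicted from that level), and
  channel attention `M_C` (a dynamic activation
  `max(a₁x + b₁, a₂x + b₂)` with per-channel coefficients from a pooled
  bottleneck, bounded in [−1, 1]);
* a **decoupled dense head** predicting per location a class score, the
  four box-edge distances `(l, t, r, b)` and a center-offset score,
  fused at inference into `s = σ(cls)·σ(ctr)`;
* **dual-weighting label assignment**: candidates near a ground-truth
  center each receive a positive weight
  `w_pos = t·e^{μt}`, `t = s·IoU^β`
  (agreement of classification and regression) and a negative weight
  `w_neg = P_neg(IoU)·s^γ`, where `P_neg` falls linearly from 1 at
  IoU 0.5 to 0 at IoU 0.95 — so fuzzy boxes with equal positive weight
  still receive distinct supervision. The loss is
  `L = Σₙ[−w_pos ln sₙ − w_neg ln(1−sₙ)] + Σₘ FL(sₘ, 0) + λ Σₙ w_pos·(1−GIoU)`.

Because the original apple/persimmon images are not publicly deposited,
the package ships a seeded **synthetic orchard generator** that
emulates the study conditions — green-on-green hue separation as a
single knob, fruit–fruit overlap, branch/leaf occluders, lighting modes
(soft/strong/backlight/low-light) and distance blur — and annotates the
visible extent of every fruit in COCO format. Everything (tensor
autograd, convolutions, the deformable sampler, SGD, COCO-style
AP/AR) runs on numpy + numba: the whole pipeline trains and evaluates
on a laptop CPU.

## Worked example

Generate a small synthetic orchard and inspect it:

```bash
$ fcoslsc synth --out-dir demo_orchard --n-images 4 --width 128 --height 128 \
      --hue-offset 12 --seed 7
wrote 4 images + demo_orchard/annotations.json
```

```python
>>> from fcoslsc import read_coco
>>> samples, cats = read_coco("demo_orchard/annotations.json")
>>> len(samples), sum(len(s.boxes) for s in samples), cats
(4, 17, {1: 'fruit'})
>>> samples[0].boxes[0]
Box(x_min=23.0, y_min=70.0, x_max=59.0, y_max=114.0)
```

Seventeen fruits survived the visibility rule (a fruit more than 75%
hidden is not annotated); each box is the tight bound of a fruit's
visible pixels. Count parameters and conv/linear FLOPs of the plain
baseline configuration at the reference input size:

```bash
$ fcoslsc complexity --plain-fcos
input (600,400)  params 32.12M  flops 47.50G
```

Train and evaluate on a generated dataset (`fcoslsc train`,
`fcoslsc eval`, `fcoslsc infer`), or drive everything from Python:

```python
>>> from fcoslsc.engine_eval import run_smoke_benchmark
>>> r = run_smoke_benchmark(seed=1, full=True)   # ~1 minute on a CPU
>>> round(r["loss_drop"], 3), round(r["AP50"], 1)
(0.691, 74.8)
```

This trains the reduced-width detector for 300 iterations on 64 easy
synthetic scenes and reports the loss decrease and COCO-style AP50 on
16 held-out scenes: the loss fell by 69% and three in four annotated
fruits are recovered at IoU 0.5 with high precision.

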