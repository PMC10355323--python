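"""Feature pyramid (F3-F7, 256 channels) and the LSC attention stack.

The LSC stack applies, in order, per block:

* scale attention ``M_L``: one weight per pyramid level from a global
  average pool -> 1x1 conv -> ReLU -> hard-sigmoid, multiplied back onto
  the level;
* spatial attention ``M_S``: each level predicts offsets/modulation for a
  modulated deformable 3x3 conv from its own (unadjusted) features, its
  neighbor levels are resized to its grid, each member is passed through
  a deformable conv with the shared offsets, and the results are
  averaged over the available members (boundary levels average over 2);
* channel attention ``M_C``: a dynamic piecewise-linear activation
  ``max(a1*x + b1, a2*x + b2)`` whose per-channel coefficients come from
  a pooled bottleneck (C -> C/r -> 4C) squashed to [-1, 1] and added as
  residuals to the identity coefficients (a1=1, a2=b1=b2=0).

Shapes are preserved exactly by every attention, so the stack can be
repeated ``n_blocks`` times and the head consumes each level at its
original resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .backbone_dcn import StageOutputs, _MOD_BIAS
from .config import LSCConfig

PYRAMID_STRIDES = (8, 16, 32, 64, 128)


@dataclass
class PyramidFeatures:
    """Ordered multi-scale stack [F3..F7]; conceptually X in R^{L x S x C}."""

    levels: List[nn.Tensor]
    strides: Optional[Sequence[int]] = None

    def __post_init__(self):
        if self.strides is None:
            self.strides = PYRAMID_STRIDES[:len(self.levels)]
        if len(self.levels) != len(self.strides):
            raise ValueError("one stride per level required")

    @property
    def num_levels(self):
        return len(self.levels)

    def shapes(self):
        return [t.shape for t in self.levels]


class FPN(nn.Module):
    """Top-down pyramid with 1x1 laterals; F6/F7 by stride-2 3x3 convs on F5."""

    def __init__(self, in_channels, out_channels=256, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.out_channels = out_channels
        self.laterals = [nn.Conv2d(c, out_channels, 1, rng=rng) for c in in_channels]
        self.fpn_convs = [nn.Conv2d(out_channels, out_channels, 3, rng=rng)
                          for _ in in_channels]
        self.extra6 = nn.Conv2d(out_channels, out_channels, 3, stride=2, rng=rng)
        self.extra7 = nn.Conv2d(out_channels, out_channels, 3, stride=2, rng=rng)

    def top_down(self, stages: StageOutputs):
        """Laterals fused top-down by elementwise addition (pre-refinement)."""
        cs = [stages.C3, stages.C4, stages.C5]
        lats = [conv(c) for conv, c in zip(self.laterals, cs)]
        fused = [None] * 3
        fused[2] = lats[2]
        for i in (1, 0):
            up = nn.resize_nearest(fused[i + 1], lats[i].shape[-2:])
            fused[i] = nn.add(lats[i], up)
        return fused

    def forward(self, stages: StageOutputs) -> PyramidFeatures:
        fused = self.top_down(stages)
        outs = [conv(f) for conv, f in zip(self.fpn_convs, fused)]
        f6 = self.extra6(outs[2])
        f7 = self.extra7(f6)
        return PyramidFeatures(levels=outs + [f6, f7])

    def macs(self, stage_hw):
        """stage_hw: [(h,w) of C3, C4, C5]."""
        total = 0
        for lat, conv, (h, w) in zip(self.laterals, self.fpn_convs, stage_hw):
            total += lat.macs(h, w) + conv.macs(h, w)
        h6, w6 = self.extra6.out_hw(*stage_hw[2])
        h7, w7 = self.extra7.out_hw(h6, w6)
        total += self.extra6.macs(h6, w6) + self.extra7.macs(h7, w7)
        return total, stage_hw + [(h6, w6), (h7, w7)]


def build_pyramid(fpn: FPN, stages: StageOutputs) -> PyramidFeatures:
    return fpn(stages)


class ScaleAttention(nn.Module):
    """M_L: per-level scalar weight in [0, 1] from a global pool."""

    def __init__(self, channels, cfg: LSCConfig = None, rng=None):
        cfg = cfg or LSCConfig()
        self.cfg = cfg
        self.conv = nn.Conv2d(channels, 1, 1, rng=rng)

    def level_weight(self, x):
        gap = nn.mean(x, axis=(2, 3), keepdims=True)          # (N, C, 1, 1)
        z = nn.relu(self.conv(gap))                           # (N, 1, 1, 1)
        return nn.hard_sigmoid(z, self.cfg.hard_sigmoid_offset,
                               self.cfg.hard_sigmoid_divisor)

    def forward(self, pyramid: PyramidFeatures) -> PyramidFeatures:
        levels = [nn.mul(self.level_weight(x), x) for x in pyramid.levels]
        return PyramidFeatures(levels, pyramid.strides)

    def macs(self, level_hw):
        return sum(self.conv.c_in for _ in level_hw)


class SpatialAttention(nn.Module):
    """M_S: cross-level deformable aggregation at each level's own grid."""

    def __init__(self, channels, cfg: LSCConfig = None, rng=None):
        cfg = cfg or LSCConfig()
        self.cfg = cfg
        self.channels = channels
        k2 = 9
        self.offset_conv = nn.Conv2d(channels, 3 * k2, 3, zero_init=True)
        self.offset_conv.bias.data[2 * k2:] = _MOD_BIAS
        n_kernels = 1 if cfg.share_neighbor_kernels else 3
        self.kernels = [
            _DeformWeights(channels, channels, rng=rng,
                           identity=(n_kernels == 1 or k == 1))
            for k in range(n_kernels)
        ]
        # norm_in feeds the offset/modulation predictor a normalized view
        # of the level — raw FPN magnitudes are unbounded and otherwise
        # drive the learned offsets out of the feature map (dead sampling);
        # norm stabilizes the aggregated output, as in the dynamic-head
        # design this follows
        self.norm_in = nn.GroupNorm(channels)
        self.norm = nn.GroupNorm(channels)

    def _kernel(self, role):
        # role: 0 = finer neighbor, 1 = self, 2 = coarser neighbor
        return self.kernels[0] if len(self.kernels) == 1 else self.kernels[role]

    def aggregate_level(self, pyramid: PyramidFeatures, i: int):
        """Mean of deformable convs over the available members at level i.

        The offsets/modulation are predicted from level i itself; the sum
        of per-member deformable convs with shared offsets is computed as
        one deformable conv over the channel-concatenated members.
        """
        levels = pyramid.levels
        L = len(levels)
        x = levels[i]
        hw = x.shape[-2:]
        branch = self.offset_conv(self.norm_in(x))
        offsets = nn.slice_axis(branch, 1, 0, 18)
        modulation = nn.sigmoid(nn.slice_axis(branch, 1, 18, 27))
        members, weights, biases = [], [], []
        for j, role in ((i - 1, 0), (i, 1), (i + 1, 2)):
            if j < 0 or j >= L:
                continue
            src = levels[j]
            if src.shape[-2:] != hw:
                src = nn.resize_bilinear(src, hw)
            k = self._kernel(role)
            members.append(src)
            weights.append(k.weight)
            biases.append(k.bias)
        stacked = members[0] if len(members) == 1 else nn.concat(members, axis=1)
        w_cat = weights[0] if len(weights) == 1 else nn.concat(weights, axis=1)
        b_sum = biases[0]
        for b in biases[1:]:
            b_sum = nn.add(b_sum, b)
        agg = nn.deformable_conv2d(stacked, w_cat, b_sum, offsets,
                                   modulation, 1, 1)
        return nn.mul(agg, 1.0 / len(members))

    def forward(self, pyramid: PyramidFeatures) -> PyramidFeatures:
        out = [self.norm(self.aggregate_level(pyramid, i))
               for i in range(len(pyramid.levels))]
        return PyramidFeatures(out, pyramid.strides)

    def macs(self, level_hw):
        c = self.channels
        total = 0
        L = len(level_hw)
        for i, (h, w) in enumerate(level_hw):
            members = sum(1 for j in (i - 1, i, i + 1) if 0 <= j < L)
            total += self.offset_conv.macs(h, w)
            total += members * 9 * c * c * h * w
        return total


class _DeformWeights(nn.Module):
    """Weights of one 3x3 deformable conv used inside M_S.

    The self-role kernel starts at an identity (center-delta) kernel and
    the neighbor kernels at a down-scaled random init, so a fresh block
    initially passes its level through almost unchanged — an inserted
    block should not destroy the signal it wraps.
    """

    def __init__(self, c_in, c_out, rng=None, identity=False):
        if rng is None:
            w = np.zeros((c_out, c_in, 3, 3), dtype=np.float32)
        else:
            w = nn.he_normal(rng, (c_out, c_in, 3, 3), c_in * 9) * 0.1
            if identity and c_in == c_out:
                w[np.arange(c_out), np.arange(c_in), 1, 1] += 1.0
        self.weight = nn.Parameter(w)
        self.bias = nn.Parameter(np.zeros(c_out, dtype=np.float32))


class ChannelAttention(nn.Module):
    """M_C: dynamic per-channel piecewise-linear activation."""

    def __init__(self, channels, cfg: LSCConfig = None, rng=None):
        cfg = cfg or LSCConfig()
        self.cfg = cfg
        self.channels = channels
        hidden = max(channels // cfg.reduction, 4)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 4 * channels, rng=rng)

    def coefficients(self, pyramid: PyramidFeatures):
        """Pooled theta(.) -> per-channel (a1, a2, b1, b2)."""
        gaps = [nn.mean(x, axis=(2, 3)) for x in pyramid.levels]   # (N, C) each
        acc = gaps[0]
        for g in gaps[1:]:
            acc = nn.add(acc, g)
        pooled = nn.mul(acc, 1.0 / len(gaps))
        raw = self.fc2(nn.relu(self.fc1(pooled)))                  # (N, 4C)
        norm = nn.sub(nn.mul(nn.sigmoid(raw), 2.0), 1.0)           # [-1, 1]
        C = self.channels
        sg, ig = self.cfg.slope_gain, self.cfg.intercept_gain
        a1 = nn.add(nn.mul(nn.slice_axis(norm, 1, 0, C), sg), 1.0)
        a2 = nn.mul(nn.slice_axis(norm, 1, C, 2 * C), sg)
        b1 = nn.mul(nn.slice_axis(norm, 1, 2 * C, 3 * C), ig)
        b2 = nn.mul(nn.slice_axis(norm, 1, 3 * C, 4 * C), ig)
        return a1, a2, b1, b2

    @staticmethod
    def apply_coefficients(x, a1, a2, b1, b2):
        """max(a1*x + b1, a2*x + b2), coefficients (N, C) broadcast over space."""
        n, c = a1.shape[0], a1.shape[1]
        r = lambda t: nn.reshape(t, (n, c, 1, 1))
        return nn.maximum(nn.add(nn.mul(x, r(a1)), r(b1)),
                          nn.add(nn.mul(x, r(a2)), r(b2)))

    def forward(self, pyramid: PyramidFeatures) -> PyramidFeatures:
        a1, a2, b1, b2 = self.coefficients(pyramid)
        levels = [self.apply_coefficients(x, a1, a2, b1, b2)
                  for x in pyramid.levels]
        return PyramidFeatures(levels, pyramid.strides)

    def macs(self, level_hw):
        return self.fc1.macs() + self.fc2.macs()


class LSCBlock(nn.Module):
    def __init__(self, channels, cfg: LSCConfig = None, rng=None):
        cfg = cfg or LSCConfig()
        self.scale = ScaleAttention(channels, cfg, rng=rng)
        self.spatial = SpatialAttention(channels, cfg, rng=rng)
        self.channel = ChannelAttention(channels, cfg, rng=rng)

    def forward(self, pyramid: PyramidFeatures) -> PyramidFeatures:
        return self.channel(self.spatial(self.scale(pyramid)))

    def macs(self, level_hw):
        return (self.scale.macs(level_hw) + self.spatial.macs(level_hw)
                + self.channel.macs(level_hw))


class LSCStack(nn.Module):
    """n_blocks repetitions of M_L -> M_S -> M_C; shape-neutral."""

    def __init__(self, channels, cfg: LSCConfig = None, rng=None):
        cfg = cfg or LSCConfig()
        if cfg.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        self.cfg = cfg
        self.blocks = [LSCBlock(channels, cfg, rng=rng) for _ in range(cfg.n_blocks)]

    def forward(self, pyramid: PyramidFeatures) -> PyramidFeatures:
        for block in self.blocks:
            pyramid = block(pyramid)
        return pyramid

    def macs(self, level_hw):
        return sum(block.macs(level_hw) for block in self.blocks)


def scale_attention(module: ScaleAttention, pyramid):
    return module(pyramid)


def spatial_attention(module: SpatialAttention, pyramid):
    return module(pyramid)


def channel_attention(module: ChannelAttention, pyramid):
    return module(pyramid)


def lsc_stack(module: LSCStack, pyramid):
    return module(pyramid)
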