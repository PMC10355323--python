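"""ResNet50 feature extractor with modulated deformable 3x3 convolutions.

Stages C3-C5 replace every 3x3 convolution inside their bottleneck blocks
with a modulated deformable convolution: an auxiliary 3x3 "offset branch"
over the same input predicts 2*3*3 per-location (dy, dx) displacements
plus 3*3 modulation coefficients squashed to [0, 1] by a sigmoid.  The
offset branch is zero-initialized (offsets 0) with the modulation bias at
``logit(0.9999)`` so the network starts from (numerically) plain-conv
behavior.

Normalization is GroupNorm: training here runs at batch size 2, where
batch statistics are unusable, and the affine parameter count matches
BatchNorm exactly so complexity accounting is unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import nn

# ResNet50 stage layout: (n_blocks, base mid width); output width = 4 * mid.
_STAGES = ((3, 64), (4, 128), (6, 256), (3, 512))

_MOD_BIAS = math.log(0.9999 / (1 - 0.9999))  # sigmoid^-1(0.9999)


@dataclass
class StageOutputs:
    """C2..C5 feature maps at strides 4/8/16/32, widths 256/512/1024/2048."""

    C2: nn.Tensor
    C3: nn.Tensor
    C4: nn.Tensor
    C5: nn.Tensor

    def as_list(self) -> List[nn.Tensor]:
        return [self.C2, self.C3, self.C4, self.C5]


class DeformConv2d(nn.Module):
    """Modulated deformable KxK convolution with its offset branch.

    One offset set (2*K*K values) is shared across channels per location;
    modulation has K*K coefficients in [0, 1] per location.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, padding=1, bias=True,
                 rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        k2 = kernel * kernel
        self.offset_conv = nn.Conv2d(c_in, 3 * k2, kernel, stride=stride,
                                     padding=padding, zero_init=True)
        self.offset_conv.bias.data[2 * k2:] = _MOD_BIAS
        if rng is None:
            w = np.zeros((c_out, c_in, kernel, kernel), dtype=np.float32)
        else:
            w = nn.he_normal(rng, (c_out, c_in, kernel, kernel),
                             c_in * kernel * kernel)
        self.weight = nn.Parameter(w)
        self.bias = nn.Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        k2 = self.kernel * self.kernel
        branch = self.offset_conv(x)
        offsets = nn.slice_axis(branch, 1, 0, 2 * k2)
        modulation = nn.sigmoid(nn.slice_axis(branch, 1, 2 * k2, 3 * k2))
        return nn.deformable_conv2d(x, self.weight, self.bias, offsets,
                                    modulation, self.stride, self.padding)

    def macs(self, out_h, out_w):
        k2 = self.kernel * self.kernel
        main = k2 * self.c_in * self.c_out * out_h * out_w
        branch = k2 * self.c_in * 3 * k2 * out_h * out_w
        return main + branch

    def out_hw(self, h, w):
        return self.offset_conv.out_hw(h, w)


def deformable_conv(x, weight, bias, offsets, modulation, stride=1, padding=1):
    """Functional modulated deformable convolution (see nn.deformable_conv2d)."""
    return nn.deformable_conv2d(x, weight, bias, offsets, modulation,
                                stride, padding)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, c_in, mid, stride=1, dcn=False, rng=None):
        out = mid * self.expansion
        self.conv1 = nn.Conv2d(c_in, mid, 1, bias=False, rng=rng)
        self.gn1 = nn.GroupNorm(mid)
        if dcn:
            self.conv2 = DeformConv2d(mid, mid, 3, stride=stride, padding=1,
                                      bias=False, rng=rng)
        else:
            self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1,
                                   bias=False, rng=rng)
        self.gn2 = nn.GroupNorm(mid)
        self.conv3 = nn.Conv2d(mid, out, 1, bias=False, rng=rng)
        self.gn3 = nn.GroupNorm(out)
        self.downsample = None
        if stride != 1 or c_in != out:
            self.downsample = nn.Conv2d(c_in, out, 1, stride=stride,
                                        bias=False, rng=rng)
            self.gn_ds = nn.GroupNorm(out)

    def forward(self, x):
        identity = x
        y = nn.relu(self.gn1(self.conv1(x)))
        y = nn.relu(self.gn2(self.conv2(y)))
        y = self.gn3(self.conv3(y))
        if self.downsample is not None:
            identity = self.gn_ds(self.downsample(x))
        return nn.relu(nn.add(y, identity))

    def macs(self, h, w):
        h2, w2 = self.conv2.out_hw(h, w)
        total = self.conv1.macs(h, w) + self.conv2.macs(h2, w2) + self.conv3.macs(h2, w2)
        if self.downsample is not None:
            total += self.downsample.macs(h2, w2)
        return total, (h2, w2)


class ResNet50DCN(nn.Module):
    """ResNet50 trunk; stages C3-C5 optionally use deformable 3x3 convs.

    ``width_mult`` scales every channel width (0.25 gives the reduced
    desk-scale variant); ``use_dcn`` toggles the deformable convolutions.
    """

    def __init__(self, width_mult=1.0, use_dcn=True, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.width_mult = width_mult
        self.use_dcn = use_dcn
        ch = lambda c: max(int(round(c * width_mult)), 8)
        stem = ch(64)
        self.conv1 = nn.Conv2d(3, stem, 7, stride=2, padding=3, bias=False, rng=rng)
        self.gn1 = nn.GroupNorm(stem)
        self.stage_widths: List[int] = []
        self.stages: List[List[Bottleneck]] = []
        c_in = stem
        for i, (n_blocks, base_mid) in enumerate(_STAGES):
            mid = ch(base_mid)
            dcn = use_dcn and i >= 1  # stages producing C3, C4, C5
            blocks = []
            for j in range(n_blocks):
                stride = 2 if (j == 0 and i > 0) else 1
                blocks.append(Bottleneck(c_in, mid, stride=stride, dcn=dcn, rng=rng))
                c_in = mid * Bottleneck.expansion
            self.stages.append(blocks)
            self.stage_widths.append(c_in)

    def forward(self, x) -> StageOutputs:
        x = nn.astensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        y = nn.relu(self.gn1(self.conv1(x)))
        y = nn.maxpool2d(y, 3, 2, 1)
        outs = []
        for blocks in self.stages:
            for block in blocks:
                y = block(y)
            outs.append(y)
        return StageOutputs(*outs)

    def extract_stages(self, images) -> StageOutputs:
        return self.forward(images)

    def macs(self, h, w):
        h1, w1 = self.conv1.out_hw(h, w)
        total = self.conv1.macs(h1, w1)
        h2, w2 = (h1 + 2 * 1 - 3) // 2 + 1, (w1 + 2 * 1 - 3) // 2 + 1  # maxpool
        cur = (h2, w2)
        stage_hw = []
        for blocks in self.stages:
            for block in blocks:
                m, cur = block.macs(*cur)
                total += m
            stage_hw.append(cur)
        return total, stage_hw


def extract_stages(backbone: ResNet50DCN, images) -> StageOutputs:
    """Run the trunk on an image batch (spatial dims must be divisible by 4)."""
    return backbone.extract_stages(images)
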