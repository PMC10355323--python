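"""Decoupled anchor-free prediction head.

A classification tower and a parallel regression tower (4 x 3x3 conv +
GroupNorm + ReLU each, parameters shared across all pyramid levels) feed
three predictors: class logits, four box-edge distances (left, top,
right, bottom, in input pixels) and a center-offset ("centerness")
logit placed on the regression tower.  Distances come out of
``exp(scale_l * raw) * stride_l`` with a per-level learnable scalar, so
they are always non-negative and start at one stride — a sane box prior
at every level.  At inference the fused score is
``sigmoid(cls) * sigmoid(centerness)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from . import nn
from .data_io import Box
from .fpn_lsc import PyramidFeatures

# dense-detector prior: initial P(object) at every location
PRIOR_PROB = 0.01


@dataclass
class HeadOutputs:
    """Per-level predictions; distances are already exp-activated (pixels)."""

    cls_logits: List[nn.Tensor]      # (N, n_classes, H, W) each
    box_deltas: List[nn.Tensor]      # (N, 4, H, W), l/t/r/b distances >= 0
    center_logits: List[nn.Tensor]   # (N, 1, H, W)
    strides: Sequence[int]           # deltas are exp(scale*raw)*stride, pixels


@dataclass(frozen=True)
class Location:
    """One head location and its anchor point on the input image."""

    level: int
    row: int
    col: int
    stride: int

    @property
    def point(self) -> Tuple[float, float]:
        return (self.stride * (self.col + 0.5), self.stride * (self.row + 0.5))


def level_locations(h: int, w: int, stride: int) -> np.ndarray:
    """(h*w, 2) array of (x, y) anchor points, row-major."""
    ys = (np.arange(h) + 0.5) * stride
    xs = (np.arange(w) + 0.5) * stride
    X, Y = np.meshgrid(xs, ys)
    return np.stack([X.ravel(), Y.ravel()], axis=1)


class _Tower(nn.Module):
    def __init__(self, channels, n_convs, rng):
        self.convs = [nn.Conv2d(channels, channels, 3, bias=True, rng=rng)
                      for _ in range(n_convs)]
        self.norms = [nn.GroupNorm(channels) for _ in range(n_convs)]

    def forward(self, x):
        for conv, norm in zip(self.convs, self.norms):
            x = nn.relu(norm(conv(x)))
        return x

    def forward_masked(self, x, mask, area):
        """Tower over a zero-padded level batch with mask-corrected norm."""
        for conv, norm in zip(self.convs, self.norms):
            x = conv(x)
            x = nn.group_norm_masked(x, norm.weight, norm.bias, norm.groups,
                                     mask, area, norm.eps)
            x = nn.relu(x)
        return x

    def macs(self, h, w):
        return sum(conv.macs(h, w) for conv in self.convs)


class FCOSHead(nn.Module):
    def __init__(self, channels=256, num_classes=1, n_convs=4, n_levels=5,
                 rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.channels = channels
        self.num_classes = num_classes
        self.cls_tower = _Tower(channels, n_convs, rng)
        self.reg_tower = _Tower(channels, n_convs, rng)
        self.cls_pred = nn.Conv2d(channels, num_classes, 3, rng=rng,
                                  bias_init=-math.log((1 - PRIOR_PROB) / PRIOR_PROB))
        self.reg_pred = nn.Conv2d(channels, 4, 3, rng=rng)
        self.ctr_pred = nn.Conv2d(channels, 1, 3, rng=rng)
        self.scales = [nn.Scale(1.0) for _ in range(n_levels)]

    def forward(self, pyramid: PyramidFeatures, level_batched=True) -> HeadOutputs:
        if level_batched and len(pyramid.levels) > 1:
            return self._forward_batched(pyramid)
        cls_logits, box_deltas, center_logits = [], [], []
        for lvl, x in enumerate(pyramid.levels):
            c = self.cls_tower(x)
            r = self.reg_tower(x)
            cls_logits.append(self.cls_pred(c))
            raw = self.reg_pred(r)
            box_deltas.append(nn.mul(nn.exp(self.scales[lvl](raw)),
                                     float(pyramid.strides[lvl])))
            center_logits.append(self.ctr_pred(r))
        return HeadOutputs(cls_logits, box_deltas, center_logits,
                           pyramid.strides)

    def _forward_batched(self, pyramid: PyramidFeatures) -> HeadOutputs:
        """Run all levels through the shared towers as one padded batch.

        Levels are zero-padded to the finest level's grid and stacked
        along the batch axis; because the towers' convolutions are
        'same'-padded and the masked group norm zeroes the padding, the
        result is numerically identical to per-level application.
        """
        levels = pyramid.levels
        N = levels[0].shape[0]
        Hm, Wm = levels[0].shape[-2:]
        hw = [t.shape[-2:] for t in levels]
        parts = [t if t.shape[-2:] == (Hm, Wm)
                 else nn.pad2d(t, (0, Hm - t.shape[-2], 0, Wm - t.shape[-1]))
                 for t in levels]
        xb = nn.concat(parts, axis=0)                     # (L*N, C, Hm, Wm)
        L = len(levels)
        dt = xb.dtype
        mask = np.zeros((L * N, 1, Hm, Wm), dtype=dt)
        area = np.empty(L * N, dtype=dt)
        for l, (h, w) in enumerate(hw):
            mask[l * N:(l + 1) * N, :, :h, :w] = 1.0
            area[l * N:(l + 1) * N] = h * w
        c = self.cls_tower.forward_masked(xb, mask, area)
        r = self.reg_tower.forward_masked(xb, mask, area)
        cls_b = self.cls_pred(c)
        raw_b = self.reg_pred(r)
        ctr_b = self.ctr_pred(r)

        def crop(t, l):
            h, w = hw[l]
            t = nn.slice_axis(t, 0, l * N, (l + 1) * N)
            t = nn.slice_axis(t, 2, 0, h)
            return nn.slice_axis(t, 3, 0, w)

        cls_logits, box_deltas, center_logits = [], [], []
        for l in range(L):
            cls_logits.append(crop(cls_b, l))
            box_deltas.append(nn.mul(nn.exp(self.scales[l](crop(raw_b, l))),
                                     float(pyramid.strides[l])))
            center_logits.append(crop(ctr_b, l))
        return HeadOutputs(cls_logits, box_deltas, center_logits,
                           pyramid.strides)

    def macs(self, level_hw):
        total = 0
        for h, w in level_hw:
            total += self.cls_tower.macs(h, w) + self.reg_tower.macs(h, w)
            total += (self.cls_pred.macs(h, w) + self.reg_pred.macs(h, w)
                      + self.ctr_pred.macs(h, w))
        return total


def head_forward(head: FCOSHead, pyramid: PyramidFeatures) -> HeadOutputs:
    return head(pyramid)


def decode_level(deltas: np.ndarray, points: np.ndarray) -> np.ndarray:
    """(S, 4) l/t/r/b distances + (S, 2) points -> (S, 4) corner boxes."""
    l, t, r, b = deltas.T
    x, y = points.T
    return np.stack([x - l, y - t, x + r, y + b], axis=1)


def decode_boxes(outputs: HeadOutputs, image_size=None, batch_index=0):
    """Decode one image's predictions into (boxes, scores, labels, levels).

    Score fusion: s = sigmoid(cls_logit) * sigmoid(center_logit).
    Boxes are clipped to the image when ``image_size`` (W, H) is given.
    """
    all_boxes, all_scores, all_labels, all_levels = [], [], [], []
    for lvl, stride in enumerate(outputs.strides):
        cls = outputs.cls_logits[lvl].data[batch_index]
        ctr = outputs.center_logits[lvl].data[batch_index]
        dlt = outputs.box_deltas[lvl].data[batch_index]
        n_cls, h, w = cls.shape
        pts = level_locations(h, w, stride)
        boxes = decode_level(dlt.reshape(4, -1).T, pts)
        if image_size is not None:
            W, H = image_size
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, W)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, H)
        probs = _sigmoid(cls.reshape(n_cls, -1)) * _sigmoid(ctr.reshape(1, -1))
        labels = probs.argmax(axis=0)
        scores = probs.max(axis=0)
        all_boxes.append(boxes)
        all_scores.append(scores)
        all_labels.append(labels)
        all_levels.append(np.full(len(scores), lvl))
    return (np.concatenate(all_boxes), np.concatenate(all_scores),
            np.concatenate(all_labels), np.concatenate(all_levels))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))
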