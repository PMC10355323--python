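"""Configuration blocks for the detector, training, inference and data.

Every symbol the assignment/loss functions use (mu, beta, gamma, k, b,
lambda, focal alpha/eta, candidate radius, regression ranges) and every
architecture knob (widths, LSC block count, hard-sigmoid form) lives
here, with the defaults the pipeline trains and evaluates under.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

# ImageNet-pretraining channel statistics (RGB, 0-255 scale).
IMAGENET_MEAN = (123.675, 116.28, 103.53)
IMAGENET_STD = (58.395, 57.12, 57.375)

# FCOS per-level regression ranges on max(l, t, r, b), in input pixels.
FCOS_REGRESS_RANGES: Tuple[Tuple[float, float], ...] = (
    (-1.0, 64.0), (64.0, 128.0), (128.0, 256.0), (256.0, 512.0), (512.0, 1e8),
)


@dataclass
class LSCConfig:
    """Scale/space/channel attention stack."""

    n_blocks: int = 3
    share_neighbor_kernels: bool = False
    reduction: int = 4
    hard_sigmoid_offset: float = 3.0
    hard_sigmoid_divisor: float = 6.0
    # residual gains applied to the normalized channel coefficients
    slope_gain: float = 0.5
    intercept_gain: float = 0.5


@dataclass
class ModelConfig:
    num_classes: int = 1
    width_mult: float = 1.0
    fpn_channels: int = 256
    use_dcn: bool = True
    use_lsc: bool = True
    lsc: LSCConfig = field(default_factory=LSCConfig)
    head_stacked_convs: int = 4
    strides: Tuple[int, ...] = (8, 16, 32, 64, 128)
    seed: int = 0


@dataclass
class AssignConfig:
    """Dual-weighting label assignment (w_pos / w_neg)."""

    mu: float = 5.0
    beta: float = 2.0
    gamma: float = 2.0
    iou_lo: float = 0.5
    iou_hi: float = 0.95
    candidate_radius: float = 1.5  # in units of level stride
    regress_ranges: Tuple[Tuple[float, float], ...] = FCOS_REGRESS_RANGES
    use_fused_score: bool = True  # s = cls prob * centerness prob

    @property
    def k_neg(self) -> float:
        # unique line through (iou_lo, 1) and (iou_hi, 0): P = -k*iou + b
        return 1.0 / (self.iou_hi - self.iou_lo)

    @property
    def b_neg(self) -> float:
        return self.iou_hi / (self.iou_hi - self.iou_lo)


@dataclass
class LossConfig:
    lambda_reg: float = 1.0
    focal_alpha: float = 0.25
    focal_eta: float = 2.0
    eps: float = 1e-6
    dual_weighting: bool = True  # False -> plain-FCOS loss (ablation baseline)


@dataclass
class TrainConfig:
    base_lr: float = 0.00125
    warmup_start_lr: float = 0.001
    warmup_iters: int = 1000
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 12
    step_epochs: Tuple[int, ...] = (8, 11)
    step_factor: float = 0.1
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.warmup_start_lr > self.base_lr:
            raise ValueError("warmup_start_lr must not exceed base_lr")
        steps = tuple(self.step_epochs)
        if list(steps) != sorted(set(steps)) or (steps and steps[-1] >= self.epochs):
            raise ValueError("step_epochs must be strictly increasing and < epochs")


@dataclass
class InferConfig:
    score_threshold: float = 0.4
    pre_nms_top_k: int = 1000
    nms_iou: float = 0.6
    max_detections: int = 100

    def __post_init__(self):
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must lie in (0, 1)")


@dataclass
class PreprocessConfig:
    target_size: Tuple[int, int] = (600, 400)  # (width, height)
    mean: Tuple[float, float, float] = IMAGENET_MEAN
    std: Tuple[float, float, float] = IMAGENET_STD
    pad_divisor: int = 32
    flip_prob: float = 0.5


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, list):
        return [_to_dict(v) for v in obj]
    return obj


def save_yaml(path, **blocks):
    with open(path, "w") as fh:
        yaml.safe_dump({k: _to_dict(v) for k, v in blocks.items()}, fh,
                       sort_keys=False)


_BLOCKS = {
    "model": ModelConfig,
    "lsc": LSCConfig,
    "assign": AssignConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "infer": InferConfig,
    "preprocess": PreprocessConfig,
}


def _from_dict(cls, d):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) or f.name == "lsc":
            v = _from_dict(LSCConfig, v)
        elif isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_yaml(path):
    """Load a YAML config file into dataclass blocks; missing blocks default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {name: _from_dict(cls, raw.get(name, {})) for name, cls in _BLOCKS.items()}
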