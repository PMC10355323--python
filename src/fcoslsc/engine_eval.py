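"""Training loop, inference post-processing, COCO-style evaluation and
the parameter/FLOP complexity counter.

The training schedule follows the published recipe: SGD with momentum
0.9 and weight decay 1e-4, base learning rate 0.00125 reached by a
linear warmup from 0.001 over the first 1000 iterations, batch size 2,
12 epochs with x0.1 drops after 8 and 11 completed epochs.

Evaluation is COCO-style: AP averaged over the IoU grid
[0.5:0.05:0.95] with 101-point interpolated precision, plus the
small/medium/large area breakdown and average recall.
"""

from __future__ import annotations

import csv
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .backbone_dcn import ResNet50DCN
from .config import (AssignConfig, InferConfig, LossConfig, ModelConfig,
                     PreprocessConfig, TrainConfig)
from .data_io import Box, ImageSample, preprocess
from .dense_head import FCOSHead, HeadOutputs, decode_level, level_locations
from .dw_assignment_loss import LossReport, fcos_baseline_loss, total_loss
from .fpn_lsc import FPN, LSCStack, PyramidFeatures
from .synthetic_orchard import SceneConfig, render_in_memory

IOU_THRESHOLDS = np.arange(0.5, 1.0, 0.05).round(2)  # 10 thresholds
AREA_RANGES = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, float("inf")),
}


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

class FCOSLSC(nn.Module):
    """Backbone (optionally deformable) -> FPN -> optional LSC -> head."""

    def __init__(self, cfg: ModelConfig = None):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = ResNet50DCN(cfg.width_mult, use_dcn=cfg.use_dcn, rng=rng)
        self.fpn = FPN(self.backbone.stage_widths[1:], cfg.fpn_channels, rng=rng)
        self.lsc = (LSCStack(cfg.fpn_channels, cfg.lsc, rng=rng)
                    if cfg.use_lsc else None)
        self.head = FCOSHead(cfg.fpn_channels, cfg.num_classes,
                             cfg.head_stacked_convs, len(cfg.strides), rng=rng)

    def forward(self, images) -> HeadOutputs:
        stages = self.backbone(images)
        pyramid = self.fpn(stages)
        if self.lsc is not None:
            pyramid = self.lsc(pyramid)
        return self.head(pyramid)


def build_model(cfg: ModelConfig = None) -> FCOSLSC:
    return FCOSLSC(cfg)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

def lr_at(iteration: int, epoch_length: int, cfg: TrainConfig = None) -> float:
    """Warmup then stepped schedule.

    Linear from ``warmup_start_lr`` to ``base_lr`` over ``warmup_iters``;
    multiplied by ``step_factor`` for every listed epoch already
    completed (e.g. steps (8, 11): x0.1 after 8 completed epochs, x0.01
    after 11).
    """
    cfg = cfg or TrainConfig()
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if iteration < cfg.warmup_iters:
        frac = iteration / cfg.warmup_iters
        lr = cfg.warmup_start_lr + frac * (cfg.base_lr - cfg.warmup_start_lr)
    else:
        lr = cfg.base_lr
    completed = iteration // max(epoch_length, 1)
    n_steps = sum(1 for e in cfg.step_epochs if completed >= e)
    return lr * cfg.step_factor ** n_steps


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stack_batch(samples: Sequence[ImageSample], pre_cfg, train_mode, rng):
    imgs, gts, labels = [], [], []
    for s in samples:
        out, _ = preprocess(s, train_mode, pre_cfg, rng)
        imgs.append(out.image.transpose(2, 0, 1))
        gts.append(out.boxes)
        labels.append(out.labels)
    return nn.Tensor(np.stack(imgs).astype(np.float32)), gts, labels


def train(model: FCOSLSC, train_samples: Sequence[ImageSample],
          train_cfg: TrainConfig = None, assign_cfg: AssignConfig = None,
          loss_cfg: LossConfig = None, pre_cfg: PreprocessConfig = None,
          max_iters: Optional[int] = None,
          lr_fn: Optional[Callable[[int], float]] = None,
          log_path=None) -> List[dict]:
    """Mini-batch SGD training; fully seeded; returns the per-iteration log.

    The log rows carry the four loss curves (total, positive-weight term,
    negative-weight term, regression term) plus the learning rate.
    Aborts with the offending iteration on a non-finite loss.
    """
    train_cfg = train_cfg or TrainConfig()
    assign_cfg = assign_cfg or AssignConfig()
    loss_cfg = loss_cfg or LossConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    if not train_samples:
        raise ValueError("training set is empty")
    n = len(train_samples)
    bs = train_cfg.batch_size
    epoch_length = math.ceil(n / bs)
    total_iters = (max_iters if max_iters is not None
                   else epoch_length * train_cfg.epochs)
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.SGD(model.parameters(), train_cfg.base_lr,
                 train_cfg.momentum, train_cfg.weight_decay)
    loss_fn = total_loss if loss_cfg.dual_weighting else fcos_baseline_loss

    log: List[dict] = []
    iteration = 0
    while iteration < total_iters:
        order = rng.permutation(n)
        for start in range(0, n, bs):
            if iteration >= total_iters:
                break
            batch = [train_samples[i] for i in order[start:start + bs]]
            images, gts, labels = _stack_batch(batch, pre_cfg, True, rng)
            outputs = model(images)
            try:
                report = loss_fn(outputs, gts, labels, assign_cfg, loss_cfg)
            except FloatingPointError as e:
                raise FloatingPointError(
                    f"aborting at iteration {iteration}: {e}") from e
            lr = (lr_fn(iteration) if lr_fn is not None
                  else lr_at(iteration, epoch_length, train_cfg))
            opt.zero_grad()
            report.total.backward()
            opt.step(lr)
            log.append({
                "iteration": iteration, "lr": lr,
                "L_total": report.total_value, "L_pos": report.l_pos,
                "L_neg": report.l_neg, "L_reg": report.l_reg,
                "L_cls": report.l_cls, "n_candidates": report.num_candidates,
            })
            iteration += 1
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
            writer.writeheader()
            writer.writerows(log)
    return log


# ---------------------------------------------------------------------------
# Inference post-processing
# ---------------------------------------------------------------------------

def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between (M, 4) and (K, 4) corner boxes."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.clip(area_a[:, None] + area_b[None] - inter, 1e-12, None)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        rest = order[~suppressed[order]]
        ious = box_iou_matrix(boxes[i][None], boxes[rest])[0]
        suppressed[rest[ious > iou_threshold]] = True
        suppressed[i] = False  # keep the anchor itself marked kept
    return np.asarray(keep, dtype=np.int64)


@dataclass
class Detections:
    boxes: np.ndarray        # (K, 4) corner boxes
    scores: np.ndarray
    labels: np.ndarray       # 1-based category ids

    def __len__(self):
        return len(self.scores)


def postprocess(outputs: HeadOutputs, infer_cfg: InferConfig = None,
                image_size=None, batch_index=0) -> Detections:
    """Score-threshold, per-level top-k, class-wise NMS, global top-k."""
    infer_cfg = infer_cfg or InferConfig()
    boxes_all, scores_all, labels_all = [], [], []
    for lvl, stride in enumerate(outputs.strides):
        cls = outputs.cls_logits[lvl].data[batch_index]
        ctr = outputs.center_logits[lvl].data[batch_index]
        dlt = outputs.box_deltas[lvl].data[batch_index]
        n_cls = cls.shape[0]
        s = (1 / (1 + np.exp(-cls.reshape(n_cls, -1)))
             * 1 / (1 + np.exp(-ctr.reshape(1, -1))))           # (ncls, S)
        cls_idx, loc_idx = np.nonzero(s >= infer_cfg.score_threshold)
        if len(loc_idx) == 0:
            continue
        sc = s[cls_idx, loc_idx]
        if len(sc) > infer_cfg.pre_nms_top_k:
            top = np.argsort(-sc, kind="stable")[:infer_cfg.pre_nms_top_k]
            cls_idx, loc_idx, sc = cls_idx[top], loc_idx[top], sc[top]
        h, w = cls.shape[-2:]
        pts = level_locations(h, w, stride)
        bx = decode_level(dlt.reshape(4, -1).T[loc_idx], pts[loc_idx])
        if image_size is not None:
            W, H = image_size
            bx[:, 0::2] = bx[:, 0::2].clip(0, W)
            bx[:, 1::2] = bx[:, 1::2].clip(0, H)
        boxes_all.append(bx)
        scores_all.append(sc)
        labels_all.append(cls_idx + 1)
    if not boxes_all:
        return Detections(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=np.int64))
    boxes = np.concatenate(boxes_all)
    scores = np.concatenate(scores_all)
    labels = np.concatenate(labels_all)
    keep_parts = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        kept = nms(boxes[idx], scores[idx], infer_cfg.nms_iou)
        keep_parts.append(idx[kept])
    keep = np.concatenate(keep_parts)
    keep = keep[np.argsort(-scores[keep], kind="stable")]
    keep = keep[:infer_cfg.max_detections]
    return Detections(boxes[keep], scores[keep], labels[keep])


def run_inference(model: FCOSLSC, samples: Sequence[ImageSample],
                  pre_cfg: PreprocessConfig = None,
                  infer_cfg: InferConfig = None):
    """Detect on each sample; returns (detections, preprocessed ground truth)."""
    pre_cfg = pre_cfg or PreprocessConfig()
    infer_cfg = infer_cfg or InferConfig()
    rng = np.random.default_rng(0)
    dets, gts = [], []
    for s in samples:
        out, _ = preprocess(s, False, pre_cfg, rng)
        with nn.no_grad():
            outputs = model(nn.Tensor(out.image.transpose(2, 0, 1)[None]))
        dets.append(postprocess(outputs, infer_cfg, (out.width, out.height)))
        gts.append(out)
    return dets, gts


# ---------------------------------------------------------------------------
# COCO-style evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """AP/AR (percent) at the COCO IoU grid with scale breakdown."""

    AP: float
    AP50: float
    AP75: float
    AP_s: float
    AP_m: float
    AP_l: float
    AR: float
    AR_s: float
    AR_m: float
    AR_l: float
    defined: bool = True

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("AP", "AP50", "AP75", "AP_s", "AP_m", "AP_l",
                 "AR", "AR_s", "AR_m", "AR_l")}


def _match_image(det_boxes, det_scores, gt_boxes, gt_ignore, tau):
    """COCO greedy matching at one IoU threshold.

    Returns (tp flags, det-ignored flags) in descending-score order.
    Each detection matches the unmatched ground truth of highest IoU
    >= tau, preferring non-ignored ground truths; a detection whose only
    match is ignored is itself ignored.
    """
    order = np.argsort(-det_scores, kind="stable")
    tp = np.zeros(len(order), dtype=bool)
    dt_ig = np.zeros(len(order), dtype=bool)
    matched = np.zeros(len(gt_boxes), dtype=bool)
    ious = box_iou_matrix(det_boxes[order], gt_boxes) if len(gt_boxes) else None
    for di in range(len(order)):
        best = _best_gt(ious[di] if ious is not None else None, matched,
                        gt_ignore, tau)
        if best >= 0:
            matched[best] = True
            if gt_ignore[best]:
                dt_ig[di] = True
            else:
                tp[di] = True
    return tp, dt_ig, order


def _best_gt(ious, matched, gt_ignore, tau):
    if ious is None:
        return -1
    best, best_iou = -1, tau - 1e-12
    for gi in range(len(ious)):
        if matched[gi]:
            continue
        # prefer any non-ignored match over ignored ones
        if best >= 0 and not gt_ignore[best] and gt_ignore[gi]:
            continue
        if ious[gi] < tau:
            continue
        if ious[gi] > best_iou or (best >= 0 and gt_ignore[best]
                                   and not gt_ignore[gi]):
            best, best_iou = gi, ious[gi]
    return best


def _ap_101(scores, tps, ignores, n_gt):
    """101-point interpolated AP from pooled detections."""
    if n_gt == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    tp = tps[order]
    ig = ignores[order]
    tp = tp[~ig]
    if len(tp) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    # monotone envelope
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    recall_grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, recall_grid, side="left")
    prec = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(prec.mean())


def evaluate(detections: Sequence[Detections],
             ground_truth: Sequence[ImageSample],
             max_detections: int = 100) -> EvalResult:
    """COCO-style AP/AR over a detection/ground-truth set (percent)."""
    classes = sorted({int(l) for s in ground_truth for l in s.labels}
                     | {int(l) for d in detections for l in d.labels})
    n_gt_total = sum(len(s.boxes) for s in ground_truth)
    n_det_total = sum(len(d) for d in detections)
    if n_gt_total == 0 and n_det_total == 0:
        nanv = float("nan")
        return EvalResult(*([nanv] * 10), defined=False)

    ap = {}
    ar = {}
    for range_name, (a_lo, a_hi) in AREA_RANGES.items():
        ap_taus = {t: [] for t in IOU_THRESHOLDS}
        ar_taus = {t: [] for t in IOU_THRESHOLDS}
        for c in classes:
            pooled = {t: {"scores": [], "tp": [], "ig": []} for t in IOU_THRESHOLDS}
            n_gt = 0
            recalls = {t: [0, 0] for t in IOU_THRESHOLDS}  # matched, total
            for det, gt in zip(detections, ground_truth):
                gmask = np.asarray([l == c for l in gt.labels], dtype=bool)
                gboxes = np.array([b.as_array() for b, m in zip(gt.boxes, gmask) if m]
                                  ).reshape(-1, 4)
                gareas = (gboxes[:, 2] - gboxes[:, 0]) * (gboxes[:, 3] - gboxes[:, 1])
                g_ig = ~((gareas >= a_lo) & (gareas < a_hi))
                dmask = det.labels == c
                dboxes = det.boxes[dmask][:max_detections]
                dscores = det.scores[dmask][:max_detections]
                dareas = (dboxes[:, 2] - dboxes[:, 0]) * (dboxes[:, 3] - dboxes[:, 1])
                n_gt += int((~g_ig).sum())
                for t in IOU_THRESHOLDS:
                    tp, dt_ig, order = _match_image(dboxes, dscores, gboxes, g_ig, t)
                    out_of_range = ~((dareas[order] >= a_lo) & (dareas[order] < a_hi))
                    dt_ig = dt_ig | (out_of_range & ~tp)
                    pooled[t]["scores"].append(dscores[order])
                    pooled[t]["tp"].append(tp)
                    pooled[t]["ig"].append(dt_ig)
                    recalls[t][0] += int(tp.sum())
            for t in IOU_THRESHOLDS:
                scores = np.concatenate(pooled[t]["scores"]) if pooled[t]["scores"] else np.zeros(0)
                tps = np.concatenate(pooled[t]["tp"]) if pooled[t]["tp"] else np.zeros(0, dtype=bool)
                igs = np.concatenate(pooled[t]["ig"]) if pooled[t]["ig"] else np.zeros(0, dtype=bool)
                ap_taus[t].append(_ap_101(scores, tps, igs, n_gt))
                ar_taus[t].append(recalls[t][0] / n_gt if n_gt else float("nan"))
        ap[range_name] = _nanmean([_nanmean(ap_taus[t]) for t in IOU_THRESHOLDS])
        ar[range_name] = _nanmean([_nanmean(ar_taus[t]) for t in IOU_THRESHOLDS])
        if range_name == "all":
            ap50 = _nanmean(ap_taus[IOU_THRESHOLDS[0]])
            ap75 = _nanmean(ap_taus[IOU_THRESHOLDS[5]])
    pct = lambda v: float(v) * 100.0
    return EvalResult(
        AP=pct(ap["all"]), AP50=pct(ap50), AP75=pct(ap75),
        AP_s=pct(ap["small"]), AP_m=pct(ap["medium"]), AP_l=pct(ap["large"]),
        AR=pct(ar["all"]), AR_s=pct(ar["small"]), AR_m=pct(ar["medium"]),
        AR_l=pct(ar["large"]))


def _nanmean(vals):
    vals = [v for v in np.atleast_1d(np.asarray(vals, dtype=np.float64))
            if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Complexity
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    """Trainable parameters and conv/linear multiply-accumulates.

    The FLOP figure counts one multiply-accumulate of convolution and
    fully connected layers as one floating point operation, evaluated
    symbolically at the stated input size (no padding to /32);
    normalization, activations and pooling are excluded.
    """

    param_count: int
    flops: int
    input_size: Tuple[int, int]
    breakdown: Dict[str, float] = field(default_factory=dict)

    @property
    def params_m(self) -> float:
        return self.param_count / 1e6

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9


def complexity(model: FCOSLSC, input_size=(600, 400)) -> ComplexityReport:
    """Symbolic parameter/FLOP count at ``input_size`` = (width, height)."""
    w, h = input_size
    backbone_macs, stage_hw = model.backbone.macs(h, w)
    fpn_macs, level_hw = model.fpn.macs(stage_hw[1:])
    lsc_macs = model.lsc.macs(level_hw) if model.lsc is not None else 0
    head_macs = model.head.macs(level_hw)
    total = backbone_macs + fpn_macs + lsc_macs + head_macs
    return ComplexityReport(
        param_count=model.param_count(), flops=int(total), input_size=tuple(input_size),
        breakdown={
            "backbone_g": backbone_macs / 1e9, "fpn_g": fpn_macs / 1e9,
            "lsc_g": lsc_macs / 1e9, "head_g": head_macs / 1e9,
            "backbone_params_m": model.backbone.param_count() / 1e6,
            "fpn_params_m": model.fpn.param_count() / 1e6,
            "lsc_params_m": (model.lsc.param_count() / 1e6
                             if model.lsc is not None else 0.0),
            "head_params_m": model.head.param_count() / 1e6,
        })


# ---------------------------------------------------------------------------
# Desk-scale end-to-end benchmark (easy synthetic scenes)
# ---------------------------------------------------------------------------

def smoke_scene_config(seed: int) -> SceneConfig:
    """Easy green-on-green scenes: high hue contrast, no occlusion."""
    return SceneConfig(
        image_size=(128, 128), fruit_count_range=(2, 4),
        fruit_radius_range=(10.0, 22.0), fruit_hue_offset=40.0,
        occluder_count_range=(0, 0), overlap_probability=0.0,
        lighting_mode="soft", blur_sigma_range=(0.0, 0.5),
        min_visible_fraction=0.25, seed=seed)


def smoke_model_config(seed: int, full: bool = True) -> ModelConfig:
    """Reduced desk-scale model: backbone width x0.25, 32-channel FPN/head."""
    cfg = ModelConfig(num_classes=1, width_mult=0.25, fpn_channels=32,
                      use_dcn=full, use_lsc=full, seed=seed)
    cfg.lsc.n_blocks = 1
    return cfg


def smoke_train_config(seed: int, iters: int = 300) -> TrainConfig:
    """From-scratch schedule for the 300-iteration benchmark."""
    return TrainConfig(base_lr=0.02, warmup_start_lr=0.004, warmup_iters=50,
                       momentum=0.9, weight_decay=0.0001, epochs=12,
                       step_epochs=(8, 11), batch_size=2, seed=seed)


def run_smoke_benchmark(seed: int, full: bool = True, n_train: int = 64,
                        n_val: int = 16, iters: int = 300,
                        eval_score_threshold: float = 0.05) -> dict:
    """Train on easy synthetic scenes and report loss drop and AP.

    ``full`` selects the complete model (deformable backbone + LSC +
    dual weighting); ``full=False`` is the plain-FCOS configuration used
    as the ablation reference.
    """
    scene = smoke_scene_config(seed)
    train_scenes = render_in_memory(scene, n_train)
    val_cfg = SceneConfig(**{**scene.__dict__, "seed": seed + 10_000})
    val_scenes = render_in_memory(val_cfg, n_val)

    model = FCOSLSC(smoke_model_config(seed, full))
    tcfg = smoke_train_config(seed, iters)
    pre = PreprocessConfig(target_size=(128, 128))
    loss_cfg = LossConfig(dual_weighting=full)

    def lr_fn(it):
        if it < tcfg.warmup_iters:
            lr = tcfg.warmup_start_lr + (it / tcfg.warmup_iters) * (
                tcfg.base_lr - tcfg.warmup_start_lr)
        else:
            lr = tcfg.base_lr
        return lr * (0.1 if it >= int(iters * 5 / 6) else 1.0)

    log = train(model, train_scenes, tcfg, AssignConfig(), loss_cfg, pre,
                max_iters=iters, lr_fn=lr_fn)
    totals = np.array([row["L_total"] for row in log])
    start = totals[:10].mean()
    end = totals[-10:].mean()
    drop = 1.0 - end / start

    dets, gts = run_inference(model, val_scenes, pre,
                              InferConfig(score_threshold=eval_score_threshold))
    result = evaluate(dets, gts)
    return {
        "seed": seed, "full": full, "loss_start": float(start),
        "loss_end": float(end), "loss_drop": float(drop),
        "AP": result.AP, "AP50": result.AP50, "log": log,
        "n_train": n_train, "n_val": n_val, "iters": iters,
    }
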