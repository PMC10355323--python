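"""Dual-weighting label assignment and the composite detection loss.

Candidate positives for a ground-truth box are the head locations that
(i) lie inside the box, (ii) lie within ``candidate_radius * stride`` of
its center and (iii) sit on a level whose regression range covers the
location's max edge distance; a location claimed by several boxes goes
to the smallest one.  Each candidate n receives

    w_pos = t * exp(mu * t),   t = s * IoU^beta

(consistency of the fused score s and the decoded box's IoU with its
ground truth) and

    w_neg = P_neg(IoU) * s^gamma,
    P_neg = 1 below IoU 0.5, 0 above 0.95, linear (-k*IoU + b) between,

so two candidates with equal w_pos but different IoU still receive
different supervision.  The loss is

    L_det = L_cls + lambda * L_reg
    L_cls = sum_n [-w_pos ln s_n - w_neg ln(1 - s_n)] + sum_m FL(s_m, 0)
    L_reg = sum_n  w_pos * (1 - GIoU(b_n, b'_n))

Per-image normalization: the w_pos-weighted sums (positive
classification term and regression term) are divided by the bare
sum of w_pos — a weighted mean — so the supervision scale is O(1)
even while every weight is still small early in training; the negative
terms (w_neg and the focal background sum) are divided by the number of
candidates, the standard dense-detector average factor.  w_pos is
detached (a pure supervision strength); w_neg stays inside the graph so
gradients flow through the live ranking signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .config import AssignConfig, LossConfig
from .data_io import Box
from .dense_head import HeadOutputs, level_locations

WeightingParams = AssignConfig  # alias: the weighting-function hyperparameters


# ---------------------------------------------------------------------------
# Elementary weighting / loss functions (scalar or ndarray)
# ---------------------------------------------------------------------------

def positive_weight(s, iou, params: AssignConfig = None):
    """w_pos = t * exp(mu * t) with t = s * IoU^beta; 0 at t = 0."""
    params = params or AssignConfig()
    t = np.asarray(s, dtype=np.float64) * np.asarray(iou, dtype=np.float64) ** params.beta
    return t * np.exp(params.mu * t)


def negative_probability(iou, params: AssignConfig = None):
    """P_neg: 1 below iou_lo, 0 above iou_hi, linear -k*iou + b between."""
    params = params or AssignConfig()
    val = params.b_neg - params.k_neg * np.asarray(iou, dtype=np.float64)
    return np.clip(val, 0.0, 1.0)


def negative_weight(s, iou, params: AssignConfig = None):
    """w_neg = P_neg(IoU) * s^gamma."""
    params = params or AssignConfig()
    return negative_probability(iou, params) * np.asarray(s, dtype=np.float64) ** params.gamma


def focal_loss(s, target: int, alpha=0.25, eta=2.0):
    """FL(s, 1) = -alpha (1-s)^eta ln s;  FL(s, 0) = -(1-alpha) s^eta ln(1-s)."""
    s = np.asarray(s, dtype=np.float64)
    if target == 1:
        return -alpha * (1.0 - s) ** eta * np.log(s)
    return -(1.0 - alpha) * s ** eta * np.log(1.0 - s)


def giou(b: Box, b2: Box) -> float:
    """Generalized IoU of two boxes."""
    iw = min(b.x_max, b2.x_max) - max(b.x_min, b2.x_min)
    ih = min(b.y_max, b2.y_max) - max(b.y_min, b2.y_min)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = b.area + b2.area - inter
    enc_w = max(b.x_max, b2.x_max) - min(b.x_min, b2.x_min)
    enc_h = max(b.y_max, b2.y_max) - min(b.y_min, b2.y_min)
    enclose = enc_w * enc_h
    return inter / union - (enclose - union) / enclose


def giou_loss(b: Box, b2: Box) -> float:
    """1 - GIoU, in [0, 2]; degenerate boxes are rejected by Box itself."""
    return 1.0 - giou(b, b2)


# ---------------------------------------------------------------------------
# Candidate bags
# ---------------------------------------------------------------------------

@dataclass
class CandidateBag:
    """Per-ground-truth set of candidate locations and their weights."""

    gt_index: int
    gt_box: Box
    member_indices: np.ndarray            # flat location indices
    scores: Optional[np.ndarray] = None   # fused score s per member
    boxes: Optional[np.ndarray] = None    # decoded (K, 4) corner boxes
    ious: Optional[np.ndarray] = None
    w_pos: Optional[np.ndarray] = None
    w_neg: Optional[np.ndarray] = None


def concat_locations(level_shapes: Sequence[Tuple[int, int]],
                     strides: Sequence[int],
                     regress_ranges: Sequence[Tuple[float, float]]):
    """Flatten per-level grids into (points, strides, ranges) arrays."""
    pts, sts, rgs = [], [], []
    for (h, w), stride, rng in zip(level_shapes, strides, regress_ranges):
        p = level_locations(h, w, stride)
        pts.append(p)
        sts.append(np.full(len(p), stride, dtype=np.float64))
        rgs.append(np.tile(np.asarray(rng, dtype=np.float64), (len(p), 1)))
    return np.concatenate(pts), np.concatenate(sts), np.concatenate(rgs)


def assign_locations(points: np.ndarray, strides: np.ndarray,
                     ranges: np.ndarray, gt_boxes: Sequence[Box],
                     params: AssignConfig = None) -> np.ndarray:
    """Per-location ground-truth index (-1 = non-candidate)."""
    params = params or AssignConfig()
    S = len(points)
    assign = np.full(S, -1, dtype=np.int64)
    if not gt_boxes:
        return assign
    best_area = np.full(S, np.inf)
    x, y = points[:, 0], points[:, 1]
    for g, box in enumerate(gt_boxes):
        l = x - box.x_min
        t = y - box.y_min
        r = box.x_max - x
        b = box.y_max - y
        inside = (l > 0) & (t > 0) & (r > 0) & (b > 0)
        maxreg = np.maximum(np.maximum(l, r), np.maximum(t, b))
        in_range = (maxreg >= ranges[:, 0]) & (maxreg <= ranges[:, 1])
        cx, cy = box.center
        near = np.hypot(x - cx, y - cy) <= params.candidate_radius * strides
        ok = inside & in_range & near
        better = ok & (box.area < best_area)
        assign[better] = g
        best_area[better] = box.area
    return assign


def build_candidate_bag(points, strides, ranges, gt_boxes,
                        params: AssignConfig = None,
                        scores=None, boxes=None) -> List[CandidateBag]:
    """Build one CandidateBag per ground truth (possibly empty).

    ``scores``/``boxes`` (fused score per location, decoded (S, 4) corner
    boxes) fill in the members' s, IoU, w_pos and w_neg when provided.
    """
    params = params or AssignConfig()
    assign = assign_locations(points, strides, ranges, gt_boxes, params)
    bags = []
    for g, gt in enumerate(gt_boxes):
        idx = np.nonzero(assign == g)[0]
        bag = CandidateBag(gt_index=g, gt_box=gt, member_indices=idx)
        if scores is not None and boxes is not None and len(idx):
            s = np.asarray(scores)[idx]
            bx = np.asarray(boxes)[idx]
            ious = np.array([box_iou_arr(b, gt) for b in bx])
            bag.scores, bag.boxes, bag.ious = s, bx, ious
            bag.w_pos = positive_weight(s, ious, params)
            bag.w_neg = negative_weight(s, ious, params)
        bags.append(bag)
    return bags


def box_iou_arr(b: np.ndarray, gt: Box) -> float:
    iw = min(b[2], gt.x_max) - max(b[0], gt.x_min)
    ih = min(b[3], gt.y_max) - max(b[1], gt.y_min)
    inter = max(iw, 0.0) * max(ih, 0.0)
    area = max(b[2] - b[0], 0.0) * max(b[3] - b[1], 0.0)
    return inter / max(area + gt.area - inter, 1e-12)


def classification_loss(bags: Sequence[CandidateBag],
                        non_candidate_scores: np.ndarray,
                        loss_cfg: LossConfig = None) -> float:
    """Eq.-style classification loss from pre-built bags (reference path).

    Sum over bag members of -w_pos ln s - w_neg ln(1-s), plus focal loss
    against label 0 over the non-candidate scores.  Raises on non-finite
    scores.
    """
    loss_cfg = loss_cfg or LossConfig()
    total = 0.0
    for bag in bags:
        if bag.scores is None or len(bag.member_indices) == 0:
            continue
        if not np.all(np.isfinite(bag.scores)):
            bad = bag.member_indices[~np.isfinite(bag.scores)][0]
            raise FloatingPointError(f"non-finite score at location {bad}")
        s = np.clip(bag.scores, loss_cfg.eps, 1 - loss_cfg.eps)
        total += float(np.sum(-bag.w_pos * np.log(s) - bag.w_neg * np.log(1 - s)))
    m = np.asarray(non_candidate_scores, dtype=np.float64)
    if m.size:
        if not np.all(np.isfinite(m)):
            raise FloatingPointError(
                f"non-finite score at non-candidate location {int(np.nonzero(~np.isfinite(m))[0][0])}")
        m = np.clip(m, loss_cfg.eps, 1 - loss_cfg.eps)
        total += float(np.sum(focal_loss(m, 0, loss_cfg.focal_alpha, loss_cfg.focal_eta)))
    return total


# ---------------------------------------------------------------------------
# Training losses (autograd path)
# ---------------------------------------------------------------------------

@dataclass
class LossReport:
    """Loss value plus the component curves (total, w_pos, w_neg, reg)."""

    total: nn.Tensor
    total_value: float
    l_cls: float
    l_reg: float
    l_pos: float      # positive-weight classification term
    l_neg: float      # negative-weight classification term
    num_candidates: int
    sum_wpos: float


def _flatten_image(outputs: HeadOutputs, n: int):
    """One image's predictions as flat tensors (+ location geometry)."""
    cls_parts, ctr_parts, dlt_parts, shapes = [], [], [], []
    for lvl in range(len(outputs.strides)):
        c = outputs.cls_logits[lvl]
        shapes.append(c.shape[-2:])
        ncls = c.shape[1]
        s_l = c.shape[-2] * c.shape[-1]
        cls_parts.append(nn.reshape(nn.slice_axis(c, 0, n, n + 1), (ncls, s_l)))
        ctr_parts.append(nn.reshape(nn.slice_axis(outputs.center_logits[lvl], 0, n, n + 1), (1, s_l)))
        dlt_parts.append(nn.reshape(nn.slice_axis(outputs.box_deltas[lvl], 0, n, n + 1), (4, s_l)))
    cls = nn.concat(cls_parts, axis=1)
    ctr = nn.concat(ctr_parts, axis=1)
    dlt = nn.concat(dlt_parts, axis=1)
    return cls, ctr, dlt, shapes


def _giou_tensor(bx0, by0, bx1, by1, gt: np.ndarray):
    """GIoU between decoded candidate boxes (tensors) and constant GT boxes."""
    gx0, gy0, gx1, gy1 = (nn.Tensor(gt[:, i]) for i in range(4))
    iw = nn.relu(nn.sub(nn.minimum(bx1, gx1), nn.maximum(bx0, gx0)))
    ih = nn.relu(nn.sub(nn.minimum(by1, gy1), nn.maximum(by0, gy0)))
    inter = nn.mul(iw, ih)
    area_b = nn.mul(nn.sub(bx1, bx0), nn.sub(by1, by0))
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = nn.add(nn.sub(area_b, inter), area_g)
    ew = nn.sub(nn.maximum(bx1, gx1), nn.minimum(bx0, gx0))
    eh = nn.sub(nn.maximum(by1, gy1), nn.minimum(by0, gy0))
    enclose = nn.mul(ew, eh)
    iou = nn.div(inter, union)
    g = nn.sub(iou, nn.div(nn.sub(enclose, union), enclose))
    return iou, g


def total_loss(outputs: HeadOutputs, gt_per_image: Sequence[Sequence[Box]],
               labels_per_image: Sequence[Sequence[int]] = None,
               assign_cfg: AssignConfig = None,
               loss_cfg: LossConfig = None) -> LossReport:
    """Dual-weighting detection loss over a batch (graph-building)."""
    assign_cfg = assign_cfg or AssignConfig()
    loss_cfg = loss_cfg or LossConfig()
    eps = loss_cfg.eps
    batch = outputs.cls_logits[0].shape[0]
    shapes = [c.shape[-2:] for c in outputs.cls_logits]
    points, strides, ranges = concat_locations(shapes, outputs.strides,
                                               assign_cfg.regress_ranges)
    S = len(points)

    total = None
    tot_pos = tot_neg = tot_cls = tot_reg = 0.0
    n_cand = 0
    wpos_sum = 0.0
    for n in range(batch):
        gts = list(gt_per_image[n])
        gt_cls = (list(labels_per_image[n]) if labels_per_image is not None
                  else [1] * len(gts))
        cls, ctr, dlt, _ = _flatten_image(outputs, n)
        ncls = cls.shape[0]
        prob = nn.sigmoid(cls)
        if assign_cfg.use_fused_score:
            s_map = nn.mul(prob, nn.sigmoid(ctr))          # (ncls, S)
        else:
            s_map = prob
        s_flat = nn.reshape(s_map, (ncls * S,))
        zc_flat = nn.reshape(cls, (ncls * S,))
        zt_flat = nn.reshape(ctr, (S,))

        assign = assign_locations(points, strides, ranges, gts, assign_cfg)
        cand = np.nonzero(assign >= 0)[0]
        neg_mask = np.ones(ncls * S, dtype=np.float64)

        img_pos = None
        img_reg = None
        n_cand_img = max(len(cand), 1)
        if len(cand):
            gidx = assign[cand]
            cls_idx = np.array([gt_cls[g] - 1 for g in gidx])  # category ids 1-based
            flat_idx = cls_idx * S + cand
            neg_mask[flat_idx] = 0.0
            s_c = nn.take(s_flat, flat_idx)
            # stable -ln s from the logits: ln sigma(z) = -softplus(-z)
            neg_ln_s = nn.softplus(-nn.take(zc_flat, flat_idx))
            if assign_cfg.use_fused_score:
                neg_ln_s = nn.add(neg_ln_s, nn.softplus(-nn.take(zt_flat, cand)))
            d_c = nn.take(dlt, cand, axis=1)                   # (4, K)
            px, py = points[cand, 0], points[cand, 1]
            bx0 = nn.sub(px, nn.slice_axis(d_c, 0, 0, 1).reshape(-1))
            by0 = nn.sub(py, nn.slice_axis(d_c, 0, 1, 2).reshape(-1))
            bx1 = nn.add(px, nn.slice_axis(d_c, 0, 2, 3).reshape(-1))
            by1 = nn.add(py, nn.slice_axis(d_c, 0, 3, 4).reshape(-1))
            gt_arr = np.array([gts[g].as_array() for g in gidx])
            iou_t, giou_t = _giou_tensor(bx0, by0, bx1, by1, gt_arr)

            # w_pos: detached supervision strength
            w_pos = positive_weight(s_c.data, np.clip(iou_t.data, 0, 1),
                                    assign_cfg)
            wpos_np = w_pos.astype(np.float64)
            norm_pos = max(float(wpos_np.sum()), 1e-8)
            # w_neg: live expression P_neg(IoU) * s^gamma
            pneg = nn.clamp(nn.sub(assign_cfg.b_neg,
                                   nn.mul(iou_t, assign_cfg.k_neg)), 0.0, 1.0)
            w_neg = nn.mul(pneg, nn.pow_scalar(s_c, assign_cfg.gamma))

            l_pos = nn.mul(nn.sum_(nn.mul(nn.Tensor(wpos_np), neg_ln_s)),
                           1.0 / norm_pos)
            one_minus = nn.maximum(nn.sub(1.0, s_c), eps)
            l_neg = nn.mul(nn.sum_(nn.mul(w_neg, -nn.log(one_minus))),
                           1.0 / n_cand_img)
            img_pos = nn.add(l_pos, l_neg)
            l_reg = nn.sum_(nn.mul(nn.Tensor(wpos_np), nn.sub(1.0, giou_t)))
            img_reg = nn.mul(l_reg, loss_cfg.lambda_reg / norm_pos)
            tot_pos += float(l_pos.data)
            tot_neg += float(l_neg.data)
            tot_reg += float(img_reg.data)
            n_cand += len(cand)
            wpos_sum += float(wpos_np.sum())

        # focal loss against label 0 over the M non-candidate entries
        fl = nn.mul(nn.pow_scalar(s_flat, loss_cfg.focal_eta),
                    -nn.log(nn.maximum(nn.sub(1.0, s_flat), eps)))
        l_focal = nn.mul(nn.sum_(nn.mul(fl, nn.Tensor(neg_mask))),
                         (1.0 - loss_cfg.focal_alpha) / n_cand_img)
        img_total = l_focal if img_pos is None else nn.add(img_pos, l_focal)
        if img_reg is not None:
            img_total = nn.add(img_total, img_reg)
        total = img_total if total is None else nn.add(total, img_total)

    total = nn.mul(total, 1.0 / batch)
    value = float(total.data)
    if not np.isfinite(value):
        raise FloatingPointError("non-finite detection loss")
    return LossReport(total=total, total_value=value,
                      l_cls=value - tot_reg / batch, l_reg=tot_reg / batch,
                      l_pos=tot_pos / batch, l_neg=tot_neg / batch,
                      num_candidates=n_cand, sum_wpos=wpos_sum)


def fcos_baseline_loss(outputs: HeadOutputs,
                       gt_per_image: Sequence[Sequence[Box]],
                       labels_per_image: Sequence[Sequence[int]] = None,
                       assign_cfg: AssignConfig = None,
                       loss_cfg: LossConfig = None) -> LossReport:
    """Plain-FCOS loss (focal + centerness BCE + GIoU) for the ablation.

    Uses the same center-sampling candidate rule but classic supervision:
    focal loss on the raw class probability with hard positive labels,
    binary cross-entropy on the centerness target
    sqrt(min(l,r)/max(l,r) * min(t,b)/max(t,b)) and centerness-weighted
    GIoU regression.
    """
    assign_cfg = assign_cfg or AssignConfig()
    loss_cfg = loss_cfg or LossConfig()
    eps = loss_cfg.eps
    batch = outputs.cls_logits[0].shape[0]
    shapes = [c.shape[-2:] for c in outputs.cls_logits]
    points, strides, ranges = concat_locations(shapes, outputs.strides,
                                               assign_cfg.regress_ranges)
    S = len(points)
    total = None
    tot_cls = tot_reg = 0.0
    n_pos_total = 0
    for n in range(batch):
        gts = list(gt_per_image[n])
        gt_cls = (list(labels_per_image[n]) if labels_per_image is not None
                  else [1] * len(gts))
        cls, ctr, dlt, _ = _flatten_image(outputs, n)
        ncls = cls.shape[0]
        prob = nn.sigmoid(cls)
        p_flat = nn.reshape(prob, (ncls * S,))
        z_flat = nn.reshape(cls, (ncls * S,))
        zt_flat = nn.reshape(ctr, (S,))
        assign = assign_locations(points, strides, ranges, gts, assign_cfg)
        cand = np.nonzero(assign >= 0)[0]
        pos_mask = np.zeros(ncls * S, dtype=np.float64)
        n_pos = max(len(cand), 1)

        img_total = None
        if len(cand):
            gidx = assign[cand]
            cls_idx = np.array([gt_cls[g] - 1 for g in gidx])
            flat_idx = cls_idx * S + cand
            pos_mask[flat_idx] = 1.0
            p_c = nn.take(p_flat, flat_idx)
            # focal positive part; -ln p stably from the logit
            l_pos = nn.mul(nn.sum_(nn.mul(nn.pow_scalar(nn.sub(1.0, p_c),
                                                        loss_cfg.focal_eta),
                                          nn.softplus(-nn.take(z_flat, flat_idx)))),
                           loss_cfg.focal_alpha)
            # centerness targets from GT geometry
            px, py = points[cand, 0], points[cand, 1]
            gt_arr = np.array([gts[g].as_array() for g in gidx])
            l_ = px - gt_arr[:, 0]
            t_ = py - gt_arr[:, 1]
            r_ = gt_arr[:, 2] - px
            b_ = gt_arr[:, 3] - py
            ct = np.sqrt((np.minimum(l_, r_) / np.maximum(l_, r_))
                         * (np.minimum(t_, b_) / np.maximum(t_, b_)))
            zt_c = nn.take(zt_flat, cand)
            l_ctr = nn.sum_(nn.add(nn.mul(nn.Tensor(ct), nn.softplus(-zt_c)),
                                   nn.mul(nn.Tensor(1.0 - ct),
                                          nn.softplus(zt_c))))
            d_c = nn.take(dlt, cand, axis=1)
            bx0 = nn.sub(px, nn.slice_axis(d_c, 0, 0, 1).reshape(-1))
            by0 = nn.sub(py, nn.slice_axis(d_c, 0, 1, 2).reshape(-1))
            bx1 = nn.add(px, nn.slice_axis(d_c, 0, 2, 3).reshape(-1))
            by1 = nn.add(py, nn.slice_axis(d_c, 0, 3, 4).reshape(-1))
            _, giou_t = _giou_tensor(bx0, by0, bx1, by1, gt_arr)
            l_reg = nn.div(nn.sum_(nn.mul(nn.Tensor(ct), nn.sub(1.0, giou_t))),
                           max(float(ct.sum()), 1e-6))
            img_total = nn.add(nn.mul(nn.add(l_pos, l_ctr), 1.0 / n_pos),
                               nn.mul(l_reg, loss_cfg.lambda_reg))
            tot_reg += float(l_reg.data) * loss_cfg.lambda_reg
            n_pos_total += len(cand)
        # focal negative part over everything not a positive entry
        # -ln(1 - sigma(z)) = softplus(z)
        fl = nn.mul(nn.pow_scalar(p_flat, loss_cfg.focal_eta),
                    nn.softplus(z_flat))
        l_neg = nn.mul(nn.sum_(nn.mul(fl, nn.Tensor(1.0 - pos_mask))),
                       (1.0 - loss_cfg.focal_alpha) / n_pos)
        img_total = l_neg if img_total is None else nn.add(img_total, l_neg)
        total = img_total if total is None else nn.add(total, img_total)
    total = nn.mul(total, 1.0 / batch)
    value = float(total.data)
    if not np.isfinite(value):
        raise FloatingPointError("non-finite detection loss")
    return LossReport(total=total, total_value=value,
                      l_cls=value - tot_reg / batch, l_reg=tot_reg / batch,
                      l_pos=0.0, l_neg=0.0,
                      num_candidates=n_pos_total, sum_wpos=float(n_pos_total))
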