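"""Dual-weighting assignment and composite loss: analytic oracles and
gradient-direction sanity."""

import math

import numpy as np
import pytest

from fcoslsc import nn
from fcoslsc.config import AssignConfig, LossConfig
from fcoslsc.data_io import Box
from fcoslsc.dense_head import HeadOutputs
from fcoslsc.dw_assignment_loss import (CandidateBag, assign_locations,
                                        build_candidate_bag,
                                        classification_loss, concat_locations,
                                        fcos_baseline_loss, focal_loss, giou,
                                        giou_loss, negative_probability,
                                        negative_weight, positive_weight,
                                        total_loss)


class TestPositiveWeight:
    def test_vanishes_at_zero_consistency(self):
        assert positive_weight(0.0, 0.9) == 0.0
        assert positive_weight(0.9, 0.0) == 0.0

    def test_perfect_consistency_value(self):
        # s = IoU = 1, mu = 5: w_pos = 1 * e^5
        assert math.isclose(positive_weight(1.0, 1.0, AssignConfig(mu=5, beta=2)),
                            math.exp(5.0), rel_tol=1e-12)
        assert math.isclose(math.exp(5.0), 148.413, rel_tol=1e-5)

    def test_monotone_in_score_and_iou(self):
        p = AssignConfig()
        assert (positive_weight(0.9, 0.9, p) > positive_weight(0.5, 0.9, p)
                > positive_weight(0.5, 0.5, p))
        grid = np.linspace(0.01, 1.0, 25)
        w_s = positive_weight(grid, 0.7, p)
        w_i = positive_weight(0.7, grid, p)
        assert np.all(np.diff(w_s) > 0) and np.all(np.diff(w_i) > 0)


class TestNegativeWeight:
    def test_probability_branches(self):
        p = AssignConfig()
        assert negative_probability(0.3, p) == 1.0
        assert negative_probability(0.95, p) == 0.0
        assert negative_probability(0.99, p) == 0.0
        # midpoint of (0.5, 0.95) -> exactly 1/2
        assert math.isclose(negative_probability(0.725, p), 0.5, abs_tol=1e-12)

    def test_forced_line_coefficients(self):
        p = AssignConfig()
        assert math.isclose(p.k_neg, 20.0 / 9.0)
        assert math.isclose(p.b_neg, 19.0 / 9.0)

    def test_weight_examples(self):
        p = AssignConfig(gamma=2)
        assert math.isclose(negative_weight(0.5, 0.3, p), 0.25)
        assert negative_weight(0.9, 0.95, p) == 0.0
        assert math.isclose(negative_weight(1.0, 0.725, p), 0.5, abs_tol=1e-12)

    def test_continuity_and_monotonicity_in_iou(self):
        p = AssignConfig()
        ious = np.linspace(0.0, 1.0, 401)
        w = negative_weight(0.8, ious, p)
        assert np.all(np.diff(w) <= 1e-12)            # non-increasing
        assert np.abs(np.diff(w)).max() < 0.01        # no jumps on a fine grid

    def test_equal_wpos_members_get_distinct_wneg(self):
        """Two candidates with identical s*IoU^beta (same w_pos) still
        receive different negative weights — the finer supervision signal."""
        p = AssignConfig()
        s1, i1 = 0.8, 0.6
        s2 = s1 * i1 ** 2 / 0.8 ** 2
        assert math.isclose(positive_weight(s1, i1, p),
                            positive_weight(s2, 0.8, p), rel_tol=1e-12)
        assert not math.isclose(negative_weight(s1, i1, p),
                                negative_weight(s2, 0.8, p), rel_tol=1e-3)


class TestFocalLoss:
    def test_worked_example(self):
        # s = 0.5, background target, alpha 0.25, eta 2
        assert math.isclose(focal_loss(0.5, 0, 0.25, 2.0),
                            -0.75 * 0.25 * math.log(0.5), rel_tol=1e-12)
        assert math.isclose(focal_loss(0.5, 0, 0.25, 2.0), 0.1300, abs_tol=5e-5)

    def test_exponent_free_limit_is_scaled_cross_entropy(self):
        for s in (0.2, 0.5, 0.9):
            assert math.isclose(focal_loss(s, 1, 0.5, 0.0), -0.5 * math.log(s))
            assert math.isclose(focal_loss(s, 0, 0.5, 0.0), -0.5 * math.log(1 - s))

    def test_well_classified_negative_vanishes(self):
        assert focal_loss(1e-6, 0, 0.25, 2.0) < 1e-12


class TestGIoU:
    def test_identity_gives_zero_loss(self):
        b = Box(3, 4, 10, 12)
        assert giou_loss(b, b) == 0.0

    def test_worked_pair(self):
        # IoU 1/7, enclosing 9, union 7 -> GIoU = 1/7 - 2/9, loss ~ 1.0794
        loss = giou_loss(Box(0, 0, 2, 2), Box(1, 1, 3, 3))
        assert math.isclose(loss, 1 - (1 / 7 - 2 / 9), rel_tol=1e-12)
        assert math.isclose(loss, 1.0794, abs_tol=1e-4)

    def test_containment_identity(self):
        outer, inner = Box(0, 0, 10, 10), Box(2, 2, 6, 6)
        iou = inner.area / outer.area
        assert math.isclose(giou_loss(outer, inner), 1 - iou, rel_tol=1e-12)

    def test_loss_bounded_between_zero_and_two(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.uniform(0, 50, 2)
            b = rng.uniform(0, 50, 2)
            box1 = Box(a[0], a[1], a[0] + rng.uniform(1, 30), a[1] + rng.uniform(1, 30))
            box2 = Box(b[0], b[1], b[0] + rng.uniform(1, 30), b[1] + rng.uniform(1, 30))
            assert 0.0 <= giou_loss(box1, box2) <= 2.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(1, 1, 1, 5)


def _toy_locations():
    """A 16x16 toy image seen by two levels (stride 8 and 16)."""
    shapes = [(2, 2), (1, 1)]
    strides = (8, 16)
    ranges = ((-1.0, 64.0), (64.0, 1e8))
    return concat_locations(shapes, strides, ranges), shapes, strides, ranges


def _brute_force_assign(points, strides, ranges, gts, radius=1.5):
    """Independent loop-based restatement of the candidate rule."""
    out = np.full(len(points), -1)
    for i, ((x, y), st, (lo, hi)) in enumerate(zip(points, strides, ranges)):
        best_area = None
        for g, box in enumerate(gts):
            inside = box.x_min < x < box.x_max and box.y_min < y < box.y_max
            maxreg = max(x - box.x_min, box.x_max - x,
                         y - box.y_min, box.y_max - y)
            cx, cy = box.center
            near = math.hypot(x - cx, y - cy) <= radius * st
            if inside and near and lo <= maxreg <= hi:
                if best_area is None or box.area < best_area:
                    best_area = box.area
                    out[i] = g
    return out


class TestCandidateBags:
    def test_matches_brute_force_enumeration(self):
        (points, strides, ranges), *_ = _toy_locations()
        rng = np.random.default_rng(1)
        for _ in range(25):
            gts = []
            for _ in range(rng.integers(1, 4)):
                x0, y0 = rng.uniform(0, 10, 2)
                gts.append(Box(x0, y0, x0 + rng.uniform(2, 14),
                               y0 + rng.uniform(2, 14)))
            got = assign_locations(points, strides, ranges, gts, AssignConfig())
            want = _brute_force_assign(points, strides, ranges, gts)
            assert np.array_equal(got, want)

    def test_gt_filling_the_image(self):
        (points, strides, ranges), *_ = _toy_locations()
        gts = [Box(0.0, 0.0, 16.0, 16.0)]
        got = assign_locations(points, strides, ranges, gts, AssignConfig())
        assert np.array_equal(got, _brute_force_assign(points, strides, ranges, gts))

    def test_nested_boxes_go_to_the_smaller(self):
        (points, strides, ranges), *_ = _toy_locations()
        big = Box(0.0, 0.0, 16.0, 16.0)
        small = Box(2.0, 2.0, 14.0, 14.0)
        assign = assign_locations(points, strides, ranges, [big, small],
                                  AssignConfig())
        shared = assign[assign >= 0]
        assert len(shared) and np.all(shared == 1)

    def test_no_ground_truth_leaves_all_non_candidates(self):
        (points, strides, ranges), *_ = _toy_locations()
        bags = build_candidate_bag(points, strides, ranges, [], AssignConfig())
        assert bags == []
        assign = assign_locations(points, strides, ranges, [], AssignConfig())
        assert np.all(assign == -1)

    def test_bag_weights_filled_from_scores_and_boxes(self):
        (points, strides, ranges), *_ = _toy_locations()
        gts = [Box(0.0, 0.0, 16.0, 16.0)]
        scores = np.full(len(points), 0.6)
        boxes = np.tile([0.0, 0.0, 16.0, 16.0], (len(points), 1))
        bags = build_candidate_bag(points, strides, ranges, gts, AssignConfig(),
                                   scores=scores, boxes=boxes)
        bag = bags[0]
        assert len(bag.member_indices) > 0
        assert np.allclose(bag.ious, 1.0)
        assert np.allclose(bag.w_pos, positive_weight(0.6, 1.0))
        assert np.allclose(bag.w_neg, 0.0)  # IoU above the upper endpoint


class TestClassificationLoss:
    def _bag(self, s, w_pos, w_neg):
        return CandidateBag(gt_index=0, gt_box=Box(0, 0, 1, 1),
                            member_indices=np.arange(len(s)),
                            scores=np.asarray(s, dtype=float),
                            w_pos=np.asarray(w_pos, dtype=float),
                            w_neg=np.asarray(w_neg, dtype=float))

    def test_single_member_log_score(self):
        loss = classification_loss([self._bag([math.exp(-1)], [1.0], [0.0])], [])
        assert math.isclose(loss, 1.0, rel_tol=1e-9)

    def test_weighted_member(self):
        loss = classification_loss([self._bag([0.5], [2.0], [1.0])], [])
        assert math.isclose(loss, 3 * math.log(2), rel_tol=1e-9)

    def test_empty_bags_reduce_to_background_focal(self):
        cfg = LossConfig()
        scores = np.array([0.5, 0.5])
        loss = classification_loss([], scores, cfg)
        assert math.isclose(loss, 2 * focal_loss(0.5, 0, cfg.focal_alpha,
                                                 cfg.focal_eta), rel_tol=1e-6)

    def test_nonfinite_score_names_location(self):
        bag = self._bag([np.nan], [1.0], [0.0])
        with pytest.raises(FloatingPointError, match="0"):
            classification_loss([bag], [])

    def test_one_member_toy_total(self):
        """Composite toy: L_cls = 3 ln 2, L_reg = giou_loss of the worked
        pair with w_pos = 1, lambda = 1 -> L ~ 3.159 before normalization."""
        l_cls = classification_loss([self._bag([0.5], [2.0], [1.0])], [])
        l_reg = 1.0 * giou_loss(Box(0, 0, 2, 2), Box(1, 1, 3, 3))
        assert math.isclose(l_cls + 1.0 * l_reg, 3.159, abs_tol=1e-3)


def _build_outputs(cls_val, ctr_val, delta_val, grad=True):
    """One-level 4x4 head output (stride 8) with constant maps."""
    cls = nn.Tensor(np.full((1, 1, 4, 4), cls_val, dtype=np.float64), grad)
    ctr = nn.Tensor(np.full((1, 1, 4, 4), ctr_val, dtype=np.float64), grad)
    dlt = nn.Tensor(np.full((1, 4, 4, 4), delta_val, dtype=np.float64), grad)
    return HeadOutputs([cls], [dlt], [ctr], strides=(8,))


class TestTotalLoss:
    GT = Box(4.0, 4.0, 20.0, 20.0)  # center (12,12), one candidate location

    def test_perfect_predictor_loss_near_zero(self):
        out = _build_outputs(0.0, 0.0, 8.0, grad=False)
        out.cls_logits[0].data[0, 0, 1, 1] = 30.0   # candidate location (12,12)
        out.cls_logits[0].data[out.cls_logits[0].data < 1] = -30.0
        out.center_logits[0].data[:] = -30.0
        out.center_logits[0].data[0, 0, 1, 1] = 30.0
        rep = total_loss(out, [[self.GT]], [[1]])
        assert rep.total_value < 1e-3
        assert rep.l_reg < 1e-6

    def test_lambda_zero_removes_regression(self):
        out = _build_outputs(-1.0, 0.5, 8.0, grad=False)
        rep = total_loss(out, [[self.GT]], [[1]], loss_cfg=LossConfig(lambda_reg=0.0))
        assert rep.l_reg == 0.0
        assert math.isclose(rep.total_value, rep.l_cls, rel_tol=1e-9)

    def test_no_ground_truth_is_valid(self):
        out = _build_outputs(-2.0, 0.0, 8.0, grad=False)
        rep = total_loss(out, [[]], [[]])
        assert rep.num_candidates == 0
        assert rep.total_value > 0

    def test_gradient_directions(self):
        """Raising a high-IoU candidate's score lowers the loss; raising a
        background score raises it."""
        out = _build_outputs(-1.0, 0.5, 8.0, grad=True)
        rep = total_loss(out, [[self.GT]], [[1]])
        rep.total.backward()
        g = out.cls_logits[0].grad[0, 0]
        assert g[1, 1] < 0          # the candidate at (12,12), IoU = 1
        assert g[0, 0] > 0          # a background location
        assert g[3, 3] > 0

    def test_loss_is_finite_and_positive(self):
        rng = np.random.default_rng(8)
        cls = nn.Tensor(rng.standard_normal((1, 1, 4, 4)), True)
        ctr = nn.Tensor(rng.standard_normal((1, 1, 4, 4)), True)
        dlt = nn.Tensor(np.abs(rng.standard_normal((1, 4, 4, 4))) * 8 + 1, True)
        out = HeadOutputs([cls], [dlt], [ctr], strides=(8,))
        rep = total_loss(out, [[self.GT]], [[1]])
        assert np.isfinite(rep.total_value) and rep.total_value > 0

    def test_baseline_loss_gradient_directions(self):
        out = _build_outputs(-1.0, 0.5, 8.0, grad=True)
        rep = fcos_baseline_loss(out, [[self.GT]], [[1]])
        rep.total.backward()
        g = out.cls_logits[0].grad[0, 0]
        assert g[1, 1] < 0 and g[0, 0] > 0
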