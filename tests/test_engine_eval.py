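"""Training schedule, NMS, COCO-style evaluation and complexity counting."""

import math

import numpy as np
import pytest

from fcoslsc import nn
from fcoslsc.config import (AssignConfig, InferConfig, LossConfig, ModelConfig,
                            PreprocessConfig, TrainConfig)
from fcoslsc.data_io import Box, ImageSample
from fcoslsc.dense_head import HeadOutputs
from fcoslsc.engine_eval import (Detections, box_iou_matrix, complexity,
                                 evaluate, FCOSLSC, lr_at, nms, postprocess,
                                 run_inference, train)
from fcoslsc.synthetic_orchard import render_in_memory, SceneConfig


class TestLearningRateSchedule:
    EPOCH = 477  # 953 images at batch 2

    def test_warmup_endpoints(self):
        cfg = TrainConfig()
        assert lr_at(0, self.EPOCH, cfg) == 0.001
        assert math.isclose(lr_at(1000, self.EPOCH, cfg), 0.00125)

    def test_warmup_is_linear(self):
        cfg = TrainConfig()
        assert math.isclose(lr_at(500, self.EPOCH, cfg), 0.001125)

    def test_steps_after_8_and_11_completed_epochs(self):
        cfg = TrainConfig()
        assert math.isclose(lr_at(8 * self.EPOCH - 1, self.EPOCH, cfg), 0.00125)
        assert math.isclose(lr_at(8 * self.EPOCH, self.EPOCH, cfg), 0.000125)
        assert math.isclose(lr_at(11 * self.EPOCH - 1, self.EPOCH, cfg), 0.000125)
        assert math.isclose(lr_at(11 * self.EPOCH, self.EPOCH, cfg), 0.0000125)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(step_epochs=(11, 8))
        with pytest.raises(ValueError):
            TrainConfig(step_epochs=(8, 12))
        with pytest.raises(ValueError):
            lr_at(-1, self.EPOCH, TrainConfig())


def _brute_force_nms(boxes, scores, thr):
    order = np.argsort(-scores, kind="stable")
    keep = []
    for i in order:
        ok = True
        for j in keep:
            if box_iou_matrix(boxes[i][None], boxes[j][None])[0, 0] > thr:
                ok = False
                break
        if ok:
            keep.append(i)
    return np.array(keep, dtype=np.int64)


class TestNMS:
    def test_duplicate_box_suppressed(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        keep = nms(boxes, np.array([0.9, 0.8]), 0.6)
        assert keep.tolist() == [0]

    def test_disjoint_boxes_all_survive(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30], [40, 0, 50, 10.0]])
        keep = nms(boxes, np.array([0.5, 0.9, 0.7]), 0.6)
        assert sorted(keep.tolist()) == [0, 1, 2]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(1, 16))
            xy = rng.uniform(0, 40, (n, 2))
            wh = rng.uniform(2, 25, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.uniform(0.01, 1.0, n)
            thr = float(rng.uniform(0.2, 0.8))
            assert nms(boxes, scores, thr).tolist() == \
                _brute_force_nms(boxes, scores, thr).tolist()


class TestPostprocess:
    def _outputs(self, scores_map, deltas=6.0):
        logit = np.log(scores_map / (1 - scores_map))
        cls = nn.Tensor(logit[None, None])
        ctr = nn.Tensor(np.full_like(cls.data, 50.0))  # centerness prob -> 1
        dlt = nn.Tensor(np.full((1, 4) + scores_map.shape, deltas))
        return HeadOutputs([cls], [dlt], [ctr], strides=(8,))

    def test_threshold_filters_low_confidence(self):
        smap = np.full((2, 2), 0.3)
        smap[0, 0] = 0.9
        dets = postprocess(self._outputs(smap), InferConfig(score_threshold=0.4))
        assert len(dets) == 1 and dets.scores[0] > 0.89

    def test_max_detections_cap(self):
        smap = np.full((4, 4), 0.95)
        cfg = InferConfig(score_threshold=0.4, nms_iou=0.99, max_detections=5)
        dets = postprocess(self._outputs(smap, deltas=2.0), cfg)
        assert len(dets) == 5
        assert np.all(np.diff(dets.scores) <= 1e-12)  # sorted by confidence

    def test_empty_result_allowed(self):
        dets = postprocess(self._outputs(np.full((2, 2), 0.1)), InferConfig())
        assert len(dets) == 0


def _det(boxes, scores, labels=None):
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    labels = (np.ones(len(scores), dtype=np.int64) if labels is None
              else np.asarray(labels))
    return Detections(boxes, scores, labels)


def _gt(boxes):
    return ImageSample(image_id=1, filename="x.png", width=200, height=200,
                       boxes=[Box(*b) for b in boxes], labels=[1] * len(boxes))


class TestEvaluate:
    def test_single_detection_iou_06_worked_example(self):
        """One GT, one detection at IoU 0.6: AP50 = 100, AP75 = 0, and the
        10-threshold mean AP = 30 (TP at thresholds 0.5, 0.55, 0.6)."""
        gt = _gt([[0, 0, 10, 10]])
        det = _det([[0, 0, 10, 6]], [0.9])  # IoU exactly 0.6
        res = evaluate([det], [gt])
        assert res.AP50 == 100.0
        assert res.AP75 == 0.0
        assert math.isclose(res.AP, 30.0, abs_tol=1e-9)

    def test_unmatched_detection_gives_zero_ap(self):
        res = evaluate([_det([[100, 100, 120, 120]], [0.9])],
                       [_gt([[0, 0, 10, 10]])])
        assert res.AP == 0.0

    def test_perfect_detections_score_100(self):
        boxes = [[0, 0, 20, 20], [50, 50, 90, 90]]
        res = evaluate([_det(boxes, [0.9, 0.8])], [_gt(boxes)])
        assert res.AP == 100.0 and res.AR == 100.0

    def test_empty_everything_flagged_undefined(self):
        res = evaluate([_det(np.zeros((0, 4)), [])], [_gt([])])
        assert not res.defined
        assert math.isnan(res.AP)

    def test_scale_breakdown_places_objects_by_area(self):
        small = [0, 0, 10, 10]          # area 100 < 32^2
        large = [50, 50, 160, 160]      # area 12100 > 96^2
        res = evaluate([_det([small, large], [0.9, 0.8])], [_gt([small, large])])
        assert res.AP_s == 100.0 and res.AP_l == 100.0
        assert math.isnan(res.AP_m)

    def test_matches_independent_reference_evaluator(self):
        """Pooled 101-point AP agrees with a plain loop-based restatement
        of the COCO protocol on random single-class detection sets."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            n_img = int(rng.integers(1, 4))
            gts, dets = [], []
            for _ in range(n_img):
                g = []
                for _ in range(rng.integers(0, 4)):
                    x, y = rng.uniform(0, 60, 2)
                    g.append([x, y, x + rng.uniform(5, 40), y + rng.uniform(5, 40)])
                d, s = [], []
                for box in g:
                    if rng.random() < 0.8:
                        jitter = rng.uniform(-6, 6, 4)
                        d.append(np.asarray(box) + jitter)
                        s.append(rng.uniform(0.2, 1.0))
                for _ in range(rng.integers(0, 3)):  # false positives
                    x, y = rng.uniform(0, 80, 2)
                    d.append([x, y, x + rng.uniform(5, 30), y + rng.uniform(5, 30)])
                    s.append(rng.uniform(0.05, 1.0))
                gts.append(_gt(g))
                dets.append(_det(np.array(d).reshape(-1, 4), s))
            if sum(len(g.boxes) for g in gts) == 0:
                continue
            res = evaluate(dets, gts)
            ref = _reference_map(dets, gts)
            assert math.isclose(res.AP, ref, abs_tol=1e-4 * 100)


def _reference_map(dets, gts):
    """Independent COCO-style mean AP (single class, 'all' areas)."""
    taus = [0.5 + 0.05 * i for i in range(10)]
    aps = []
    for tau in taus:
        records = []  # (score, is_tp)
        n_gt = 0
        for det, gt in zip(dets, gts):
            gboxes = [b.as_array() for b in gt.boxes]
            n_gt += len(gboxes)
            used = [False] * len(gboxes)
            order = sorted(range(len(det.scores)),
                           key=lambda i: -det.scores[i])
            for i in order:
                best, best_iou = -1, tau
                for j, gb in enumerate(gboxes):
                    if used[j]:
                        continue
                    iou = box_iou_matrix(det.boxes[i][None],
                                         np.asarray(gb)[None])[0, 0]
                    if iou >= best_iou:
                        best, best_iou = j, iou
                if best >= 0:
                    used[best] = True
                    records.append((det.scores[i], True))
                else:
                    records.append((det.scores[i], False))
        if n_gt == 0:
            continue
        records.sort(key=lambda r: -r[0])
        tp = fp = 0
        pr = []
        for _, is_tp in records:
            tp += is_tp
            fp += not is_tp
            pr.append((tp / n_gt, tp / (tp + fp)))
        ap = 0.0
        for r in [i / 100 for i in range(101)]:
            ap += max([p for (rec, p) in pr if rec >= r], default=0.0) / 101
        aps.append(ap)
    return 100.0 * float(np.mean(aps)) if aps else float("nan")


class TestComplexityArithmetic:
    def test_single_conv_mac_closed_form(self):
        conv = nn.Conv2d(16, 16, 3)
        assert conv.macs(32, 32) == 3 * 3 * 16 * 16 * 32 * 32 == 2_359_296

    def test_conv_parameter_count(self):
        conv = nn.Conv2d(256, 256, 3)
        assert conv.weight.size + conv.bias.size == 590_080

    def test_params_independent_of_input_size_flops_scale(self):
        model = FCOSLSC(ModelConfig(width_mult=0.25, fpn_channels=32,
                                    use_dcn=False, use_lsc=False))
        r1 = complexity(model, (128, 128))
        r2 = complexity(model, (256, 256))
        assert r1.param_count == r2.param_count
        assert 3.5 < r2.flops / r1.flops < 4.5


class TestTraining:
    def _dataset(self, n=8):
        cfg = SceneConfig(image_size=(64, 64), fruit_count_range=(1, 2),
                          fruit_radius_range=(6.0, 12.0), fruit_hue_offset=40.0,
                          occluder_count_range=(0, 0), overlap_probability=0.0,
                          blur_sigma_range=(0.0, 0.0), seed=5)
        return render_in_memory(cfg, n)

    def _cfgs(self):
        model_cfg = ModelConfig(width_mult=0.25, fpn_channels=32, seed=1)
        model_cfg.lsc.n_blocks = 1
        pre = PreprocessConfig(target_size=(64, 64))
        tcfg = TrainConfig(base_lr=0.005, warmup_start_lr=0.001, warmup_iters=4,
                           epochs=2, step_epochs=(1,), batch_size=2, seed=3)
        return model_cfg, pre, tcfg

    def test_two_epochs_are_deterministic_and_log_the_schedule(self):
        data = self._dataset()
        model_cfg, pre, tcfg = self._cfgs()
        logs = []
        for _ in range(2):
            model = FCOSLSC(model_cfg)
            logs.append(train(model, data, tcfg, AssignConfig(), LossConfig(),
                              pre))
        assert len(logs[0]) == 8  # 8 images, batch 2, 2 epochs
        assert [r["L_total"] for r in logs[0]] == [r["L_total"] for r in logs[1]]
        for it, row in enumerate(logs[0]):
            assert row["lr"] == lr_at(it, 4, tcfg)

    def test_inference_pipeline_emits_detections_structures(self):
        data = self._dataset(2)
        model_cfg, pre, _ = self._cfgs()
        model = FCOSLSC(model_cfg)
        dets, gts = run_inference(model, data, pre,
                                  InferConfig(score_threshold=0.01))
        assert len(dets) == len(gts) == 2
        for d in dets:
            assert d.boxes.shape[1] == 4 if len(d) else True
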