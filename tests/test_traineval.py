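"""Decoding, NMS, mAP evaluation oracles, and training-loop behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from beamyolo.assembly import ModelConfig, build_model
from beamyolo.synthdata import BoxAnnotation, SceneSpec, generate_scene
from beamyolo.traineval import (Detection, TrainConfig, decode_predictions,
                                evaluate, iou_matrix, nms, predict,
                                smoke_train)


def det(cid, cx, cy, w, h, conf):
    return Detection(cid, cx, cy, w, h, conf)


def ann(cid, cx, cy, w, h):
    return BoxAnnotation(cid, cx, cy, w, h)


class TestNMS:
    def test_duplicate_box_suppressed_keeping_higher_confidence(self):
        boxes = np.array([[0.1, 0.1, 0.3, 0.3], [0.1, 0.1, 0.3, 0.3]])
        keep = nms(boxes, np.array([0.8, 0.9]), iou_thresh=0.5)
        assert keep == [1]

    def test_disjoint_boxes_all_kept(self):
        boxes = np.array([[0.0, 0.0, 0.2, 0.2], [0.5, 0.5, 0.7, 0.7]])
        assert sorted(nms(boxes, np.array([0.9, 0.8]), 0.5)) == [0, 1]


class TestDecode:
    def _head_maps(self, nc=3, reg_max=8, sizes=((8, 8), (4, 4), (2, 2))):
        maps = []
        for h, w in sizes:
            maps.append((np.zeros((1, 4 * reg_max, h, w)),
                         np.full((1, nc, h, w), -20.0)))
        return maps

    def test_all_negative_logits_give_empty_list(self):
        dets = decode_predictions(self._head_maps(), reg_max=8)
        assert dets == [[]]

    def test_single_cell_activation_decodes_with_stride_arithmetic(self):
        reg_max = 8
        maps = self._head_maps(reg_max=reg_max)
        box, cls = maps[0]
        cls[0, 1, 3, 2] = 8.0  # confident class-1 at cell (y=3, x=2), stride 8
        # put all distribution mass on bin 2 for every side: d = 2 cells
        box[0, :, 3, 2] = np.tile(np.eye(reg_max)[2] * 50.0, 4)
        dets = decode_predictions(maps, strides=(8, 16, 32), reg_max=reg_max,
                                  conf_thresh=0.25)[0]
        assert len(dets) == 1
        d = dets[0]
        img = 8 * 8  # level-0 grid of 8 cells at stride 8
        assert d.class_id == 1
        assert d.cx == pytest.approx((2 + 0.5) * 8 / img)
        assert d.cy == pytest.approx((3 + 0.5) * 8 / img)
        assert d.w == pytest.approx(2 * 2 * 8 / img)
        assert d.h == pytest.approx(2 * 2 * 8 / img)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            decode_predictions(self._head_maps(), conf_thresh=1.5)


class TestEvaluate:
    def test_perfect_detector_scores_one(self):
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2)], [ann(1, 0.3, 0.3, 0.1, 0.1)]]
        dets = [[det(0, 0.5, 0.5, 0.2, 0.2, 1.0)], [det(1, 0.3, 0.3, 0.1, 0.1, 1.0)]]
        res = evaluate(dets, gt)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)
        assert res.precision == pytest.approx(1.0)
        assert res.recall == pytest.approx(1.0)

    def test_no_detections_zero_recall(self):
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2)]]
        res = evaluate([[]], gt)
        assert res.recall == 0.0
        assert res.map50 == 0.0

    def test_intermediate_iou_matches_three_of_ten_thresholds(self):
        # shift 0.045 in x: inter 0.155*0.2, union 0.08-0.031 -> IoU ~ 0.633;
        # TP at thresholds 0.50/0.55/0.60, FP from 0.65 on
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2)]]
        dets = [[det(0, 0.545, 0.5, 0.2, 0.2, 0.9)]]
        box_iou = iou_matrix(np.array([dets[0][0].corners()]),
                             np.array([gt[0][0].corners()]))[0, 0]
        assert box_iou == pytest.approx(0.031 / 0.049)
        res = evaluate(dets, gt)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(0.3)

    def test_order_invariance(self, rng):
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2), ann(0, 0.2, 0.2, 0.1, 0.1)]]
        dd = [det(0, 0.5, 0.5, 0.2, 0.2, 0.7), det(0, 0.2, 0.2, 0.1, 0.1, 0.9),
              det(0, 0.8, 0.8, 0.1, 0.1, 0.5)]
        r1 = evaluate([dd], gt)
        r2 = evaluate([list(reversed(dd))], gt)
        assert r1 == r2

    def test_duplicate_true_positive_never_increases_ap(self):
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2)]]
        single = evaluate([[det(0, 0.5, 0.5, 0.2, 0.2, 0.9)]], gt)
        doubled = evaluate([[det(0, 0.5, 0.5, 0.2, 0.2, 0.9),
                             det(0, 0.5, 0.5, 0.2, 0.2, 0.8)]], gt)
        assert doubled.map50 <= single.map50 + 1e-12

    def test_map50_dominates_map50_95(self, rng):
        gt, dd = [], []
        for i in range(4):
            gt.append([ann(i % 2, 0.3 + 0.1 * i, 0.4, 0.15, 0.15)])
            jitter = 0.02 * rng.uniform(-1, 1)
            dd.append([det(i % 2, 0.3 + 0.1 * i + jitter, 0.4, 0.15, 0.15,
                           rng.uniform(0.3, 1.0))])
        res = evaluate(dd, gt)
        assert res.map50 >= res.map50_95

    def test_detections_without_ground_truth_class_are_excluded(self):
        gt = [[ann(0, 0.5, 0.5, 0.2, 0.2)]]
        dets = [[det(0, 0.5, 0.5, 0.2, 0.2, 0.9), det(5, 0.2, 0.2, 0.1, 0.1, 0.9)]]
        res = evaluate(dets, gt)
        assert res.map50 == pytest.approx(1.0)  # class 5 absent from GT


def _tiny_model(num_classes=3, seed=0):
    cfg = ModelConfig(num_classes=num_classes, input_size=(64, 64),
                      width_mult=0.125, reg_max=8, seed=seed)
    return build_model(cfg)


def _tiny_dataset(n, num_classes=3, seed=50):
    spec = SceneSpec(image_size=64, num_classes=num_classes,
                     objects_per_image=(1, 2), object_size_px=(16, 32),
                     contrast="high", seed=seed)
    return [generate_scene(replace(spec, seed=spec.seed + i)) for i in range(n)]


class TestTraining:
    def test_zero_learning_rate_freezes_loss(self):
        model = _tiny_model()
        data = _tiny_dataset(2)
        cfg = TrainConfig(epochs=1, batch_size=2, lr=0.0, image_size=64,
                          warmup_steps=1, seed=0)
        trace = smoke_train(model, data, cfg, steps=3, log=None)
        # constant up to float summation reordering of the shuffled batch
        assert max(trace) - min(trace) < 1e-9

    def test_same_seed_reproduces_trace(self):
        traces = []
        for _ in range(2):
            model = _tiny_model(seed=1)
            cfg = TrainConfig(epochs=1, batch_size=2, image_size=64, seed=4)
            traces.append(smoke_train(model, _tiny_dataset(4), cfg, steps=3, log=None))
        np.testing.assert_allclose(traces[0], traces[1], atol=1e-6)

    def test_short_run_decreases_smoothed_loss(self):
        model = _tiny_model()
        data = _tiny_dataset(8)
        cfg = TrainConfig(epochs=10, batch_size=4, image_size=64,
                          warmup_steps=4, seed=0)
        trace = smoke_train(model, data, cfg, steps=24, log=None)
        assert np.mean(trace[-6:]) < np.mean(trace[:6])

    def test_predict_emits_valid_detections(self):
        model = _tiny_model()
        data = _tiny_dataset(2)
        dets = predict(model, [im for im, _ in data], conf_thresh=0.0)
        for dd in dets:
            for d in dd:
                x0, y0, x1, y1 = d.corners()
                assert -1e-9 <= x0 < x1 <= 1 + 1e-9
                assert np.isfinite(d.confidence)
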