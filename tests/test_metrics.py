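import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simscorr.metrics import (
    MAP_THRESHOLDS,
    MatchResult,
    average_precision,
    confusion_matrix,
    map_50_95,
    mask_iou,
    match_instances,
    precision_recall_f1,
)
from simscorr.rois import CLASS_NAMES, ROISet
from simscorr.segment import Detection
from tests.conftest import disk_mask, square_mask

SHAPE = (40, 40)


def roiset(*instances):
    rois = ROISet(image_shape=SHAPE)
    for class_id, mask, conf in instances:
        rois.add(class_id, mask, confidence=conf)
    return rois


class TestMaskIoU:
    def test_identical(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        assert mask_iou(m, m) == 1.0

    def test_disjoint(self):
        a = square_mask(SHAPE, 0, 0, 10)
        b = square_mask(SHAPE, 20, 20, 10)
        assert mask_iou(a, b) == 0.0

    def test_one_third(self):
        # two 10x10 squares overlapping in a 10x5 strip: 50 / 150
        a = square_mask(SHAPE, 0, 0, 10)
        b = square_mask(SHAPE, 0, 5, 10)
        assert mask_iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_raises(self):
        z = np.zeros(SHAPE, dtype=bool)
        with pytest.raises(ValueError):
            mask_iou(z, z)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_iou(np.ones((4, 4), bool), np.ones((5, 5), bool))

    @given(st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(SHAPE) < 0.3
        b = rng.random(SHAPE) < 0.3
        if not (a.any() or b.any()):
            return
        assert mask_iou(a, b) == mask_iou(b, a)
        assert 0.0 <= mask_iou(a, b) <= 1.0


class TestMatchInstances:
    def test_perfect_prediction(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        truth = roiset((0, m, 1.0))
        pred = roiset((0, m, 0.9))
        res = match_instances(truth, pred)
        assert res.tp == 1 and res.fp == 0 and res.fn == 0
        assert res.pairs[0][2] == 1.0

    def test_highest_iou_truth_wins(self):
        t1 = square_mask(SHAPE, 0, 0, 10)
        t2 = square_mask(SHAPE, 0, 8, 10)
        pred_mask = square_mask(SHAPE, 0, 2, 10)  # IoU 0.666 with t1, 0.5 t2
        truth = roiset((0, t1, 1.0), (0, t2, 1.0))
        pred = roiset((0, pred_mask, 0.9))
        res = match_instances(truth, pred, iou_threshold=0.3)
        assert res.tp == 1
        assert res.pairs[0][0] == truth.instances[0].instance_id
        assert len(res.unmatched_truth) == 1

    def test_empty_pred_all_unmatched(self):
        truth = roiset((0, disk_mask(SHAPE, (20, 20), 8), 1.0))
        res = match_instances(truth, ROISet(image_shape=SHAPE))
        assert res.fn == 1 and res.tp == 0

    def test_class_mismatch_never_matches(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        res = match_instances(roiset((0, m, 1.0)), roiset((1, m, 0.9)))
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    def test_each_side_matched_once(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        truth = roiset((0, m, 1.0))
        pred = roiset((0, m, 0.9), (0, m, 0.8))
        res = match_instances(truth, pred)
        assert res.tp == 1 and res.fp == 1


class TestPrecisionRecallF1:
    def test_perfect(self):
        res = MatchResult([(1, 1, 1.0)] * 5, [], [], 0.5)
        assert precision_recall_f1(res) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        # TP=3, FP=1, FN=2
        res = MatchResult([(1, 1, 0.9)] * 3, [8, 9], [7], 0.5)
        p, r, f1 = precision_recall_f1(res)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert f1 == pytest.approx(2 / (1 / 0.75 + 1 / 0.6), abs=1e-6)

    def test_degenerate_zero(self):
        res = MatchResult([], [], [5], 0.5)
        assert precision_recall_f1(res) == (0.0, 0.0, 0.0)


def detection(class_id, mask, conf):
    return Detection(class_id, mask, conf)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        truth = roiset((0, m, 1.0))
        dets = [detection(0, m, 0.9)]
        for thr in MAP_THRESHOLDS:
            assert average_precision(dets, truth, thr)[0] == 1.0
        mean_ap, per_class = map_50_95(dets, truth)
        assert mean_ap == 1.0

    def test_tp_then_fp_ap_is_one(self):
        # all-point interpolation: envelope at recall 1 is 1.0
        m = disk_mask(SHAPE, (20, 20), 8)
        fp = square_mask(SHAPE, 0, 0, 6)
        truth = roiset((0, m, 1.0))
        dets = [detection(0, m, 0.9), detection(0, fp, 0.8)]
        assert average_precision(dets, truth, 0.5)[0] == pytest.approx(1.0)

    def test_fp_then_tp_brute_force_curve(self):
        # confidence order: FP first -> PR points (0,0) then (0.5, 1.0);
        # all-point AP = 1 * 0.5
        m = disk_mask(SHAPE, (20, 20), 8)
        fp = square_mask(SHAPE, 0, 0, 6)
        truth = roiset((0, m, 1.0))
        dets = [detection(0, fp, 0.95), detection(0, m, 0.9)]
        assert average_precision(dets, truth, 0.5)[0] == pytest.approx(0.5)

    def test_iou_sweep_worked_example(self):
        # detection overlaps truth at IoU 0.6: TP at 0.50-0.60, FP above
        truth_mask = square_mask(SHAPE, 0, 0, 10)
        det_mask = square_mask(SHAPE, 0, 2, 10)  # IoU 80/120 = 2/3
        iou = mask_iou(truth_mask, det_mask)
        assert iou == pytest.approx(2 / 3)
        truth = roiset((0, truth_mask, 1.0))
        dets = [detection(0, det_mask, 0.9)]
        mean_ap, _ = map_50_95(dets, truth)
        n_hit = sum(1 for t in MAP_THRESHOLDS if iou >= t)
        assert mean_ap == pytest.approx(n_hit / len(MAP_THRESHOLDS))

    def test_confidence_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        truth = roiset((0, disk_mask(SHAPE, (10, 10), 5), 1.0),
                       (0, disk_mask(SHAPE, (30, 30), 5), 1.0))
        dets = [detection(0, disk_mask(SHAPE, (10, 10), 5), 0.7),
                detection(0, square_mask(SHAPE, 20, 0, 6), 0.5),
                detection(0, disk_mask(SHAPE, (30, 30), 5), 0.3)]
        base = average_precision(dets, truth, 0.5)
        rescaled = [detection(d.class_id, d.mask,
                              float(1 / (1 + np.exp(-5 * d.confidence))))
                    for d in dets]
        assert average_precision(rescaled, truth, 0.5) == base

    def test_map_never_exceeds_ap50(self):
        rng = np.random.default_rng(1)
        truth = roiset((0, disk_mask(SHAPE, (12, 12), 6), 1.0),
                       (1, disk_mask(SHAPE, (28, 28), 6), 1.0))
        dets = [detection(0, disk_mask(SHAPE, (12, 13), 6), 0.8),
                detection(1, disk_mask(SHAPE, (28, 28), 5), 0.7)]
        ap50 = average_precision(dets, truth, 0.5)
        _, per_class = map_50_95(dets, truth)
        for cls, ap in per_class.items():
            assert ap <= ap50[cls] + 1e-12

    def test_class_without_truth_excluded(self):
        truth = roiset((0, disk_mask(SHAPE, (20, 20), 8), 1.0))
        dets = [detection(0, disk_mask(SHAPE, (20, 20), 8), 0.9),
                detection(3, square_mask(SHAPE, 0, 0, 5), 0.8)]
        ap = average_precision(dets, truth, 0.5)
        assert set(ap) == {0}


class TestConfusionMatrix:
    def test_perfect_six_classes(self):
        masks = [disk_mask((80, 80), (10 + 12 * i, 40), 5) for i in range(6)]
        truth = ROISet(image_shape=(80, 80))
        pred = ROISet(image_shape=(80, 80))
        for i, m in enumerate(masks):
            truth.add(i, m)
            pred.add(i, m, confidence=0.9)
        cm = confusion_matrix(truth, pred)
        assert np.allclose(cm.matrix[:6, :6], np.eye(6))
        assert np.all(cm.matrix[6, :] == 0)
        assert np.all(cm.matrix[:, 6] == 0)

    def test_missed_truth_goes_to_background_row(self):
        truth = roiset((1, disk_mask(SHAPE, (20, 20), 8), 1.0))
        cm = confusion_matrix(truth, ROISet(image_shape=SHAPE))
        assert cm.matrix[6, 1] == 1.0

    def test_spurious_pred_goes_to_background_column(self):
        pred = roiset((2, disk_mask(SHAPE, (20, 20), 8), 0.9))
        cm = confusion_matrix(ROISet(image_shape=SHAPE), pred)
        assert cm.matrix[2, 6] == 1.0

    def test_misclassification_counts_cross_class(self):
        m = disk_mask(SHAPE, (20, 20), 8)
        cm = confusion_matrix(roiset((0, m, 1.0)), roiset((1, m, 0.9)))
        assert cm.matrix[1, 0] == 1.0

    def test_true_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        truth = ROISet(image_shape=(120, 120))
        pred = ROISet(image_shape=(120, 120))
        for i in range(10):
            c = tuple(rng.integers(10, 110, 2))
            m = disk_mask((120, 120), c, 6)
            truth.add(int(rng.integers(0, 6)), m)
            if rng.random() < 0.7:
                pred.add(int(rng.integers(0, 6)), m, confidence=0.8)
        cm = confusion_matrix(truth, pred)
        sums = cm.matrix[:, :6].sum(axis=0)
        present = cm.counts[:, :6].sum(axis=0) > 0
        assert np.allclose(sums[present], 1.0, atol=1e-9)

    def test_frame_labels(self):
        cm = confusion_matrix(roiset((0, disk_mask(SHAPE, (20, 20), 8), 1.0)),
                              ROISet(image_shape=SHAPE))
        df = cm.to_frame()
        assert list(df.columns) == list(CLASS_NAMES) + ["background"]
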