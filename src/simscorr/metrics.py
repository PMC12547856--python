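"""Segmentation scoring: IoU, precision/recall/F1, AP, mAP, confusion matrix.

Matching follows the standard detection-evaluation convention: predictions
are processed in descending confidence and each one greedily takes the
highest-IoU unmatched ground-truth instance at or above the IoU threshold.
Average precision uses the all-point interpolated precision-recall curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import ROISet

log = logging.getLogger(__name__)

#: IoU thresholds of the mAP@0.5-0.95 sweep.
MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two same-shape boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]   # (truth_id, pred_id, IoU)
    unmatched_truth: list[int]
    unmatched_pred: list[int]
    iou_threshold: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truth)


def _greedy_match(truth_items, pred_items, iou_threshold, same_class=True):
    """Greedy confidence-ordered matching.

    ``*_items``: lists of (id, class_id, mask, confidence).  Returns
    (pairs, unmatched_truth_ids, unmatched_pred_ids).
    """
    order = sorted(range(len(pred_items)),
                   key=lambda i: -pred_items[i][3])
    taken: set[int] = set()
    pairs = []
    matched_pred = set()
    for pi in order:
        pid, pcls, pmask, _ = pred_items[pi]
        best_iou, best_ti = 0.0, None
        for ti, (tid, tcls, tmask, _) in enumerate(truth_items):
            if ti in taken:
                continue
            if same_class and tcls != pcls:
                continue
            inter = np.logical_and(pmask, tmask).sum()
            if inter == 0:
                continue
            iou = inter / (pmask.sum() + tmask.sum() - inter)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti is not None and best_iou >= iou_threshold:
            taken.add(best_ti)
            matched_pred.add(pi)
            pairs.append((truth_items[best_ti][0], pid, float(best_iou)))
    unmatched_truth = [t[0] for i, t in enumerate(truth_items)
                       if i not in taken]
    unmatched_pred = [p[0] for i, p in enumerate(pred_items)
                      if i not in matched_pred]
    return pairs, unmatched_truth, unmatched_pred


def _items(rois: ROISet):
    return [(inst.instance_id, inst.class_id, inst.mask, inst.confidence)
            for inst in rois]


def match_instances(truth: ROISet, pred: ROISet,
                    iou_threshold: float = 0.5) -> MatchResult:
    """Match predictions to same-class ground-truth instances."""
    if tuple(truth.image_shape) != tuple(pred.image_shape):
        raise ValueError("truth and prediction frames differ in shape")
    pairs, ut, up = _greedy_match(_items(truth), _items(pred), iou_threshold)
    return MatchResult(pairs, ut, up, iou_threshold)


def precision_recall_f1(match: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1); F1 = 0 when precision + recall = 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _ap_from_curve(tp_flags: np.ndarray, n_truth: int) -> float:
    """All-point interpolated AP from the descending-confidence TP/FP flags."""
    if n_truth == 0:
        raise ValueError("AP undefined without ground truth")
    if len(tp_flags) == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1 - tp_flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (monotone nonincreasing from the right)
    mrec = np.concatenate([[0.0], recall])
    mpre = np.concatenate([[1.0], precision])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    return float(np.sum(np.diff(mrec) * mpre[1:]))


def _class_tp_flags(dets, truths, iou_threshold):
    """Descending-confidence TP/FP flags for one class."""
    dets = sorted(dets, key=lambda d: -d[1])
    taken: set[int] = set()
    flags = np.zeros(len(dets))
    for di, (mask, _conf) in enumerate(dets):
        best_iou, best_ti = 0.0, None
        for ti, tmask in enumerate(truths):
            if ti in taken:
                continue
            inter = np.logical_and(mask, tmask).sum()
            if inter == 0:
                continue
            iou = inter / (mask.sum() + tmask.sum() - inter)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti is not None and best_iou >= iou_threshold:
            taken.add(best_ti)
            flags[di] = 1
    return flags


def average_precision(detections, truth: ROISet,
                      iou_threshold: float = 0.5) -> dict[int, float]:
    """Per-class AP at one IoU threshold.

    ``detections``: objects with ``class_id``, ``mask`` and ``confidence``
    attributes (:class:`~simscorr.segment.Detection` instances or ROI
    instances).  Classes with no ground truth are excluded and logged.
    """
    ap: dict[int, float] = {}
    truth_classes = {inst.class_id for inst in truth}
    det_classes = {d.class_id for d in detections}
    for cls in sorted(det_classes - truth_classes):
        log.info("class %d has detections but no ground truth; excluded "
                 "from AP", cls)
    for cls in sorted(truth_classes):
        truths = [inst.mask for inst in truth.by_class(cls)]
        dets = [(d.mask, d.confidence) for d in detections
                if d.class_id == cls]
        flags = _class_tp_flags(dets, truths, iou_threshold)
        ap[cls] = _ap_from_curve(flags, len(truths))
    return ap


def map_50_95(detections, truth: ROISet) -> tuple[float, dict[int, float]]:
    """mAP@0.5-0.95: AP averaged over IoU thresholds 0.50:0.05:0.95, then
    over classes with ground truth.  Returns (mAP, per-class means)."""
    per_class: dict[int, list[float]] = {}
    for thr in MAP_THRESHOLDS:
        for cls, ap in average_precision(detections, truth, thr).items():
            per_class.setdefault(cls, []).append(ap)
    class_means = {cls: float(np.mean(v)) for cls, v in per_class.items()}
    if not class_means:
        raise ValueError("no class has ground truth; mAP undefined")
    return float(np.mean(list(class_means.values()))), class_means


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """(C+1) x (C+1) relative-frequency matrix.

    Rows are the predicted class, columns the true class; index C is the
    background.  Each true-class column is normalized to sum to 1; the
    background column is normalized over the predictions it contains.
    """

    matrix: np.ndarray
    class_names: tuple[str, ...]
    counts: np.ndarray = field(default=None)

    @property
    def labels(self) -> list[str]:
        return list(self.class_names) + ["background"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)


def confusion_matrix(truth: ROISet, pred: ROISet,
                     iou_threshold: float = 0.5) -> ConfusionMatrix:
    """Instance-level confusion matrix with a background row and column.

    Instances are matched spatially (class-agnostic, greedy by confidence);
    a matched pair increments (predicted class, true class), an unmatched
    truth counts as predicted background, an unmatched prediction as a
    detection on background.
    """
    c = len(truth.class_names)
    counts = np.zeros((c + 1, c + 1))
    t_items = _items(truth)
    p_items = _items(pred)
    pairs, ut, up = _greedy_match(t_items, p_items, iou_threshold,
                                  same_class=False)
    t_class = {i[0]: i[1] for i in t_items}
    p_class = {i[0]: i[1] for i in p_items}
    for tid, pid, _iou in pairs:
        counts[p_class[pid], t_class[tid]] += 1
    for tid in ut:
        counts[c, t_class[tid]] += 1
    for pid in up:
        counts[p_class[pid], c] += 1
    matrix = counts.copy()
    sums = matrix.sum(axis=0)
    nonzero = sums > 0
    matrix[:, nonzero] = matrix[:, nonzero] / sums[nonzero]
    return ConfusionMatrix(matrix=matrix, class_names=truth.class_names,
                           counts=counts)
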