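"""Detection metrics: IoU, precision/recall, AP and mAP.

AP realizes the precision-recall integral as the standard 101-point
interpolated precision envelope; mAP averages per-class AP, and the
0.5:0.95 variant additionally averages over the ten IoU thresholds
0.50, 0.55, ..., 0.95. Matching is class-wise greedy by descending
confidence: a detection is a true positive when its best-IoU unmatched
ground truth reaches the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detection import Detection

log = logging.getLogger(__name__)

COCO_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)


def iou(box_a, box_b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes; 0 when disjoint."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        log.warning("IoU of a degenerate (zero-area) box defined as 0")
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) vs (M,4) corner boxes."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a, b = np.asarray(boxes_a, float), np.asarray(boxes_b, float)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])).clip(0)
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])).clip(0)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


@dataclass
class MatchCounts:
    """TP/FP/FN tallies for one class at one IoU threshold."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _truths_as_array(truths) -> np.ndarray:
    arr = np.asarray(truths, dtype=float)
    return arr.reshape(-1, 5)


def match_detections(dets: list[Detection], truths, iou_threshold: float
                     ) -> dict[int, MatchCounts]:
    """Greedy one-to-one matching within one image.

    ``truths`` rows are ``(class_id, x1, y1, x2, y2)``. Returns per-class
    counts at the given threshold.
    """
    truths = _truths_as_array(truths)
    dets = sorted(dets, key=lambda d: -d.confidence)
    counts: dict[int, MatchCounts] = {}
    classes = set(int(t[0]) for t in truths) | set(d.class_id for d in dets)
    for c in classes:
        gt = truths[truths[:, 0] == c][:, 1:]
        dboxes = np.array([d.box for d in dets if d.class_id == c]).reshape(-1, 4)
        ious = iou_matrix(dboxes, gt)
        matched = np.zeros(len(gt), dtype=bool)
        mc = MatchCounts()
        for i in range(len(dboxes)):
            cand = np.where(~matched, ious[i], -1.0)
            j = int(cand.argmax()) if len(gt) else -1
            if j >= 0 and cand[j] >= iou_threshold:
                matched[j] = True
                mc.tp += 1
            else:
                mc.fp += 1
        mc.fn = int((~matched).sum())
        counts[c] = mc
    return counts


def precision_recall(counts: MatchCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0/0 defined as 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def average_precision(tp_flags: np.ndarray, confidences: np.ndarray,
                      n_truth: int) -> float:
    """AP from per-detection TP flags via 101-point interpolation.

    ``tp_flags``/``confidences`` are aligned per detection (any order);
    ``n_truth`` is the number of ground-truth objects of the class.
    """
    if n_truth == 0:
        raise ValueError("AP undefined for a class with no ground truths")
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # precision envelope, sampled at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, grid, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def mean_ap(per_class_ap: dict[int, float]) -> float:
    """Unweighted mean of per-class APs."""
    if not per_class_ap:
        return 0.0
    return float(np.mean(list(per_class_ap.values())))


def _per_class_flags(dets_per_image, truths_per_image, cls: int, thr: float):
    """TP flags and confidences for one class at one threshold, across images."""
    flags, confs, n_truth = [], [], 0
    for dets, truths in zip(dets_per_image, truths_per_image):
        truths = _truths_as_array(truths)
        gt = truths[truths[:, 0] == cls][:, 1:]
        n_truth += len(gt)
        cdets = sorted((d for d in dets if d.class_id == cls),
                       key=lambda d: -d.confidence)
        dboxes = np.array([d.box for d in cdets]).reshape(-1, 4)
        ious = iou_matrix(dboxes, gt)
        matched = np.zeros(len(gt), dtype=bool)
        for i, d in enumerate(cdets):
            cand = np.where(~matched, ious[i], -1.0)
            j = int(cand.argmax()) if len(gt) else -1
            hit = j >= 0 and cand[j] >= thr
            if hit:
                matched[j] = True
            flags.append(1.0 if hit else 0.0)
            confs.append(d.confidence)
    return np.array(flags), np.array(confs), n_truth


def coco_map(dets_per_image, truths_per_image) -> dict:
    """Dataset-level evaluation report.

    Returns ``{"map50", "map50_95", "per_class": {cls: {thr: AP}},
    "precision", "recall"}``; precision/recall are macro-averages at
    IoU 0.5 over classes with ground truths. Classes without ground
    truths are excluded from the means with a warning.
    """
    truth_classes = set()
    for truths in truths_per_image:
        truth_classes |= set(int(t[0]) for t in _truths_as_array(truths))
    det_classes = set(d.class_id for dets in dets_per_image for d in dets)
    for c in sorted(det_classes - truth_classes):
        log.warning("class %d has detections but no ground truths; "
                    "excluded from mAP", c)

    per_class: dict[int, dict[float, float]] = {}
    for c in sorted(truth_classes):
        per_class[c] = {}
        for thr in COCO_THRESHOLDS:
            flags, confs, n_truth = _per_class_flags(
                dets_per_image, truths_per_image, c, float(thr))
            per_class[c][float(thr)] = average_precision(flags, confs, n_truth)

    map_per_thr = {float(t): mean_ap({c: per_class[c][float(t)] for c in per_class})
                   for t in COCO_THRESHOLDS}
    # macro P/R at IoU 0.5
    ps, rs = [], []
    for c in sorted(truth_classes):
        tp = fp = fn = 0
        for dets, truths in zip(dets_per_image, truths_per_image):
            mc = match_detections([d for d in dets if d.class_id == c],
                                  _truths_as_array(truths)[
                                      _truths_as_array(truths)[:, 0] == c],
                                  0.5).get(c)
            if mc:
                tp, fp, fn = tp + mc.tp, fp + mc.fp, fn + mc.fn
        p, r = precision_recall(MatchCounts(tp, fp, fn))
        ps.append(p)
        rs.append(r)
    return {
        "map50": map_per_thr[0.5],
        "map50_95": float(np.mean(list(map_per_thr.values()))),
        "map_per_threshold": map_per_thr,
        "per_class": per_class,
        "precision": float(np.mean(ps)) if ps else 0.0,
        "recall": float(np.mean(rs)) if rs else 0.0,
    }
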