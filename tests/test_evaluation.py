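"""Metric correctness against independent oracles."""

import numpy as np
import pytest

from strawdet.detection import Detection
from strawdet.evaluation import (COCO_THRESHOLDS, MatchCounts, average_precision,
                                 coco_map, iou, match_detections, mean_ap,
                                 precision_recall)

# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)
# ---------------------------------------------------------------------------


def greedy_match_oracle(dets, truths, thr):
    """Plain-python greedy matcher over one class."""
    used = set()
    tp = fp = 0
    for d in sorted(dets, key=lambda d: -d.confidence):
        best, best_iou = None, 0.0
        for j, t in enumerate(truths):
            if j in used:
                continue
            v = iou(d.box, t)
            if v > best_iou:
                best, best_iou = j, v
        if best is not None and best_iou >= thr:
            used.add(best)
            tp += 1
        else:
            fp += 1
    return tp, fp, len(truths) - len(used)


def exact_step_ap(tp_flags, confidences, n_truth):
    """Exact area under the interpolated-precision step curve."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp_flags, float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = np.concatenate([[0.0], cum_tp / n_truth])
    precision = np.concatenate([[1.0], cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)])
    env = np.maximum.accumulate(precision[::-1])[::-1]
    return float(np.sum(np.diff(recall) * env[1:]))


def _random_boxes(rng, n, size=100):
    xy = rng.uniform(0, size * 0.8, (n, 2))
    wh = rng.uniform(3, size * 0.3, (n, 2))
    return np.concatenate([xy, xy + wh], axis=1)


# ---------------------------------------------------------------------------
# IoU / matching / precision-recall
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ((0, 0, 10, 10), (0, 0, 10, 10), 1.0),
    ((0, 0, 10, 10), (20, 20, 30, 30), 0.0),
    ((0, 0, 10, 10), (5, 0, 15, 10), 50 / 150),
])
def test_iou_closed_form(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)


def test_iou_degenerate_box_is_zero():
    assert iou((5, 5, 5, 10), (0, 0, 10, 10)) == 0.0


def test_match_perfect_and_empty_detections():
    truths = np.array([[0, 0, 0, 10, 10], [0, 20, 20, 40, 40]], float)
    dets = [Detection(0, 0.9, (0, 0, 10, 10)), Detection(0, 0.8, (20, 20, 40, 40))]
    mc = match_detections(dets, truths, 0.5)[0]
    assert (mc.tp, mc.fp, mc.fn) == (2, 0, 0)
    mc = match_detections([], truths, 0.5)[0]
    assert (mc.tp, mc.fp, mc.fn) == (0, 0, 2)


def test_match_equals_greedy_oracle_on_random_instances(rng):
    for _ in range(50):
        truths = _random_boxes(rng, 5)
        dets = [Detection(0, float(c), tuple(b))
                for c, b in zip(rng.random(10), _random_boxes(rng, 10))]
        truth_rows = np.concatenate(
            [np.zeros((5, 1)), truths], axis=1)
        mc = match_detections(dets, truth_rows, 0.5)[0]
        assert (mc.tp, mc.fp, mc.fn) == greedy_match_oracle(
            dets, [tuple(t) for t in truths], 0.5)


@pytest.mark.parametrize("tp,fp,fn,p,r", [
    (8, 2, 2, 0.8, 0.8),
    (0, 0, 5, 0.0, 0.0),     # 0/0 convention for precision
    (0, 3, 0, 0.0, 0.0),
])
def test_precision_recall_formulas(tp, fp, fn, p, r):
    assert precision_recall(MatchCounts(tp, fp, fn)) == (pytest.approx(p),
                                                         pytest.approx(r))


def test_precision_recall_random_counts_match_recomputation(rng):
    for _ in range(25):
        tp, fp, fn = (int(x) for x in rng.integers(0, 50, 3))
        p, r = precision_recall(MatchCounts(tp, fp, fn))
        assert p == (tp / (tp + fp) if tp + fp else 0.0)
        assert r == (tp / (tp + fn) if tp + fn else 0.0)


# ---------------------------------------------------------------------------
# AP and mAP
# ---------------------------------------------------------------------------

def test_single_truth_single_tp_gives_unit_ap():
    assert average_precision([1.0], [0.9], 1) == pytest.approx(1.0, abs=1e-9)


def test_ap_of_perfect_detector_is_one(rng):
    flags = np.ones(20)
    assert average_precision(flags, rng.random(20), 20) == pytest.approx(1.0)


def _synthetic_eval_set(rng, n_images=20, n_classes=3):
    """Detections = jittered truths with random scores plus false positives."""
    dets_all, truths_all = [], []
    for _ in range(n_images):
        n = int(rng.integers(1, 5))
        boxes = _random_boxes(rng, n)
        classes = rng.integers(0, n_classes, n)
        truths_all.append(np.concatenate([classes[:, None], boxes], axis=1))
        dets = []
        for c, b in zip(classes, boxes):
            if rng.random() < 0.9:
                jit = b + rng.normal(0, 2.0, 4)
                if jit[2] > jit[0] and jit[3] > jit[1]:
                    dets.append(Detection(int(c), float(rng.random()), tuple(jit)))
        for _ in range(int(rng.integers(0, 3))):
            dets.append(Detection(int(rng.integers(0, n_classes)),
                                  float(rng.random() * 0.5),
                                  tuple(_random_boxes(rng, 1)[0])))
        dets_all.append(dets)
    return dets_all, truths_all


def test_map_matches_exact_step_integration_oracle(rng):
    """101-point interpolation tracks the exact step integral within 0.01."""
    from strawdet.evaluation import _per_class_flags

    dets, truths = _synthetic_eval_set(rng)
    for thr in COCO_THRESHOLDS:
        for c in range(3):
            flags, confs, n_truth = _per_class_flags(dets, truths, c, float(thr))
            if n_truth == 0:
                continue
            ap = average_precision(flags, confs, n_truth)
            assert abs(ap - exact_step_ap(flags, confs, n_truth)) < 0.01


def test_perfect_detector_scores_one_everywhere(rng):
    truths_all, dets_all = [], []
    for _ in range(5):
        boxes = _random_boxes(rng, 3)
        classes = rng.integers(0, 3, 3)
        truths_all.append(np.concatenate([classes[:, None], boxes], axis=1))
        dets_all.append([Detection(int(c), 0.99, tuple(b))
                         for c, b in zip(classes, boxes)])
    rep = coco_map(dets_all, truths_all)
    assert rep["map50"] == pytest.approx(1.0)
    assert rep["map50_95"] == pytest.approx(1.0)
    assert rep["precision"] == pytest.approx(1.0)
    assert rep["recall"] == pytest.approx(1.0)


def test_map_monotone_in_iou_threshold_and_bounded(rng):
    dets, truths = _synthetic_eval_set(rng)
    rep = coco_map(dets, truths)
    assert 0.0 <= rep["map50_95"] <= rep["map50"] <= 1.0
    per_thr = [rep["map_per_threshold"][float(t)] for t in COCO_THRESHOLDS]
    assert all(0.0 <= v <= 1.0 for v in per_thr)


def test_ap_invariant_under_confidence_rescaling(rng):
    dets, truths = _synthetic_eval_set(rng, n_images=8)
    rep1 = coco_map(dets, truths)
    scaled = [[Detection(d.class_id, d.confidence * 0.5, d.box) for d in ds]
              for ds in dets]
    rep2 = coco_map(scaled, truths)
    assert rep1["map50"] == pytest.approx(rep2["map50"])
    assert rep1["map50_95"] == pytest.approx(rep2["map50_95"])


def test_class_without_truths_is_excluded_with_warning(rng, caplog):
    truths = [np.array([[0, 0, 0, 10, 10]], float)]
    dets = [[Detection(0, 0.9, (0, 0, 10, 10)), Detection(2, 0.8, (1, 1, 9, 9))]]
    with caplog.at_level("WARNING"):
        rep = coco_map(dets, truths)
    assert rep["map50"] == pytest.approx(1.0)
    assert any("no ground truths" in r.message for r in caplog.records)


def test_mean_ap_is_unweighted_mean():
    assert mean_ap({0: 0.5, 1: 1.0}) == pytest.approx(0.75)
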