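"""Decoding raw head outputs into pixel-space detections.

The box branch predicts, for each anchor point and box side, a discrete
distribution over ``reg_max`` offsets; its expectation (in stride units)
gives the distance from the anchor to that side. Class logits pass through a
sigmoid. Decoded boxes are filtered by confidence and pruned by class-wise
greedy non-maximum suppression.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import Detect
from .detection import Detection


def make_anchors(shapes, strides, offset: float = 0.5):
    """Anchor centers in pixels for each (H, W) level; returns (A,2) and (A,)."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strs.append(np.full(h * w, s, dtype=np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(strs)


def flatten_outputs(raw, nc: int):
    """Per-level (B, 4*reg_max+nc, H, W) maps -> (B, A, 4*reg_max) and (B, A, nc)."""
    dist, cls, shapes = [], [], []
    r4 = 4 * Detect.REG_MAX
    for o in raw:
        arr = o.data if isinstance(o, nn.Tensor) else o
        B, C, H, W = arr.shape
        flat = arr.reshape(B, C, H * W).transpose(0, 2, 1)
        dist.append(flat[:, :, :r4])
        cls.append(flat[:, :, r4:])
        shapes.append((H, W))
    return np.concatenate(dist, axis=1), np.concatenate(cls, axis=1), shapes


def dist_to_boxes(dist: np.ndarray, anchors: np.ndarray, strides: np.ndarray):
    """Distribution logits (B, A, 4*reg_max) -> boxes (B, A, 4) in pixels."""
    B, A, _ = dist.shape
    r = Detect.REG_MAX
    logits = dist.reshape(B, A, 4, r)
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    ltrb = (p @ np.arange(r, dtype=np.float32)) * strides[None, :, None]
    x1y1 = anchors[None] - ltrb[:, :, :2]
    x2y2 = anchors[None] + ltrb[:, :, 2:]
    return np.concatenate([x1y1, x2y2], axis=-1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy suppression; returns kept indices sorted by descending score."""
    order = np.argsort(-scores, kind="stable")
    x1, y1, x2, y2 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    areas = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(x1[i], x1[rest])
        yy1 = np.maximum(y1[i], y1[rest])
        xx2 = np.minimum(x2[i], x2[rest])
        yy2 = np.minimum(y2[i], y2[rest])
        inter = np.maximum(xx2 - xx1, 0) * np.maximum(yy2 - yy1, 0)
        iou = inter / np.maximum(areas[i] + areas[rest] - inter, 1e-12)
        order = rest[iou <= iou_thresh]
    return keep


def predict(model, image: np.ndarray, conf_thresh: float | None = None,
            iou_thresh: float | None = None, max_det: int = 300) -> list[Detection]:
    """Run the detector on one HWC RGB image (uint8 or float in [0,1])."""
    cfg = model.cfg
    conf_thresh = cfg.conf_thresh if conf_thresh is None else conf_thresh
    iou_thresh = cfg.iou_thresh if iou_thresh is None else iou_thresh
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HWC RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    H0, W0 = img.shape[:2]
    # pad to a multiple of 32 (boxes stay in the original pixel frame)
    H = int(np.ceil(H0 / 32) * 32)
    W = int(np.ceil(W0 / 32) * 32)
    if (H, W) != (H0, W0):
        img = np.pad(img, ((0, H - H0), (0, W - W0), (0, 0)))
    x = img.transpose(2, 0, 1)[None].astype(np.float32)
    with nn.no_grad():
        raw = model.forward(x)
    dist, cls_logits, shapes = flatten_outputs(raw, cfg.num_classes)
    anchors, strides = make_anchors(shapes, model.STRIDES)
    boxes = dist_to_boxes(dist, anchors, strides)[0]
    from scipy.special import expit
    scores = expit(cls_logits[0])

    cls_id = scores.argmax(axis=1)
    conf = scores[np.arange(len(cls_id)), cls_id]
    m = conf >= conf_thresh
    boxes, conf, cls_id = boxes[m], conf[m], cls_id[m]
    boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, W0)
    boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, H0)

    out: list[Detection] = []
    for c in np.unique(cls_id):
        sel = np.flatnonzero(cls_id == c)
        keep = nms(boxes[sel], conf[sel], iou_thresh)
        for i in keep:
            b = boxes[sel[i]]
            if b[2] - b[0] <= 0 or b[3] - b[1] <= 0:
                continue
            out.append(Detection(class_id=int(c), confidence=float(conf[sel[i]]),
                                 box=(float(b[0]), float(b[1]),
                                      float(b[2]), float(b[3]))))
    out.sort(key=lambda d: -d.confidence)
    return out[:max_det]
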