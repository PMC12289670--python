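"""Training: task-aligned assignment, composite detection loss, Adam + cosine.

The loss is the standard single-stage recipe the architecture inherits:
binary cross-entropy on class logits, a complete-IoU box loss, and a
distribution-focal loss on the discretized side offsets, with task-aligned
assignment (alignment metric ``cls^alpha * IoU^beta``, top-k candidates per
ground truth restricted to anchors inside the box). Per-epoch augmentation
probabilities come from the warmup schedule when enabled.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from . import nn
from .augment import apply_augmentations
from .blocks import Detect
from .config import TrainConfig
from .data import DatasetManifest, labels_to_corners
from .evaluation import coco_map, iou_matrix
from .postprocess import make_anchors, predict
from .schedule import ScheduleState, effective_plan

log = logging.getLogger(__name__)

REG_MAX = Detect.REG_MAX


# ---------------------------------------------------------------------------
# optimizer and LR schedule
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


def cosine_lr(epoch: int, total: int, lr0: float, final_frac: float = 0.01) -> float:
    """Cosine annealing from ``lr0`` to ``final_frac * lr0``."""
    t = min(max(epoch / max(total - 1, 1), 0.0), 1.0)
    return lr0 * (final_frac + (1 - final_frac) * 0.5 * (1 + math.cos(math.pi * t)))


# ---------------------------------------------------------------------------
# task-aligned assignment (pure numpy; gradients do not flow through it)
# ---------------------------------------------------------------------------

def task_aligned_assign(pred_scores: np.ndarray, pred_boxes: np.ndarray,
                        anchors: np.ndarray, gt_cls: np.ndarray,
                        gt_boxes: np.ndarray, topk: int = 10,
                        alpha: float = 0.5, beta: float = 6.0):
    """Assign anchors of one image to ground truths.

    Returns ``(fg_mask (A,), gt_idx (A,), target_scores (A, nc))``.
    """
    A, nc = pred_scores.shape
    fg = np.zeros(A, dtype=bool)
    gt_idx = np.full(A, -1, dtype=int)
    tscores = np.zeros((A, nc), dtype=np.float32)
    M = len(gt_boxes)
    if M == 0:
        return fg, gt_idx, tscores

    ious = iou_matrix(pred_boxes, gt_boxes)                     # (A, M)
    cls_p = pred_scores[:, gt_cls]                              # (A, M)
    metric = (cls_p ** alpha) * (ious ** beta)
    inside = ((anchors[:, 0:1] > gt_boxes[None, :, 0]) &
              (anchors[:, 0:1] < gt_boxes[None, :, 2]) &
              (anchors[:, 1:2] > gt_boxes[None, :, 1]) &
              (anchors[:, 1:2] < gt_boxes[None, :, 3]))
    metric = np.where(inside, metric, 0.0)

    cand = np.zeros_like(metric, dtype=bool)
    k = min(topk, A)
    top = np.argpartition(-metric, k - 1, axis=0)[:k]           # (k, M)
    cand[top, np.arange(M)[None, :]] = True
    cand &= metric > 0.0

    # a truth smaller than the anchor spacing may contain no anchor center;
    # fall back to the nearest anchor so every truth stays learnable
    for j in np.flatnonzero(cand.sum(axis=0) == 0):
        ctr = (gt_boxes[j, :2] + gt_boxes[j, 2:]) / 2
        i = int(((anchors - ctr) ** 2).sum(axis=1).argmin())
        cand[i, j] = True
        metric[i, j] = max(metric[i, j], 1e-6)

    # an anchor claimed by several truths goes to the one with the best metric
    m_masked = np.where(cand, metric, -1.0)
    best_gt = m_masked.argmax(axis=1)
    fg = m_masked[np.arange(A), best_gt] > 0
    gt_idx[fg] = best_gt[fg]

    # normalized target scores (per-truth max alignment scaled by max IoU)
    for j in range(M):
        sel = np.flatnonzero(fg & (gt_idx == j))
        if sel.size == 0:
            continue
        amax = metric[sel, j].max()
        imax = ious[sel, j].max()
        tscores[sel, gt_cls[j]] = metric[sel, j] * imax / (amax + 1e-9)
    return fg, gt_idx, tscores


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _flatten_raw(raw):
    """Raw per-level Tensors -> (dist (B,A,4*reg_max), cls (B,A,nc)) Tensors."""
    flats = []
    for o in raw:
        B, C, H, W = o.shape
        flats.append(o.reshape(B, C, H * W).transpose(0, 2, 1))
    full = nn.cat(flats, axis=1)
    r4 = 4 * REG_MAX
    dist = nn.narrow(full, 2, 0, r4)
    cls = nn.narrow(full, 2, r4, full.shape[2] - r4)
    return dist, cls


def _decode_boxes(dist: nn.Tensor, anchors: np.ndarray, strides: np.ndarray):
    """Differentiable expectation decode: (B,A,4*reg_max) -> (B,A,4) pixels."""
    B, A, _ = dist.shape
    p = dist.reshape(B, A, 4, REG_MAX).softmax(axis=-1)
    proj = nn.Tensor(np.arange(REG_MAX, dtype=np.float32).reshape(REG_MAX, 1))
    ltrb = (p @ proj).reshape(B, A, 4) * nn.Tensor(strides.reshape(1, A, 1))
    anc = nn.Tensor(np.concatenate([anchors, anchors], axis=1)[None])  # (1,A,4)
    sign = nn.Tensor(np.array([-1, -1, 1, 1], dtype=np.float32).reshape(1, 1, 4))
    return anc + ltrb * sign


def _ciou(pred: nn.Tensor, gt: np.ndarray) -> nn.Tensor:
    """Complete IoU between (F,4) predictions and fixed ground-truth boxes."""
    eps = 1e-7
    px1, py1, px2, py2 = (nn.narrow(pred, 1, i, 1) for i in range(4))
    g = np.asarray(gt, dtype=np.float32)
    gx1, gy1, gx2, gy2 = (nn.Tensor(g[:, i:i + 1]) for i in range(4))
    iw = px2.minimum(gx2) - px1.maximum(gx1)
    ih = py2.minimum(gy2) - py1.maximum(gy1)
    inter = iw.clamp_min(0.0) * ih.clamp_min(0.0)
    w1, h1 = px2 - px1, py2 - py1
    w2, h2 = gx2 - gx1, gy2 - gy1
    union = w1 * h1 + w2 * h2 - inter + eps
    iou = inter / union
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - gx1 - gx2).pow(2.0) + (py1 + py2 - gy1 - gy2).pow(2.0)) * 0.25
    v = (w2 / (h2 + eps)).atan() - (w1 / (h1 + eps)).atan()
    v = v * v * (4.0 / math.pi ** 2)
    with nn.no_grad():
        alpha = v.data / (v.data - iou.data + (1 + eps))
    return iou - rho2 / c2 - v * nn.Tensor(alpha)


def compute_loss(raw, targets_px, model, lambda_box: float = 7.5,
                 lambda_cls: float = 0.5, lambda_dfl: float = 1.5):
    """Composite detection loss for one batch.

    ``targets_px`` is a list (len B) of (M,5) arrays ``(class, x1, y1, x2, y2)``
    in pixels. Returns ``(total_loss Tensor, parts dict)``.
    """
    nc = model.cfg.num_classes
    dist, cls_logits = _flatten_raw(raw)
    shapes = [(o.shape[2], o.shape[3]) for o in raw]
    anchors, strides = make_anchors(shapes, model.STRIDES)
    B, A, _ = cls_logits.shape
    pboxes = _decode_boxes(dist, anchors, strides)

    with nn.no_grad():
        from scipy.special import expit
        scores_np = expit(cls_logits.data)
    tscores = np.zeros((B, A, nc), dtype=np.float32)
    fg_all, gt_box_all = [], []
    for b in range(B):
        t = np.asarray(targets_px[b], dtype=np.float32).reshape(-1, 5)
        fg, gt_idx, ts = task_aligned_assign(
            scores_np[b], pboxes.data[b], anchors,
            t[:, 0].astype(int), t[:, 1:])
        tscores[b] = ts
        fg_all.append(fg)
        gt_box_all.append(t[gt_idx[fg], 1:])
    fg_mask = np.stack(fg_all)                       # (B, A)
    ts_sum = max(float(tscores.sum()), 1.0)

    loss_cls = nn.bce_with_logits(cls_logits, tscores) * (1.0 / ts_sum)

    flat_idx = np.flatnonzero(fg_mask.reshape(-1))
    if flat_idx.size:
        gt_boxes = np.concatenate(gt_box_all, axis=0)
        w = tscores.reshape(B * A, nc)[flat_idx].sum(axis=1)     # (F,)
        pb = pboxes.reshape(B * A, 4).take(flat_idx, axis=0)
        ciou = _ciou(pb, gt_boxes)
        wt = nn.Tensor(w.reshape(-1, 1))
        loss_box = ((1.0 - ciou) * wt).sum() * (1.0 / ts_sum)

        # distribution-focal targets in stride units
        str_fg = np.tile(strides, B)[flat_idx]
        anc_fg = np.tile(anchors, (B, 1))[flat_idx]
        ltrb = np.concatenate([(anc_fg - gt_boxes[:, :2]),
                               (gt_boxes[:, 2:] - anc_fg)], axis=1)
        ltrb = np.clip(ltrb / str_fg[:, None], 0, REG_MAX - 1 - 0.01)
        tl = np.floor(ltrb).astype(int)
        wl = (tl + 1).astype(np.float32) - ltrb
        logp = dist.reshape(B * A, 4, REG_MAX).take(flat_idx, axis=0) \
                   .log_softmax(axis=-1)
        onehot_l = np.eye(REG_MAX, dtype=np.float32)[tl]          # (F,4,R)
        onehot_r = np.eye(REG_MAX, dtype=np.float32)[tl + 1]
        w_mat = onehot_l * wl[..., None] + onehot_r * (1 - wl)[..., None]
        per_side = -(logp * nn.Tensor(w_mat))
        loss_dfl = (per_side.sum(axis=2).mean(axis=1, keepdims=True)
                    * nn.Tensor(w.reshape(-1, 1))).sum() * (1.0 / ts_sum)
    else:
        loss_box = nn.Tensor(0.0)
        loss_dfl = nn.Tensor(0.0)

    total = loss_box * lambda_box + loss_cls * lambda_cls + loss_dfl * lambda_dfl
    parts = {"box": float(loss_box.data), "cls": float(loss_cls.data),
             "dfl": float(loss_dfl.data), "total": float(total.data),
             "num_fg": int(fg_mask.sum())}
    return total, parts


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _load_split_arrays(manifest: DatasetManifest, split: str):
    images, labels = [], []
    for img, lab, _stem in manifest.load_split(split):
        images.append(img)
        labels.append(lab)
    return images, labels


def evaluate_model(model, images, labels_norm, conf_thresh: float = 0.001):
    """mAP report of a model over in-memory images with normalized labels."""
    dets, truths = [], []
    for img, lab in zip(images, labels_norm):
        H, W = img.shape[:2]
        dets.append(predict(model, img, conf_thresh=conf_thresh))
        truths.append(labels_to_corners(lab, W, H))
    return coco_map(dets, truths)


def train(model, dataset, cfg: TrainConfig, val_interval: int = 10):
    """Train in place; returns ``(model, history)``.

    ``dataset`` is a :class:`DatasetManifest` (or path to one). Augmentation
    probabilities follow the warmup schedule when the model config enables it,
    otherwise base probabilities apply from epoch 0. The checkpoint with the
    best validation mAP@0.5:0.95 is restored at the end when a validation
    split exists.
    """
    if not isinstance(dataset, DatasetManifest):
        dataset = DatasetManifest.load(dataset)
    images, labels = _load_split_arrays(dataset, "train")
    if not images:
        raise ValueError("training split is empty")
    val_images, val_labels = _load_split_arrays(dataset, "val")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.lr)
    n = len(images)
    history = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        if model.cfg.use_warmup:
            plan = effective_plan(ScheduleState(epoch, cfg.epochs), cfg.augment)
        else:
            plan = effective_plan(ScheduleState(cfg.epochs, cfg.epochs), cfg.augment)
        if (cfg.close_mosaic_epochs
                and epoch >= cfg.epochs - cfg.close_mosaic_epochs):
            probs = dict(plan.effective_probabilities)
            probs["mosaic"] = 0.0
            plan = type(plan)(plan.warmup_factor, plan.base_probabilities, probs)
        opt.lr = cosine_lr(epoch, cfg.epochs, cfg.lr, cfg.cosine_final_lr_frac)

        order = rng.permutation(n)
        fired: list = []
        epoch_parts = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            batch_x, batch_t = [], []
            for i in idxs:
                extras = None
                if plan.effective_probabilities.get("mosaic", 0) > 0 and n >= 4:
                    pick = rng.choice(n, 3, replace=False)
                    extras = [(images[j], labels[j]) for j in pick]
                aug_seed = int(rng.integers(2 ** 31))
                img, lab = apply_augmentations(
                    images[i], labels[i], plan, aug_seed,
                    magnitudes=cfg.augment_magnitudes,
                    extra_samples=extras, fired=fired)
                if img.dtype == np.uint8:
                    img = img.astype(np.float32) / 255.0
                H, W = img.shape[:2]
                batch_x.append(img.transpose(2, 0, 1))
                batch_t.append(labels_to_corners(lab, W, H))
            x = np.stack(batch_x).astype(np.float32)
            raw = model.forward(x)
            loss, parts = compute_loss(raw, batch_t, model)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {parts}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip_norm:
                clip_grad_norm(model.parameters(), cfg.grad_clip_norm)
            opt.step()
            for k in epoch_parts:
                epoch_parts[k] += parts[k]
            n_batches += 1

        rec = {k: v / n_batches for k, v in epoch_parts.items()}
        rec.update(epoch=epoch, lr=opt.lr, warmup_p=plan.warmup_factor,
                   augmentations_fired=len(fired))
        if val_images and (epoch % val_interval == val_interval - 1
                           or epoch == cfg.epochs - 1):
            report = evaluate_model(model, val_images, val_labels)
            rec["val_map50"] = report["map50"]
            rec["val_map50_95"] = report["map50_95"]
            if report["map50_95"] > best[0]:
                best = (report["map50_95"], model.state_dict())
        history.append(rec)
        log.info("epoch %d: loss %.4f (box %.3f cls %.3f dfl %.3f) "
                 "P=%.2f lr=%.2e fired=%d", epoch, rec["total"], rec["box"],
                 rec["cls"], rec["dfl"], rec["warmup_p"], rec["lr"],
                 rec["augmentations_fired"])
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history
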