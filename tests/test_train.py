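"""Training loop: determinism, schedule wiring, loss sanity."""

import numpy as np
import pytest

from strawdet import ModelConfig, TrainConfig, build_model
from strawdet import nn
from strawdet.train import (_ciou, clip_grad_norm, compute_loss, cosine_lr,
                            task_aligned_assign, train)

NO_AUG = {"mosaic": 0.0, "fliplr": 0.0, "hsv": 0.0, "translate_scale": 0.0}


def test_cosine_lr_endpoints():
    assert cosine_lr(0, 100, 0.01) == pytest.approx(0.01)
    assert cosine_lr(99, 100, 0.01) == pytest.approx(0.0001)
    mid = cosine_lr(50, 100, 0.01)
    assert 0.0001 < mid < 0.01


def test_ciou_identical_boxes_is_one(rng):
    b = np.array([[10, 10, 30, 40]], np.float32)
    out = _ciou(nn.Tensor(b), b)
    assert out.data[0, 0] == pytest.approx(1.0, abs=1e-5)


def test_assigner_covers_every_truth(rng):
    """Each ground truth receives at least one anchor, even sub-stride ones."""
    A = 144
    anchors = np.stack(np.meshgrid(np.arange(12) * 8 + 4,
                                   np.arange(12) * 8 + 4), -1).reshape(-1, 2).astype(float)
    scores = rng.random((A, 4)).astype(np.float32) * 1e-3
    pred_boxes = np.concatenate([anchors - 30, anchors + 30], axis=1)
    gt_boxes = np.array([[5, 5, 9, 9],          # 4 px box between anchor centers
                         [40, 40, 80, 80]], float)
    fg, gt_idx, ts = task_aligned_assign(scores, pred_boxes, anchors,
                                         np.array([0, 1]), gt_boxes)
    assert set(gt_idx[fg]) == {0, 1}
    assert ts.sum() > 0


def test_loss_runs_and_is_finite(tiny_model, rng):
    x = rng.random((2, 3, 64, 64)).astype(np.float32)
    raw = tiny_model.forward(x)
    targets = [np.array([[0, 10, 10, 30, 30]], np.float32),
               np.zeros((0, 5), np.float32)]
    loss, parts = compute_loss(raw, targets, tiny_model)
    assert np.isfinite(parts["total"])
    assert parts["num_fg"] > 0
    loss.backward()
    grads = [p.grad for p in tiny_model.parameters() if p.grad is not None]
    assert grads and all(np.isfinite(g).all() for g in grads)
    tiny_model.zero_grad()


def test_clip_grad_norm_scales_down(rng):
    p = nn.Parameter(np.zeros(4, np.float32))
    p.grad = np.full(4, 10.0, np.float32)
    clip_grad_norm([p], 1.0)
    assert np.linalg.norm(p.grad) == pytest.approx(1.0)


def _short_cfg(**kw):
    base = dict(epochs=1, batch_size=4, image_size=64, lr=1e-3, seed=0,
                augment=dict(NO_AUG))
    base.update(kw)
    return TrainConfig(**base)


def test_identical_seeds_identical_first_epoch_loss(tiny_dataset):
    losses = []
    for _ in range(2):
        model = build_model(ModelConfig(scale="n", num_classes=4), seed=1)
        _, hist = train(model, tiny_dataset, _short_cfg(), val_interval=1000)
        losses.append(hist[0]["total"])
    assert losses[0] == losses[1]


def test_warmup_epoch_zero_fires_no_augmentations(tiny_dataset):
    model = build_model(ModelConfig(scale="n", num_classes=4, use_warmup=True),
                        seed=1)
    cfg = _short_cfg(augment={"fliplr": 1.0, "hsv": 1.0})
    _, hist = train(model, tiny_dataset, cfg, val_interval=1000)
    assert hist[0]["warmup_p"] == 0.0
    assert hist[0]["augmentations_fired"] == 0


def test_without_warmup_augmentations_fire_from_epoch_zero(tiny_dataset):
    model = build_model(ModelConfig(scale="n", num_classes=4), seed=1)
    cfg = _short_cfg(augment={"fliplr": 1.0})
    _, hist = train(model, tiny_dataset, cfg, val_interval=1000)
    assert hist[0]["warmup_p"] == 1.0
    assert hist[0]["augmentations_fired"] == 8   # every train sample flipped


def test_empty_dataset_raises(tmp_path):
    from strawdet.data import DatasetManifest

    man = DatasetManifest(root=tmp_path)
    man.save()
    model = build_model(ModelConfig(scale="n", num_classes=4), seed=1)
    with pytest.raises(ValueError):
        train(model, man, _short_cfg())
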