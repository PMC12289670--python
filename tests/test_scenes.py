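"""Synthetic scene generator: geometry, depth consistency, dataset layout."""

import numpy as np
import pytest

from strawdet.data import DatasetManifest, labels_to_corners, read_yolo_labels
from strawdet.rgbd import CameraIntrinsics, box_depth
from strawdet.scenes import (DEFAULT_INTRINSICS, SceneObject, SceneSpec,
                             make_dataset, render_scene)


def test_projected_size_follows_similar_triangles():
    # radius 2 cm at Z=50 with fx=600 -> 24 px; disc centered at principal point
    spec = SceneSpec(objects=[SceneObject("ripe", (0.0, 0.0, 50.0), 2.0)], seed=0)
    _, _, labels, boxes = render_scene(spec)
    _, x1, y1, x2, y2 = boxes[0]
    assert (x2 - x1) / 2 == pytest.approx(24, abs=1.5)
    assert (x1 + x2) / 2 == pytest.approx(320.5, abs=1.0)
    assert (y1 + y2) / 2 == pytest.approx(320.5, abs=1.0)


def test_occlusion_keeps_nearest_depth():
    spec = SceneSpec(objects=[SceneObject("ripe", (0.0, 0.0, 50.0), 2.0),
                              SceneObject("unripe", (0.5, 0.0, 40.0), 2.0)], seed=0)
    _, depth_mm, _, _ = render_scene(spec)
    assert depth_mm[320, 326] == 400      # overlap region shows the nearer Z


def test_render_deterministic():
    spec = SceneSpec(objects=[SceneObject("flower", (2.0, -3.0, 45.0), 1.5)], seed=9)
    a = render_scene(spec)
    b = render_scene(spec)
    assert all(np.array_equal(x, y) for x, y in zip(a[:3], b[:3]))


def test_out_of_frame_object_rejected():
    spec = SceneSpec(objects=[SceneObject("ripe", (40.0, 0.0, 35.0), 2.0)], seed=0)
    with pytest.raises(ValueError, match="object 0"):
        render_scene(spec)


def test_depth_label_consistency():
    """Median depth in each box's central crop equals the object's Z."""
    spec = SceneSpec(objects=[SceneObject("ripe", (-5.0, 4.0, 55.0), 2.2),
                              SceneObject("unripe", (8.0, -6.0, 40.0), 1.8)], seed=2)
    _, depth_mm, _, boxes = render_scene(spec)
    for obj, row in zip(spec.objects, boxes):
        z = box_depth(row[1:], depth_mm, DEFAULT_INTRINSICS)
        assert z == pytest.approx(obj.position_cm[2], abs=0.1)


@pytest.fixture(scope="module")
def dataset100(tmp_path_factory):
    root = tmp_path_factory.mktemp("ds100")
    return make_dataset(100, seed=5, out_dir=root, image_size=64,
                        objects_per_image=(4, 4), depth_range_cm=(8, 20))


def test_split_ratio_7_2_1(dataset100):
    counts = {k: len(v) for k, v in dataset100.splits.items()}
    assert counts == {"train": 70, "val": 20, "test": 10}


def test_labels_normalized_and_roundtrip(dataset100):
    man = DatasetManifest.load(dataset100.root)
    n_checked = 0
    for split in ("train", "val", "test"):
        for stem in man.splits[split][:5]:
            lab = read_yolo_labels(man.label_path(split, stem))
            assert (lab[:, 1:] >= 0).all() and (lab[:, 1:] <= 1).all()
            # normalized -> pixel -> normalized round trip within 1 px
            px = labels_to_corners(lab, 64, 64)
            assert ((px[:, 3] - px[:, 1]) > 0).all()
            back = np.round(px[:, 1:]).astype(int)
            assert np.abs(px[:, 1:] - back).max() <= 0.51
            n_checked += len(lab)
    assert n_checked > 0


def test_class_mix_within_binomial_bound(dataset100):
    """Uniform class mix over 400 objects: each class within 3 sigma of 100."""
    man = dataset100
    counts = np.zeros(4)
    for split in ("train", "val", "test"):
        for stem in man.splits[split]:
            lab = read_yolo_labels(man.label_path(split, stem))
            for c in lab[:, 0]:
                counts[int(c)] += 1
    n = counts.sum()
    sigma = np.sqrt(n * 0.25 * 0.75)
    assert np.abs(counts - n * 0.25).max() < 3 * sigma


def test_make_dataset_deterministic(tmp_path):
    import hashlib

    def tree_hash(root):
        h = hashlib.sha256()
        for p in sorted(root.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    a, b = tmp_path / "a", tmp_path / "b"
    make_dataset(10, seed=3, out_dir=a, image_size=64)
    make_dataset(10, seed=3, out_dir=b, image_size=64)
    assert tree_hash(a) == tree_hash(b)


def test_make_dataset_rejects_tiny_n(tmp_path):
    with pytest.raises(ValueError):
        make_dataset(5, out_dir=tmp_path / "x")
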