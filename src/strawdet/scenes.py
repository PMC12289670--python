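"""Synthetic strawberry scenes with exact labels, depth maps and 3-D truth.

Objects of the four growth-stage classes (bud, flower, under-ripe fruit,
ripe fruit) are parametric colored shapes placed at known camera-frame 3-D
positions and drawn at their pinhole-projected location and size over a
cluttered leaf-green background. The depth map carries each object's Z
(nearest object wins per pixel) in millimeters over a far background plane,
and labels are the exact projected boxes in YOLO-normalized format — so
detector training, metric computation and RGB-D localization can all be
exercised against known ground truth without any external data.

The emulated acquisition geometry: 640 x 640 frames, object distances
0.3-0.8 m, four growth stages, and a 7:2:1 train/val/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (CLASS_NAMES, DatasetManifest, corners_to_labels, save_image,
                   write_yolo_labels)
from .rgbd import CameraIntrinsics, project, write_depth

DEFAULT_INTRINSICS = CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=320.0,
                                      depth_scale=0.1)
BACKGROUND_DEPTH_CM = 150.0
DEPTH_RANGE_CM = (30.0, 80.0)       # emulated shooting distance 0.3-0.8 m

# physical radii in cm per class
CLASS_RADIUS = {"bud": (0.5, 0.8), "flower": (1.0, 1.6),
                "unripe": (1.2, 2.2), "ripe": (1.5, 2.5)}
# factor by which the drawn shape may exceed the core radius (petals etc.)
CLASS_EXTENT = {"bud": 1.6, "flower": 1.7, "unripe": 1.0, "ripe": 1.0}


@dataclass(frozen=True)
class SceneObject:
    class_name: str
    position_cm: tuple      # (X, Y, Z) camera frame
    radius_cm: float

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.position_cm[2] <= 0:
            raise ValueError("objects must be in front of the camera (Z > 0)")

    @property
    def class_id(self) -> int:
        return CLASS_NAMES.index(self.class_name)


@dataclass
class SceneSpec:
    objects: list
    image_size: int = 640
    intrinsics: CameraIntrinsics = field(default_factory=lambda: DEFAULT_INTRINSICS)
    clutter_density: float = 40e-6      # clutter ellipses per pixel
    seed: int = 0


def _grid(n: int):
    y, x = np.mgrid[0:n, 0:n]
    return x.astype(np.float32), y.astype(np.float32)


def _disc(x, y, u, v, r):
    return (x - u) ** 2 + (y - v) ** 2 <= r * r


def _ellipse(x, y, u, v, a, b, theta):
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - u) * ct + (y - v) * st
    yr = -(x - u) * st + (y - v) * ct
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _draw_background(n: int, density: float, rng: np.random.Generator):
    img = np.empty((n, n, 3), dtype=np.float32)
    base = np.array([0.32, 0.24, 0.18])     # soil brown
    img[...] = base + rng.normal(0, 0.02, size=(n, n, 3))
    x, y = _grid(n)
    for _ in range(max(1, int(density * n * n))):
        u, v = rng.uniform(0, n, 2)
        a, b = rng.uniform(0.02 * n, 0.08 * n, 2)
        theta = rng.uniform(0, np.pi)
        shade = rng.uniform(0.6, 1.1)
        leaf = np.array([0.13, 0.42, 0.15]) * shade
        m = _ellipse(x, y, u, v, a, b, theta)
        img[m] = 0.25 * img[m] + 0.75 * leaf
    return np.clip(img, 0, 1)


def _draw_object(img, x, y, obj: SceneObject, u, v, pr, rng):
    """Paint one object; returns its full mask (pre-occlusion)."""
    cls = obj.class_name
    if cls == "bud":
        mask = np.zeros(img.shape[:2], dtype=bool)
        for ang in (0.5, 2.6, 4.4):
            du, dv = 0.55 * pr * np.cos(ang), 0.55 * pr * np.sin(ang)
            m = _disc(x, y, u + du, v + dv, 0.65 * pr)
            img[m] = np.array([0.75, 0.82, 0.62]) * rng.uniform(0.9, 1.05)
            mask |= m
    elif cls == "flower":
        mask = np.zeros(img.shape[:2], dtype=bool)
        for i in range(5):
            ang = 2 * np.pi * i / 5 + 0.3
            du, dv = 0.85 * pr * np.cos(ang), 0.85 * pr * np.sin(ang)
            m = _ellipse(x, y, u + du, v + dv, 0.62 * pr, 0.45 * pr, ang)
            img[m] = np.array([0.96, 0.96, 0.92]) * rng.uniform(0.92, 1.0)
            mask |= m
        m = _disc(x, y, u, v, 0.42 * pr)
        img[m] = [0.95, 0.83, 0.18]
        mask |= m
    elif cls == "unripe":
        mask = _disc(x, y, u, v, pr)
        t = np.clip((y - (v - pr)) / max(2 * pr, 1e-6), 0, 1)
        grad = (np.array([0.35, 0.62, 0.22])[None, None] * (1 - t[..., None])
                + np.array([0.85, 0.45, 0.35])[None, None] * t[..., None])
        img[mask] = grad[mask]
    elif cls == "ripe":
        mask = _disc(x, y, u, v, pr)
        img[mask] = [0.80, 0.08, 0.10]
        for _ in range(max(3, int(pr))):
            su = u + rng.uniform(-0.8, 0.8) * pr
            sv = v + rng.uniform(-0.8, 0.8) * pr
            m = _disc(x, y, su, sv, max(0.06 * pr, 1.0)) & mask
            img[m] = [0.45, 0.05, 0.06]
    else:   # pragma: no cover
        raise ValueError(cls)
    return mask


def render_scene(spec: SceneSpec):
    """Render (rgb uint8, depth uint16 mm, labels Nx5 normalized, boxes px).

    Raises if any object's projected shape leaves the frame; deterministic
    (byte-identical) for a fixed spec.
    """
    n = spec.image_size
    K = spec.intrinsics
    rng = np.random.default_rng(spec.seed)
    img = _draw_background(n, spec.clutter_density, rng)
    depth_cm = np.full((n, n), BACKGROUND_DEPTH_CM, dtype=np.float32)
    x, y = _grid(n)

    rows = []
    # far-to-near so nearer objects overpaint (painter's algorithm)
    order = sorted(range(len(spec.objects)),
                   key=lambda i: -spec.objects[i].position_cm[2])
    boxes_px = [None] * len(spec.objects)
    for i in order:
        obj = spec.objects[i]
        X, Y, Z = obj.position_cm
        u, v = project(X, Y, Z, K)
        pr = K.fx * obj.radius_cm / Z
        ext = pr * CLASS_EXTENT[obj.class_name]
        if not (ext <= u <= n - 1 - ext and ext <= v <= n - 1 - ext):
            raise ValueError(
                f"object {i} ({obj.class_name} at {obj.position_cm}) projects "
                f"outside the {n}x{n} frame")
        mask = _draw_object(img, x, y, obj, u, v, pr, rng)
        if not mask.any():
            raise ValueError(
                f"object {i} ({obj.class_name} at {obj.position_cm}) projects "
                f"to less than one pixel")
        depth_cm[mask] = np.minimum(depth_cm[mask], Z)
        ys, xs = np.nonzero(mask)
        boxes_px[i] = (obj.class_id, xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
    for b in boxes_px:
        rows.append(b)
    boxes_px = np.array(rows, dtype=float).reshape(-1, 5)
    labels = corners_to_labels(boxes_px, n, n)
    rgb = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    depth_mm = np.round(depth_cm / K.depth_scale).astype(np.uint16)
    return rgb, depth_mm, labels, boxes_px


def sample_scene(rng: np.random.Generator, n_objects: int,
                 class_mix: dict | None = None, image_size: int = 640,
                 intrinsics: CameraIntrinsics | None = None,
                 clutter_density: float = 40e-6,
                 depth_range_cm: tuple = DEPTH_RANGE_CM) -> SceneSpec:
    """Draw a random in-frame, lightly-overlapping scene specification."""
    K = intrinsics or _scaled_intrinsics(image_size)
    if class_mix is None:
        class_mix = {c: 0.25 for c in CLASS_NAMES}
    names = list(class_mix)
    probs = np.array([class_mix[c] for c in names], dtype=float)
    probs /= probs.sum()
    objects, centers = [], []
    for _ in range(n_objects):
        # class is drawn once so the realized mix stays multinomial even
        # though placement below is rejection-sampled
        cls = names[rng.choice(len(names), p=probs)]
        for _attempt in range(40):
            r = rng.uniform(*CLASS_RADIUS[cls])
            Z = rng.uniform(*depth_range_cm)
            pr = K.fx * r / Z
            if pr < 2.0:        # below sensor resolution at this frame size
                continue
            ext = pr * CLASS_EXTENT[cls] + 2
            if 2 * ext >= image_size - 2:
                continue
            u = rng.uniform(ext, image_size - 1 - ext)
            v = rng.uniform(ext, image_size - 1 - ext)
            if any((u - uu) ** 2 + (v - vv) ** 2 < (pr + rr) ** 2
                   for uu, vv, rr in centers):
                continue
            X = (u - K.cx) * Z / K.fx
            Y = (v - K.cy) * Z / K.fy
            objects.append(SceneObject(cls, (X, Y, Z), r))
            centers.append((u, v, pr))
            break
    return SceneSpec(objects=objects, image_size=image_size, intrinsics=K,
                     clutter_density=clutter_density,
                     seed=int(rng.integers(2 ** 31)))


def _scaled_intrinsics(image_size: int) -> CameraIntrinsics:
    s = image_size / 640.0
    K = DEFAULT_INTRINSICS
    return CameraIntrinsics(fx=K.fx * s, fy=K.fy * s, cx=K.cx * s, cy=K.cy * s,
                            depth_scale=K.depth_scale)


def make_dataset(n_images: int, class_mix: dict | None = None, seed: int = 0,
                 out_dir="dataset", image_size: int = 640,
                 objects_per_image: tuple = (1, 4),
                 clutter_density: float = 40e-6,
                 depth_range_cm: tuple = DEPTH_RANGE_CM,
                 split_ratio: tuple = (0.7, 0.2, 0.1)) -> DatasetManifest:
    """Render a dataset in the manifest layout with a seeded 7:2:1 split."""
    if n_images < 10:
        raise ValueError("need at least 10 images for a 7:2:1 split")
    if abs(sum(split_ratio) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    K = _scaled_intrinsics(image_size)
    manifest = DatasetManifest(root=Path(out_dir), image_size=image_size,
                               intrinsics={"fx": K.fx, "fy": K.fy, "cx": K.cx,
                                           "cy": K.cy, "depth_scale": K.depth_scale})
    n_train = int(n_images * split_ratio[0])
    n_val = int(n_images * split_ratio[1])
    assignment = (["train"] * n_train + ["val"] * n_val
                  + ["test"] * (n_images - n_train - n_val))
    perm = rng.permutation(n_images)
    for idx in range(n_images):
        split = assignment[perm[idx]]
        stem = f"img_{idx:05d}"
        n_obj = int(rng.integers(objects_per_image[0], objects_per_image[1] + 1))
        spec = sample_scene(rng, n_obj, class_mix, image_size, K, clutter_density,
                            depth_range_cm=depth_range_cm)
        rgb, depth_mm, labels, _ = render_scene(spec)
        save_image(manifest.image_path(split, stem), rgb)
        write_yolo_labels(manifest.label_path(split, stem), labels)
        write_depth(manifest.depth_path(split, stem), depth_mm)
        manifest.splits[split].append(stem)
    manifest.save()
    return manifest
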