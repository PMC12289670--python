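"""Image/label augmentations gated by the warmup schedule.

Each augmentation fires independently with its plan probability, in a fixed
canonical order (mosaic, translate/scale, horizontal flip, HSV jitter), from
a single seeded generator, so a (seed, plan) pair fully determines the
output. Boxes are YOLO-normalized ``(class, cx, cy, w, h)`` rows and stay
normalized and consistent with the geometric transform; boxes that collapse
to zero area are dropped with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .schedule import AugmentationPlan

log = logging.getLogger(__name__)

_ORDER = ("mosaic", "translate_scale", "fliplr", "hsv")

DEFAULT_MAGNITUDES = {"hsv_h": 0.015, "hsv_s": 0.7, "hsv_v": 0.4,
                      "translate": 0.1, "scale": 0.25}

_MIN_SIDE = 1e-4    # normalized; smaller boxes count as degenerate


def _clip_boxes(labels: np.ndarray) -> np.ndarray:
    """Clip normalized cxcywh boxes to the unit square, dropping degenerates."""
    if labels.size == 0:
        return labels.reshape(0, 5)
    cls = labels[:, 0]
    x1 = labels[:, 1] - labels[:, 3] / 2
    y1 = labels[:, 2] - labels[:, 4] / 2
    x2 = labels[:, 1] + labels[:, 3] / 2
    y2 = labels[:, 2] + labels[:, 4] / 2
    x1, x2 = np.clip(x1, 0, 1), np.clip(x2, 0, 1)
    y1, y2 = np.clip(y1, 0, 1), np.clip(y2, 0, 1)
    w, h = x2 - x1, y2 - y1
    keep = (w > _MIN_SIDE) & (h > _MIN_SIDE)
    if not keep.all():
        log.warning("dropped %d degenerate box(es) after transform",
                    int((~keep).sum()))
    out = np.stack([cls, (x1 + x2) / 2, (y1 + y2) / 2, w, h], axis=1)
    return out[keep]


def fliplr(image: np.ndarray, labels: np.ndarray):
    """Mirror horizontally; cx -> 1 - cx."""
    out = labels.copy()
    if out.size:
        out[:, 1] = 1.0 - out[:, 1]
    return np.ascontiguousarray(image[:, ::-1]), out


def hsv_jitter(image: np.ndarray, rng: np.random.Generator,
               mags: dict) -> np.ndarray:
    """Random hue shift and saturation/value gains (boxes unaffected)."""
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-mags["hsv_h"], mags["hsv_h"])) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(1 - mags["hsv_s"],
                                                    1 + mags["hsv_s"]), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(1 - mags["hsv_v"],
                                                    1 + mags["hsv_v"]), 0, 1)
    return skcolor.hsv2rgb(hsv).astype(np.float32)


def translate_scale(image: np.ndarray, labels: np.ndarray,
                    rng: np.random.Generator, mags: dict):
    """Random zoom about the image center plus a random shift."""
    H, W = image.shape[:2]
    f = rng.uniform(1 - mags["scale"], 1 + mags["scale"])
    tx = rng.uniform(-mags["translate"], mags["translate"])
    ty = rng.uniform(-mags["translate"], mags["translate"])
    # output pixel (r, c) samples input ((r - cy')/f + cy, (c - cx')/f + cx)
    cy, cx = (H - 1) / 2, (W - 1) / 2
    offset = [cy - (cy + ty * H) / f, cx - (cx + tx * W) / f]
    out = np.stack([
        ndi.affine_transform(image[..., ch], np.diag([1 / f, 1 / f]),
                             offset=offset, order=1, mode="constant", cval=0.45)
        for ch in range(image.shape[2])], axis=-1).astype(np.float32)
    lab = labels.copy()
    if lab.size:
        lab[:, 1] = f * (lab[:, 1] - 0.5) + 0.5 + tx
        lab[:, 2] = f * (lab[:, 2] - 0.5) + 0.5 + ty
        lab[:, 3] *= f
        lab[:, 4] *= f
    return out, _clip_boxes(lab)


def mosaic(image: np.ndarray, labels: np.ndarray, extra, rng: np.random.Generator):
    """Compose the image with three others on a 2x2 grid, resized back."""
    if len(extra) < 3:
        raise ValueError("mosaic needs three extra (image, labels) samples")
    picks = [(image, labels)] + [extra[i] for i in
                                 rng.choice(len(extra), 3, replace=False)]
    H, W = image.shape[:2]
    canvas = np.zeros((2 * H, 2 * W, 3), dtype=np.float32)
    labs = []
    for q, (img, lab) in enumerate(picks):
        oy, ox = (q // 2) * H, (q % 2) * W
        if img.shape[:2] != (H, W):
            img = sk_resize(img, (H, W), anti_aliasing=True).astype(np.float32)
        canvas[oy:oy + H, ox:ox + W] = img
        if lab.size:
            la = lab.copy()
            la[:, 1] = (la[:, 1] + ox / W) / 2
            la[:, 2] = (la[:, 2] + oy / H) / 2
            la[:, 3:5] /= 2
            labs.append(la)
    out = sk_resize(canvas, (H, W), anti_aliasing=True).astype(np.float32)
    lab = np.concatenate(labs) if labs else labels.reshape(0, 5)
    return out, _clip_boxes(lab)


def apply_augmentations(image: np.ndarray, labels: np.ndarray,
                        plan: AugmentationPlan, rng_seed: int,
                        magnitudes: dict | None = None,
                        extra_samples=None, fired: list | None = None):
    """Apply the plan's augmentations to one sample; reproducible per seed.

    ``fired`` (optional list) collects the names of augmentations that fired,
    for the per-epoch training log.
    """
    unknown = set(plan.effective_probabilities) - set(_ORDER)
    if unknown:
        raise ValueError(f"unknown augmentation(s) in plan: {sorted(unknown)}")
    mags = dict(DEFAULT_MAGNITUDES)
    if magnitudes:
        mags.update(magnitudes)
    rng = np.random.default_rng(rng_seed)
    img = np.asarray(image)
    as_uint8 = img.dtype == np.uint8
    if as_uint8:
        img = img.astype(np.float32) / 255.0
    lab = np.asarray(labels, dtype=np.float32).reshape(-1, 5)

    for name in _ORDER:
        p = plan.effective_probabilities.get(name, 0.0)
        if p <= 0.0 or rng.random() >= p:
            continue
        if name == "mosaic":
            if not extra_samples:
                continue
            img, lab = mosaic(img, lab, extra_samples, rng)
        elif name == "translate_scale":
            img, lab = translate_scale(img, lab, rng, mags)
        elif name == "fliplr":
            img, lab = fliplr(img, lab)
        elif name == "hsv":
            img = hsv_jitter(img, rng, mags)
        if fired is not None:
            fired.append(name)

    if as_uint8:
        img = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    return img, lab
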