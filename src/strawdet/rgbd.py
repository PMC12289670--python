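"""RGB-D localization: 2-D detections + aligned depth -> camera-frame 3-D.

The pinhole model maps a pixel ``(u, v)`` at depth ``Z`` to
``X = (u - cx) Z / fx``, ``Y = (v - cy) Z / fy``. Depth per box is the
median of valid (nonzero) depth samples in the central 20 %-by-area crop of
the box, which is robust to background pixels near box edges. The reported
camera distance is the Euclidean norm of ``(X, Y, Z)`` by default; raw-Z
mode is a flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .detection import Detection

log = logging.getLogger(__name__)


class LocalizationUnavailable(RuntimeError):
    """No valid depth pixels inside the sampled box region."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics; ``depth_scale`` converts stored depth units to cm.

    The default ``depth_scale = 0.1`` reads millimeter-valued depth maps.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    depth_scale: float = 0.1

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: float(v) for k, v in d.items()})


def read_depth(path) -> np.ndarray:
    """Load a depth map: 16-bit PNG, .npy, or flat binary with a JSON sidecar."""
    path = Path(path)
    if path.suffix == ".png":
        arr = iio.imread(path)
    elif path.suffix == ".npy":
        arr = np.load(path)
    else:
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        arr = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    if arr.ndim != 2:
        raise ValueError(f"depth map must be 2-D, got shape {arr.shape}")
    if (np.asarray(arr, dtype=np.float64) < 0).any():
        raise ValueError("depth values must be >= 0")
    return arr


def write_depth(path, depth: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(depth, dtype=np.uint16))


def central_region(box, frac_area: float = 0.2):
    """The central crop holding ``frac_area`` of the box area (same aspect)."""
    x1, y1, x2, y2 = box
    s = np.sqrt(frac_area)
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    hw, hh = (x2 - x1) * s / 2, (y2 - y1) * s / 2
    return cx - hw, cy - hh, cx + hw, cy + hh


def box_depth(box, depth: np.ndarray, intrinsics: CameraIntrinsics) -> float:
    """Median valid depth in the central 20 % of the box, in centimeters."""
    H, W = depth.shape
    x1, y1, x2, y2 = central_region(box)
    c1, c2 = int(np.clip(np.floor(x1), 0, W - 1)), int(np.clip(np.ceil(x2), 1, W))
    r1, r2 = int(np.clip(np.floor(y1), 0, H - 1)), int(np.clip(np.ceil(y2), 1, H))
    region = np.asarray(depth[r1:max(r2, r1 + 1), c1:max(c2, c1 + 1)], dtype=float)
    valid = region[region > 0]
    if valid.size == 0:
        raise LocalizationUnavailable(
            f"no valid depth pixels in central region of box {tuple(box)}")
    return float(np.median(valid)) * intrinsics.depth_scale


def backproject(u: float, v: float, z_cm: float,
                intrinsics: CameraIntrinsics) -> tuple[float, float, float]:
    """Pixel + depth -> camera-frame (X, Y, Z) in centimeters."""
    if z_cm <= 0:
        raise ValueError(f"depth must be positive, got {z_cm}")
    x = (u - intrinsics.cx) * z_cm / intrinsics.fx
    y = (v - intrinsics.cy) * z_cm / intrinsics.fy
    return float(x), float(y), float(z_cm)


def project(x: float, y: float, z: float,
            intrinsics: CameraIntrinsics) -> tuple[float, float]:
    """Forward pinhole projection (the inverse of :func:`backproject`)."""
    if z <= 0:
        raise ValueError("point must be in front of the camera (Z > 0)")
    return (intrinsics.fx * x / z + intrinsics.cx,
            intrinsics.fy * y / z + intrinsics.cy)


def localize_detections(dets: list[Detection], depth: np.ndarray,
                        intrinsics: CameraIntrinsics,
                        euclidean_distance: bool = True) -> list[Detection]:
    """Annotate each detection with 3-D position and camera distance.

    Detections whose box has no valid depth keep ``position_3d = None``.
    """
    out = []
    for d in dets:
        x1, y1, x2, y2 = d.box
        try:
            z = box_depth(d.box, depth, intrinsics)
        except LocalizationUnavailable:
            log.warning("detection at %s has no valid depth; reported without 3-D",
                        d.box)
            out.append(replace(d, position_3d=None, distance_cm=None))
            continue
        pos = backproject((x1 + x2) / 2, (y1 + y2) / 2, z, intrinsics)
        dist = float(np.linalg.norm(pos)) if euclidean_distance else pos[2]
        out.append(replace(d, position_3d=pos, distance_cm=dist))
    return out
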