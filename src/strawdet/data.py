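"""Dataset manifest and YOLO-format label I/O.

Layout on disk::

    <root>/manifest.yaml
    <root>/images/{train,val,test}/<stem>.png
    <root>/labels/{train,val,test}/<stem>.txt     # "class cx cy w h", normalized
    <root>/depth/{train,val,test}/<stem>.png      # optional, 16-bit millimeters
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

CLASS_NAMES = ("bud", "flower", "unripe", "ripe")
SPLITS = ("train", "val", "test")


def read_yolo_labels(path) -> np.ndarray:
    """Label file -> (N, 5) array of (class, cx, cy, w, h); empty file is fine."""
    path = Path(path)
    if not path.exists() or not path.read_text().strip():
        return np.zeros((0, 5), dtype=np.float32)
    rows = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed label line {line!r}")
        rows.append([float(p) for p in parts])
    arr = np.array(rows, dtype=np.float32)
    if ((arr[:, 1:] < 0) | (arr[:, 1:] > 1)).any():
        raise ValueError(f"{path}: label coordinates outside [0,1]")
    return arr


def write_yolo_labels(path, labels: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for c, cx, cy, w, h in np.asarray(labels).reshape(-1, 5)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def labels_to_corners(labels: np.ndarray, width: int, height: int) -> np.ndarray:
    """Normalized cxcywh -> pixel (class, x1, y1, x2, y2)."""
    lab = np.asarray(labels, dtype=float).reshape(-1, 5)
    out = np.empty_like(lab)
    out[:, 0] = lab[:, 0]
    out[:, 1] = (lab[:, 1] - lab[:, 3] / 2) * width
    out[:, 2] = (lab[:, 2] - lab[:, 4] / 2) * height
    out[:, 3] = (lab[:, 1] + lab[:, 3] / 2) * width
    out[:, 4] = (lab[:, 2] + lab[:, 4] / 2) * height
    return out


def corners_to_labels(corners: np.ndarray, width: int, height: int) -> np.ndarray:
    """Pixel (class, x1, y1, x2, y2) -> normalized cxcywh."""
    c = np.asarray(corners, dtype=float).reshape(-1, 5)
    out = np.empty_like(c)
    out[:, 0] = c[:, 0]
    out[:, 1] = (c[:, 1] + c[:, 3]) / 2 / width
    out[:, 2] = (c[:, 2] + c[:, 4]) / 2 / height
    out[:, 3] = (c[:, 3] - c[:, 1]) / width
    out[:, 4] = (c[:, 4] - c[:, 2]) / height
    return out


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(path, image: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


@dataclass
class DatasetManifest:
    root: Path
    classes: tuple = CLASS_NAMES
    splits: dict = field(default_factory=lambda: {s: [] for s in SPLITS})
    image_size: int = 640
    intrinsics: dict | None = None

    def image_path(self, split, stem) -> Path:
        return Path(self.root) / "images" / split / f"{stem}.png"

    def label_path(self, split, stem) -> Path:
        return Path(self.root) / "labels" / split / f"{stem}.txt"

    def depth_path(self, split, stem) -> Path:
        return Path(self.root) / "depth" / split / f"{stem}.png"

    def save(self) -> Path:
        path = Path(self.root) / "manifest.yaml"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump({"classes": list(self.classes),
                            "image_size": self.image_size,
                            "intrinsics": self.intrinsics,
                            "splits": {k: list(v) for k, v in self.splits.items()}},
                           fh, sort_keys=False)
        return path

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        if path.is_dir():
            path = path / "manifest.yaml"
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(root=path.parent, classes=tuple(d["classes"]),
                   splits=d["splits"], image_size=d.get("image_size", 640),
                   intrinsics=d.get("intrinsics"))

    def load_split(self, split: str):
        """Yield (image, labels, stem) for a split."""
        if split not in self.splits:
            raise KeyError(f"unknown split {split!r}")
        for stem in self.splits[split]:
            yield (load_image(self.image_path(split, stem)),
                   read_yolo_labels(self.label_path(split, stem)), stem)
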