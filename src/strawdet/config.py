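"""Run configuration: model, training and camera blocks.

Everything is a plain dataclass serializable to/from YAML so that a single
config file drives the CLI; defaults mirror the training protocol the
detector was designed around (100 epochs, batch 32, 640 px, Adam at 0.01
with cosine annealing, 7:2:1 split).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

SCALE_PRESETS = {"n": (0.33, 0.25), "s": (0.33, 0.50)}

# Attention embedding width of CGFM nodes keyed by spliced channel count.
# Calibrated against the whole-model parameter budget; nodes whose width is
# not listed use the full spliced width.
CGFM_ATTN_DIMS = {768: 624, 384: 320}


@dataclass
class ModelConfig:
    scale: str = "s"
    num_classes: int = 80
    use_warmup: bool = False          # training-schedule flag; never adds parameters
    use_se_msdwa: bool = False
    use_cgfm: bool = False
    # SE-MSDWA hyperparameters
    se_dw_kernel: int = 5
    se_strip_kernels: tuple = (5, 9, 17)
    se_reduction: int = 2             # calibrated against the parameter budget
    # CGFM hyperparameters
    cgfm_heads: int = 4
    cgfm_attn_dims: dict = field(default_factory=lambda: dict(CGFM_ATTN_DIMS))
    cgfm_sa_stride: int = 2
    # prediction-time defaults
    conf_thresh: float = 0.25
    iou_thresh: float = 0.7

    def __post_init__(self):
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}; choose from n, s")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def depth_multiple(self) -> float:
        return SCALE_PRESETS[self.scale][0]

    @property
    def width_multiple(self) -> float:
        return SCALE_PRESETS[self.scale][1]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    image_size: int = 640
    lr: float = 0.01                  # Adam initial learning rate
    cosine_final_lr_frac: float = 0.01
    grad_clip_norm: float = 10.0      # global-norm clip; stabilizes early steps
    seed: int = 0
    # base augmentation probabilities, scaled per epoch by the warmup factor
    augment: dict = field(default_factory=lambda: {
        "mosaic": 1.0, "fliplr": 0.5, "hsv": 0.5, "translate_scale": 0.5})
    augment_magnitudes: dict = field(default_factory=lambda: {
        "hsv_h": 0.015, "hsv_s": 0.7, "hsv_v": 0.4,
        "translate": 0.1, "scale": 0.25})
    close_mosaic_epochs: int = 0      # disable mosaic in the last k epochs (off)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name, p in self.augment.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"augmentation probability {name}={p} outside [0,1]")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    if "cgfm_attn_dims" in d and d["cgfm_attn_dims"] is not None:
        d["cgfm_attn_dims"] = {int(k): int(v) for k, v in d["cgfm_attn_dims"].items()}
    if "se_strip_kernels" in d:
        d["se_strip_kernels"] = tuple(d["se_strip_kernels"])
    return ModelConfig(**d)


def save_config(cfg, path):
    d = asdict(cfg)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
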