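"""Detector assembly: CSP backbone, path-aggregation neck, anchor-free head.

``build_model`` constructs either the plain baseline or the modified variant
with the SE-MSDWA block appended to the backbone tail and CGFM nodes
replacing the four neck concatenations. Builds are deterministic given the
config and seed, and ``count_parameters`` enumerates learnable scalars.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import (C2f, CGFM, CGFMConfig, ConvAct, Detect, MSDWAConfig,
                     SEConfig, SEMSDWA, SPPF)
from .config import ModelConfig


def _make_divisible(x: float, div: int = 8) -> int:
    return max(div, int(np.ceil(x / div) * div))


class Concat(nn.Module):
    """Plain channel concatenation (the node CGFM replaces)."""

    def forward(self, x1, x2):
        return nn.cat([x1, x2])


class DetectionModel(nn.Module):
    """Backbone -> neck -> head; returns three raw prediction maps."""

    STRIDES = (8, 16, 32)

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        d, w = cfg.depth_multiple, cfg.width_multiple
        c1, c2, c3, c4, c5 = (_make_divisible(c * w) for c in (64, 128, 256, 512, 1024))
        n3 = max(round(3 * d), 1)
        n6 = max(round(6 * d), 1)
        self.channels = (c3, c4, c5)        # P3 / P4 / P5 widths

        # backbone
        self.b0 = ConvAct(3, c1, 3, 2)
        self.b1 = ConvAct(c1, c2, 3, 2)
        self.b2 = C2f(c2, c2, n3, shortcut=True)
        self.b3 = ConvAct(c2, c3, 3, 2)
        self.b4 = C2f(c3, c3, n6, shortcut=True)
        self.b5 = ConvAct(c3, c4, 3, 2)
        self.b6 = C2f(c4, c4, n6, shortcut=True)
        self.b7 = ConvAct(c4, c5, 3, 2)
        self.b8 = C2f(c5, c5, n3, shortcut=True)
        self.b9 = SPPF(c5, c5)
        if cfg.use_se_msdwa:
            self.se_msdwa = SEMSDWA(MSDWAConfig(
                channels=c5, dw_kernel=cfg.se_dw_kernel,
                strip_kernels=tuple(cfg.se_strip_kernels),
                se=SEConfig(c5, cfg.se_reduction)))
        else:
            self.se_msdwa = None

        # neck (path aggregation); fusion nodes are Concat or CGFM
        def fuse(cin1, cin2):
            if not cfg.use_cgfm:
                return Concat()
            spliced = cin1 + cin2
            return CGFM(CGFMConfig(
                channels_in_1=cin1, channels_in_2=cin2, heads=cfg.cgfm_heads,
                attn_dim=cfg.cgfm_attn_dims.get(spliced),
                sa_stride=cfg.cgfm_sa_stride))

        self.fuse1 = fuse(c5, c4)
        self.n12 = C2f(c5 + c4, c4, n3)
        self.fuse2 = fuse(c4, c3)
        self.n15 = C2f(c4 + c3, c3, n3)
        self.d16 = ConvAct(c3, c3, 3, 2)
        self.fuse3 = fuse(c3, c4)
        self.n18 = C2f(c3 + c4, c4, n3)
        self.d19 = ConvAct(c4, c4, 3, 2)
        self.fuse4 = fuse(c4, c5)
        self.n21 = C2f(c4 + c5, c5, n3)

        self.head = Detect(cfg.num_classes, (c3, c4, c5), self.STRIDES)

    # -- execution ----------------------------------------------------------
    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size {x.shape[2:]} not divisible by 32")
        x = self.b1(self.b0(x))
        p3 = self.b4(self.b3(self.b2(x)))
        p4 = self.b6(self.b5(p3))
        p5 = self.b9(self.b8(self.b7(p4)))
        if self.se_msdwa is not None:
            p5 = self.se_msdwa(p5)
        t = self.n12(self.fuse1(nn.upsample_nearest2x(p5), p4))
        out3 = self.n15(self.fuse2(nn.upsample_nearest2x(t), p3))
        out4 = self.n18(self.fuse3(self.d16(out3), t))
        out5 = self.n21(self.fuse4(self.d19(out4), p5))
        return self.head([out3, out4, out5])

    # -- introspection -------------------------------------------------------
    def graph(self):
        """Ordered (name, node-type) pairs describing the layer graph."""
        nodes = [("b0", "ConvAct"), ("b1", "ConvAct"), ("b2", "C2f"),
                 ("b3", "ConvAct"), ("b4", "C2f"), ("b5", "ConvAct"),
                 ("b6", "C2f"), ("b7", "ConvAct"), ("b8", "C2f"), ("b9", "SPPF")]
        if self.se_msdwa is not None:
            nodes.append(("se_msdwa", "SEMSDWA"))
        for name in ("fuse1", "n12", "fuse2", "n15", "d16", "fuse3", "n18",
                     "d19", "fuse4", "n21"):
            nodes.append((name, type(getattr(self, name)).__name__))
        nodes.append(("head", "Detect"))
        return nodes


def build_model(cfg: ModelConfig, seed: int = 0) -> DetectionModel:
    """Deterministically construct a detector from its config."""
    nn.seed_init(seed)
    return DetectionModel(cfg)


def save_checkpoint(model: DetectionModel, path):
    """Self-describing archive: config + weights in one .npz."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> DetectionModel:
    import json

    from .config import model_config_from_dict

    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    cfg = model_config_from_dict(json.loads(state.pop("__config__").tobytes()))
    model = build_model(cfg)
    model.load_state_dict(state)
    return model


def count_parameters(model: nn.Module) -> int:
    """Number of learnable scalars in the model (exact)."""
    return model.num_parameters()


def count_parameters_m(model: nn.Module) -> float:
    """Parameter count in millions, rounded to two decimals (reporting scale)."""
    return round(count_parameters(model) / 1e6, 2)
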