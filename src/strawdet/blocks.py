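"""Building blocks of the detector.

Standard CSP-style pieces (``ConvAct``, ``Bottleneck``, ``C2f``, ``SPPF``,
``Detect``) plus the two bespoke attention blocks:

* ``SEMSDWA`` — squeeze-and-excitation-enhanced multi-scale depthwise
  attention: an initial depthwise convolution, three depthwise strip-kernel
  branches (1x5/5x1, 1x9/9x1, 1x17/17x1), a pointwise fusion convolution and
  an SE channel-reweighting stage, applied to the block input as a gated
  residual.
* ``CGFM`` — context-guide fusion: a drop-in replacement for channel
  concatenation in the neck that derives sigmoid gates from multi-head
  self-attention over the spliced map and cross-mixes the two inputs.

All convolutions carry biases and no batch normalization (the batch-norm-
fused parameterization), so enumerated learnable scalars match the analytic
count helpers exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# generic convolutional pieces
# ---------------------------------------------------------------------------

class ConvAct(nn.Module):
    """Convolution + SiLU."""

    def __init__(self, c1, c2, k=1, s=1):
        self.conv = nn.Conv2d(c1, c2, k, s)

    def forward(self, x):
        return self.conv(x).silu()


class Bottleneck(nn.Module):
    def __init__(self, c, shortcut=True):
        self.cv1 = ConvAct(c, c, 3)
        self.cv2 = ConvAct(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """Cross-stage block: split, chain bottlenecks, re-fuse."""

    def __init__(self, c1, c2, n=1, shortcut=False):
        self.c = c2 // 2
        self.cv1 = ConvAct(c1, 2 * self.c, 1)
        self.cv2 = ConvAct((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList(Bottleneck(self.c, shortcut) for _ in range(n))

    def forward(self, x):
        y = nn.chunk(self.cv1(x), [self.c, self.c])
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(nn.cat(y))


class SPPF(nn.Module):
    """Spatial-pyramid fast pooling tail."""

    def __init__(self, c1, c2, k=5):
        c_ = c1 // 2
        self.cv1 = ConvAct(c1, c_, 1)
        self.cv2 = ConvAct(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(nn.maxpool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(nn.cat(y))


# ---------------------------------------------------------------------------
# squeeze-and-excitation + multi-scale depthwise attention
# ---------------------------------------------------------------------------

@dataclass
class SEConfig:
    channels: int
    reduction: int = 16

    @property
    def hidden(self) -> int:
        return max(1, self.channels // self.reduction)


@dataclass
class MSDWAConfig:
    channels: int
    dw_kernel: int = 5
    strip_kernels: tuple = (5, 9, 17)
    se: SEConfig | None = None

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.se is None:
            self.se = SEConfig(self.channels)
        if self.se.channels != self.channels:
            raise ValueError("SE channel width must match block channels")


class SqueezeExcite(nn.Module):
    """Channel reweighting: global average pool -> FC bottleneck -> sigmoid."""

    def __init__(self, cfg: SEConfig):
        self.cfg = cfg
        self.fc1 = nn.Linear(cfg.channels, cfg.hidden)
        self.fc2 = nn.Linear(cfg.hidden, cfg.channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"SE expects {self.cfg.channels} channels, got {x.shape[1]}")
        w = self.fc2(self.fc1(nn.global_avg_pool(x)).relu()).sigmoid()
        B, C = w.shape
        return x * w.reshape(B, C, 1, 1)


class StripBranch(nn.Module):
    """A 1xk depthwise convolution followed by kx1 (approximates kxk context)."""

    def __init__(self, channels, k):
        self.h = nn.DepthwiseConv2d(channels, (1, k))
        self.v = nn.DepthwiseConv2d(channels, (k, 1))

    def forward(self, x):
        return self.v(self.h(x))


class SEMSDWA(nn.Module):
    """Multi-scale depthwise attention with an SE stage.

    Pipeline: ``d = dw(x)``; strip branches on ``d``; ``f = pw(d + sum(b_i))``;
    ``a = SE(f)``; output ``x * a + x`` (attention on the block input with a
    residual connection). Spatial shape is preserved throughout.
    """

    def __init__(self, cfg: MSDWAConfig):
        self.cfg = cfg
        C = cfg.channels
        self.dw = nn.DepthwiseConv2d(C, cfg.dw_kernel)
        self.branches = nn.ModuleList(StripBranch(C, k) for k in cfg.strip_kernels)
        self.pw = nn.Conv2d(C, C, 1)
        self.se = SqueezeExcite(cfg.se)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"SE-MSDWA expects {self.cfg.channels} channels, got {x.shape[1]}")
        if x.shape[2] < 1 or x.shape[3] < 1:
            raise ValueError("spatial size must be at least 1x1")
        d = self.dw(x)
        s = d
        for b in self.branches:
            s = s + b(d)
        a = self.se(self.pw(s))
        return x * a + x


def msdwa_param_count(cfg: MSDWAConfig) -> int:
    """Closed-form learnable-scalar count of an ``SEMSDWA`` block."""
    C = cfg.channels
    n = C * cfg.dw_kernel ** 2 + C                      # initial depthwise
    for k in cfg.strip_kernels:                          # strip pairs (1,k)+(k,1)
        n += 2 * (C * k + C)
    n += C * C + C                                       # pointwise fusion
    h = cfg.se.hidden                                    # SE bottleneck
    n += C * h + h + h * C + C
    return n


# ---------------------------------------------------------------------------
# context-guide fusion
# ---------------------------------------------------------------------------

@dataclass
class CGFMConfig:
    channels_in_1: int
    channels_in_2: int
    heads: int = 4
    attn_dim: int | None = None     # embedding width of the attention stage
    sa_stride: int = 2              # token subsampling for maps larger than 20x20

    @property
    def channels(self) -> int:
        return self.channels_in_1 + self.channels_in_2

    @property
    def channels_out(self) -> int:
        return self.channels            # drop-in for concatenation

    def __post_init__(self):
        e = self.attn_dim if self.attn_dim is not None else self.channels
        if e % self.heads:
            raise ValueError(
                f"attention width {e} not divisible by {self.heads} heads")


class MultiHeadSelfAttention(nn.Module):
    """Self-attention over spatial positions; channels are the embedding.

    Q, K, V come from learned 1x1 projections into ``attn_dim`` channels; the
    merged heads are mapped back to the input width by a learned output
    projection. Spatial shape is preserved.
    """

    def __init__(self, channels: int, heads: int, attn_dim: int | None = None):
        e = channels if attn_dim is None else attn_dim
        if e % heads:
            raise ValueError(f"channels {e} not divisible by heads {heads}")
        self.heads = heads
        self.e = e
        self.q = nn.Conv2d(channels, e, 1)
        self.k = nn.Conv2d(channels, e, 1)
        self.v = nn.Conv2d(channels, e, 1)
        self.proj = nn.Conv2d(e, channels, 1)

    def attention_matrix(self, x: Tensor) -> np.ndarray:
        """Post-softmax attention weights, shape (B, heads, N, N); diagnostic."""
        att, _ = self._attend(x)
        return att.data

    def _attend(self, x: Tensor):
        B, C, H, W = x.shape
        h, e = self.heads, self.e
        dh = e // h
        q = self.q(x).reshape(B, h, dh, H * W).transpose(0, 1, 3, 2)
        k = self.k(x).reshape(B, h, dh, H * W)
        v = self.v(x).reshape(B, h, dh, H * W).transpose(0, 1, 3, 2)
        att = ((q @ k) * (1.0 / math.sqrt(dh))).softmax(axis=-1)
        out = (att @ v).transpose(0, 1, 3, 2).reshape(B, e, H, W)
        return att, out

    def forward(self, x: Tensor) -> Tensor:
        _, out = self._attend(x)
        return self.proj(out)


class CGFM(nn.Module):
    """Attention-guided replacement for channel concatenation.

    ``z = conv1x1(cat(x1, x2))``; sigmoid of the self-attended ``z`` is split
    into per-input gates; each input is gated and the channel-matched other
    input is added; the two blends are re-concatenated, so the output has
    ``C1 + C2`` channels exactly like plain concatenation.
    """

    def __init__(self, cfg: CGFMConfig):
        self.cfg = cfg
        C = cfg.channels
        self.pre = nn.Conv2d(C, C, 1)
        self.attn = MultiHeadSelfAttention(C, cfg.heads, cfg.attn_dim)
        self.match21 = nn.Conv2d(cfg.channels_in_2, cfg.channels_in_1, 1)
        self.match12 = nn.Conv2d(cfg.channels_in_1, cfg.channels_in_2, 1)
        self.diagnostic = False     # gates to 1, cross-terms zeroed -> plain concat

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        c1, c2 = self.cfg.channels_in_1, self.cfg.channels_in_2
        if x1.shape[1] != c1 or x2.shape[1] != c2:
            raise ValueError(
                f"CGFM expects channels ({c1},{c2}), got ({x1.shape[1]},{x2.shape[1]})")
        if x1.shape[0] != x2.shape[0] or x1.shape[2:] != x2.shape[2:]:
            raise ValueError(f"CGFM spatial/batch mismatch: {x1.shape} vs {x2.shape}")
        if self.diagnostic:
            return nn.cat([x1, x2])
        z = self.pre(nn.cat([x1, x2]))
        H, W = z.shape[2], z.shape[3]
        s = self.cfg.sa_stride
        if s > 1 and max(H, W) > 20 and H % s == 0 and W % s == 0:
            a = nn.upsample_nearest(self.attn(nn.subsample2d(z, s)), s)
        else:
            a = self.attn(z)
        g = a.sigmoid()
        g1, g2 = nn.chunk(g, [c1, c2])
        blended1 = g1 * x1 + self.match21(x2)
        blended2 = g2 * x2 + self.match12(x1)
        return nn.cat([blended1, blended2])


def cgfm_param_count(cfg: CGFMConfig) -> int:
    """Closed-form learnable-scalar count of a ``CGFM`` node."""
    C = cfg.channels
    e = cfg.attn_dim if cfg.attn_dim is not None else C
    n = C * C + C                                        # pre 1x1
    n += 3 * (C * e + e)                                 # Q, K, V projections
    n += e * C + C                                       # output projection
    n += cfg.channels_in_2 * cfg.channels_in_1 + cfg.channels_in_1   # match21
    n += cfg.channels_in_1 * cfg.channels_in_2 + cfg.channels_in_2   # match12
    return n


# ---------------------------------------------------------------------------
# detection head
# ---------------------------------------------------------------------------

class Detect(nn.Module):
    """Decoupled anchor-free head with distribution-based box regression.

    Per pyramid level, a box branch predicts ``4 * reg_max`` logits (discrete
    distributions over side offsets) and a class branch predicts ``nc``
    logits. Decoding happens in :mod:`strawdet.postprocess`.
    """

    REG_MAX = 16

    def __init__(self, nc: int, ch: tuple, strides: tuple = (8, 16, 32)):
        self.nc = nc
        self.ch = tuple(ch)
        self.strides = tuple(strides)
        c2 = max(16, ch[0] // 4, self.REG_MAX * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box = nn.ModuleList(
            nn.Sequential(ConvAct(x, c2, 3), ConvAct(c2, c2, 3),
                          nn.Conv2d(c2, 4 * self.REG_MAX, 1))
            for x in ch)
        self.cls = nn.ModuleList(
            nn.Sequential(ConvAct(x, c3, 3), ConvAct(c3, c3, 3),
                          nn.Conv2d(c3, nc, 1))
            for x in ch)
        self._init_biases()

    def _init_biases(self):
        # class prior so early training is not swamped by background
        for branch, s in zip(self.cls, self.strides):
            branch[-1].bias.data[...] = math.log(5.0 / self.nc / (640.0 / s) ** 2)
        for branch in self.box:
            branch[-1].bias.data[...] = 1.0

    def forward(self, feats):
        return [nn.cat([b(f), c(f)]) for f, b, c in zip(feats, self.box, self.cls)]
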