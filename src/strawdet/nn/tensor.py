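"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based autodiff core: every op builds a ``Tensor``
whose ``_backward`` closure scatters the upstream gradient to its parents.
Only the operations the detector needs are provided (elementwise arithmetic,
matmul, dense/depthwise 2-D convolution, pooling, nearest upsampling,
softmax, gather, slicing/concatenation).  float32 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference / assignment)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and is_grad_enabled()
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # release the tape
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numel(self) -> int:
        return int(self.data.size)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-o)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self * o.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def atan(self):
        def backward(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(np.arctan(self.data), (self,), backward)

    def sigmoid(self):
        s = expit(self.data)

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def silu(self):
        s = expit(self.data)
        out_data = self.data * s

        def backward(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), backward)

    def maximum(self, other: "Tensor"):
        o = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data >= o.data
        out_data = np.where(mask, self.data, o.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * ~mask, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    def minimum(self, other: "Tensor"):
        o = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data <= o.data
        out_data = np.where(mask, self.data, o.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * ~mask, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def take(self, indices: np.ndarray, axis: int = 0):
        """Gather along ``axis`` with integer indices (differentiable)."""
        indices = np.asarray(indices)
        out_data = np.take(self.data, indices, axis=axis)

        def backward(g):
            full = np.zeros_like(self.data)
            moved = np.moveaxis(full, axis, 0)   # view; add.at writes through
            np.add.at(moved, indices, np.moveaxis(g, axis, 0))
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ o.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accum(_unbroadcast(gb, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, (self,), backward)

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        s = np.exp(out_data)

        def backward(g):
            self._accum(g - s * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (counted by ``count_parameters``)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        # parameters stay trainable even if created under no_grad
        self.requires_grad = True


# ---------------------------------------------------------------------------
# functional ops with non-trivial data movement
# ---------------------------------------------------------------------------

def cat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x._accum(full)

    return Tensor._make(x.data[sl], (x,), backward)


def chunk(x: Tensor, sizes, axis: int = 1):
    out, start = [], 0
    for s in sizes:
        out.append(narrow(x, axis, start, s))
        start += s
    return out


def _pad2d(a: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return a
    return np.pad(a, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=value)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: tuple[int, int] | int = 0) -> Tensor:
    """Dense 2-D cross-correlation, NCHW, weight (O, C, kh, kw)."""
    if isinstance(padding, int):
        padding = (padding, padding)
    ph, pw = padding
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cw}")
    xp = _pad2d(x.data, ph, pw)
    Ho = (H + 2 * ph - kh) // stride + 1
    Wo = (W + 2 * pw - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    out_data = (cols @ wmat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(O, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if ph or pw:
                dxp = dxp[:, :, ph:H + ph, pw:W + pw]
            x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None,
                     padding: tuple[int, int] | int = 0) -> Tensor:
    """Depthwise (one filter per channel) stride-1 convolution; weight (C, kh, kw)."""
    if isinstance(padding, int):
        padding = (padding, padding)
    ph, pw = padding
    B, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {Cw}")
    xp = _pad2d(x.data, ph, pw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (B, C, H, W, kh, kw) since stride 1 and same padding
    out_data = np.einsum("bchwij,cij->bchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, C, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("bchwij,bchw->cij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of grad with flipped kernel
            gp = _pad2d(g, kh - 1 - ph, kw - 1 - pw)
            gw = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, ::-1, ::-1]
            x._accum(np.einsum("bchwij,cij->bchw", gw, wf, optimize=True))

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    B, C, H, W = x.data.shape
    xp = _pad2d(x.data, padding, padding, value=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((B, C, H + 2 * padding, W + 2 * padding), dtype=np.float32)
        ki, kj = np.divmod(arg, k)
        bb, cc, ii, jj = np.meshgrid(np.arange(B), np.arange(C), np.arange(Ho),
                                     np.arange(Wo), indexing="ij")
        np.add.at(dxp, (bb, cc, ii * stride + ki, jj * stride + kj), g)
        if padding:
            dxp = dxp[:, :, padding:H + padding, padding:W + padding]
        x._accum(dxp)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest(x: Tensor, s: int = 2) -> Tensor:
    out_data = x.data.repeat(s, axis=2).repeat(s, axis=3)

    def backward(g):
        B, C, Hs, Ws = g.shape
        x._accum(g.reshape(B, C, Hs // s, s, Ws // s, s).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    return upsample_nearest(x, 2)


def subsample2d(x: Tensor, s: int) -> Tensor:
    """Strided spatial subsampling (token thinning for attention)."""
    out_data = x.data[:, :, ::s, ::s]

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, :, ::s, ::s] = g
        x._accum(full)

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) channel means (adaptive average pooling to 1x1)."""
    B, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).copy())

    return Tensor._make(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on logits; returns the elementwise sum."""
    z, t = logits.data, np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        loss = loss * weights
    out_data = loss.sum()

    def backward(g):
        d = expit(z) - t
        if weights is not None:
            d = d * weights
        logits._accum(g * d)

    return Tensor._make(np.float32(out_data), (logits,), backward)
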