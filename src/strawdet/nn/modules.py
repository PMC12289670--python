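"""Minimal layer/module system on top of the autodiff core."""

from __future__ import annotations

import math

import numpy as np

from .tensor import (Parameter, Tensor, conv2d, depthwise_conv2d)

__all__ = ["Module", "ModuleList", "Sequential", "Conv2d", "DepthwiseConv2d",
           "Linear", "Identity"]


class Module:
    """Base class; children and parameters are discovered via attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.numel() for p in self.parameters())

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)[:5]} "
                           f"extra={sorted(extra)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        self.items = list(mods)

    def append(self, m):
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *mods):
        self.items = list(mods)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng):
    # He-normal; variance-preserving for ReLU-family activations, which keeps
    # the batch-norm-free network trainable at depth
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


# A module-level RNG used only for weight init; reseeded by the builder so
# that model construction is deterministic given a config seed.
_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """Dense convolution with bias (batch-norm-fused parameterization)."""

    def __init__(self, c_in: int, c_out: int, k: int | tuple = 1, stride: int = 1,
                 padding: int | tuple | None = None, bias: bool = True):
        kh, kw = (k, k) if isinstance(k, int) else k
        if padding is None:
            padding = (kh // 2, kw // 2)  # 'same' for odd kernels
        self.stride = stride
        self.padding = padding if isinstance(padding, tuple) else (padding, padding)
        fan_in = c_in * kh * kw
        self.weight = Parameter(_kaiming((c_out, c_in, kh, kw), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    """One filter per channel, stride 1, 'same' padding."""

    def __init__(self, channels: int, k: int | tuple, bias: bool = True):
        kh, kw = (k, k) if isinstance(k, int) else k
        self.padding = (kh // 2, kw // 2)
        fan_in = kh * kw
        self.weight = Parameter(_kaiming((channels, kh, kw), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True):
        self.weight = Parameter(_kaiming((n_in, n_out), n_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y
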