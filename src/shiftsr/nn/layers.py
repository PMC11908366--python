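"""Building blocks for the denoiser: convolutions, group normalization,
residual blocks with additive time conditioning, and windowed multi-head
self-attention with optional cyclic shift (Swin-style).

All modules operate on channels-last ``(N, H, W, C)`` tensors.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "GroupNorm",
    "ResBlock",
    "WindowAttention",
    "sinusoidal_embedding",
]


class Module:
    """Tiny module base: recursive parameter discovery + state dicts."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return Tensor(w.astype(dtype), requires_grad=True)


class Conv2d(Module):
    """3x3 (or 1x1) same-padding convolution, NHWC, weight ``(kh,kw,Cin,Cout)``."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, zero_init: bool = False):
        fan_in = kernel * kernel * c_in
        if zero_init:
            self.weight = Tensor(np.zeros((kernel, kernel, c_in, c_out), dtype=dtype),
                                 requires_grad=True)
        else:
            self.weight = _he(rng, (kernel, kernel, c_in, c_out), fan_in, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = _he(rng, (c_in, c_out), c_in, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.dot_last(self.weight) + self.bias


class GroupNorm(Module):
    """Group normalization over (H, W, channels-within-group)."""

    def __init__(self, channels: int, groups: Optional[int] = None, eps: float = 1e-5,
                 dtype=np.float32):
        if groups is None:
            groups = 8
            while channels % groups:
                groups //= 2
        if channels % groups:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        g = self.groups
        xg = x.reshape(n, h, w, g, c // g)
        mu = xg.mean(axis=(1, 2, 4), keepdims=True)
        d = xg - mu
        var = (d * d).mean(axis=(1, 2, 4), keepdims=True)
        xn = d * (var + self.eps).power(-0.5)
        return xn.reshape(n, h, w, c) * self.weight + self.bias


def sinusoidal_embedding(t: np.ndarray, dim: int, dtype=np.float32) -> np.ndarray:
    """Standard transformer sinusoidal embedding of integer timesteps.

    Returns shape ``(len(t), dim)``; the raw step index is embedded (not
    ``beta_t``), keeping the conditioning schedule-agnostic.
    """
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:  # odd dim
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb.astype(dtype)


class ResBlock(Module):
    """GN -> SiLU -> conv -> (+ time bias) -> GN -> SiLU -> conv, with skip."""

    def __init__(self, c_in: int, c_out: int, temb_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.norm1 = GroupNorm(c_in, dtype=dtype)
        self.conv1 = Conv2d(c_in, c_out, 3, rng, dtype)
        self.temb_proj = Linear(temb_dim, c_out, rng, dtype)
        self.norm2 = GroupNorm(c_out, dtype=dtype)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, dtype)
        self.skip = Conv2d(c_in, c_out, 1, rng, dtype) if c_in != c_out else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        n = x.shape[0]
        bias = self.temb_proj(temb.silu()).reshape(n, 1, 1, -1)
        h = h + bias
        h = self.conv2(self.norm2(h).silu())
        s = self.skip(x) if self.skip is not None else x
        return s + h


class WindowAttention(Module):
    """Multi-head self-attention inside non-overlapping square windows.

    With ``shifted=True`` the feature map is cyclically rolled by half a
    window before partitioning (and rolled back after), so information mixes
    across window boundaries when blocks alternate shifted/unshifted.
    """

    def __init__(self, channels: int, window: int, rng: np.random.Generator,
                 heads: Optional[int] = None, shifted: bool = False, dtype=np.float32):
        if heads is None:
            heads = max(1, channels // 32)
        if channels % heads:
            raise ValueError(f"heads={heads} must divide channels={channels}")
        self.window = window
        self.heads = heads
        self.shifted = shifted
        self.norm = GroupNorm(channels, dtype=dtype)
        self.q = Linear(channels, channels, rng, dtype)
        self.k = Linear(channels, channels, rng, dtype)
        self.v = Linear(channels, channels, rng, dtype)
        self.proj = Linear(channels, channels, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        n, hh, ww, c = x.shape
        w = self.window
        for dim_name, extent in (("height", hh), ("width", ww)):
            if extent % w:
                raise ValueError(
                    f"window size {w} does not divide {dim_name} {extent}"
                )
        h = self.norm(x)
        if self.shifted:
            h = h.roll((-(w // 2), -(w // 2)), (1, 2))

        def part(t: Tensor) -> Tensor:
            # (N,H,W,C) -> (N*nw, heads, w*w, c/heads)
            t = t.reshape(n, hh // w, w, ww // w, w, c)
            t = t.transpose((0, 1, 3, 2, 4, 5))
            t = t.reshape(n * (hh // w) * (ww // w), w * w, self.heads, c // self.heads)
            return t.transpose((0, 2, 1, 3))

        q, k, v = part(self.q(h)), part(self.k(h)), part(self.v(h))
        scale = (c // self.heads) ** -0.5
        att = q.matmul(k.transpose((0, 1, 3, 2))) * scale
        out = att.softmax(axis=-1).matmul(v)
        out = out.transpose((0, 2, 1, 3)).reshape(
            n, hh // w, ww // w, w, w, c
        ).transpose((0, 1, 3, 2, 4, 5)).reshape(n, hh, ww, c)
        out = self.proj(out)
        if self.shifted:
            out = out.roll((w // 2, w // 2), (1, 2))
        return x + out
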