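"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape of :class:`Tensor` nodes; each primitive records a backward closure.
Image tensors are channels-last ``(N, H, W, C)`` throughout, which keeps the
convolution a plain GEMM per kernel offset and the normalization/attention
reshapes cheap.  Every primitive's gradient is validated by finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping an ``np.ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------------- infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _make(data, parents, backward, requires_grad=True):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    @staticmethod
    def _needs(*xs) -> bool:
        return any(isinstance(x, Tensor) and x.requires_grad for x in xs)

    def backward(self) -> None:
        """Backpropagate from a scalar node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # ----------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x, dtype) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=dtype))

    def __add__(self, other):
        other = Tensor._lift(other, self.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd, Tensor._needs(a, b))

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd, a.requires_grad)

    def __sub__(self, other):
        other = Tensor._lift(other, self.dtype)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor._lift(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other, self.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd, Tensor._needs(a, b))

    __rmul__ = __mul__

    def power(self, exponent: float) -> "Tensor":
        """Elementwise power with a *constant* exponent."""
        a = self
        out_data = a.data**exponent

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bwd, a.requires_grad)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd, a.requires_grad)

    def silu(self) -> "Tensor":
        """``x * sigmoid(x)`` as a single primitive (saves graph nodes)."""
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out = a.data * s

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * (s + out * (1.0 - s)))

        return Tensor._make(out, (a,), bwd, a.requires_grad)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_mod(ax, a.ndim) for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (a,), bwd, a.requires_grad)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd, a.requires_grad)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bwd,
                            a.requires_grad)

    def roll(self, shift: tuple[int, int], axes: tuple[int, int]) -> "Tensor":
        """Cyclic shift (used by shifted-window attention)."""
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.roll(g, tuple(-s for s in shift), axis=axes))

        return Tensor._make(np.roll(a.data, shift, axis=axes), (a,), bwd,
                            a.requires_grad)

    # --------------------------------------------------------------- linalg
    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product; batch dimensions must match exactly."""
        a, b = self, other
        if a.ndim >= 3 or b.ndim >= 3:
            if a.shape[:-2] != b.shape[:-2]:
                raise ValueError(
                    f"batch dims must match: {a.shape} vs {b.shape}"
                )

        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
            if b.requires_grad:
                b._accumulate(np.matmul(np.swapaxes(a.data, -1, -2), g))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd,
                            Tensor._needs(a, b))

    def dot_last(self, w: "Tensor") -> "Tensor":
        """Contract the last axis with a 2-D weight ``(C_in, C_out)``.

        The affine map behind dense layers and 1x1 convolutions applied to
        ``(..., C_in)`` tensors.
        """
        a = self
        out_data = a.data @ w.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ w.data.T)
            if w.requires_grad:
                lead = int(np.prod(a.shape[:-1]))
                w._accumulate(
                    a.data.reshape(lead, a.shape[-1]).T @ g.reshape(lead, g.shape[-1])
                )

        return Tensor._make(out_data, (a, w), bwd, Tensor._needs(a, w))

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        return Tensor._make(y, (a,), bwd, a.requires_grad)

    # --------------------------------------------------------- image-shaped
    def conv2d(self, w: "Tensor", b: Optional["Tensor"] = None) -> "Tensor":
        """Same-padding stride-1 2-D convolution on NHWC input.

        ``w`` has shape ``(kh, kw, C_in, C_out)``; realized as one GEMM per
        kernel offset, which is the fastest pure-NumPy formulation.
        """
        a = self
        N, H, W, Cin = a.shape
        kh, kw, win, Cout = w.shape
        if win != Cin:
            raise ValueError(f"conv weight expects C_in={win}, input has C_in={Cin}")
        ph, pw = kh // 2, kw // 2
        xp = np.pad(a.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        out = np.zeros((N * H * W, Cout), dtype=a.dtype)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i : i + H, j : j + W, :]
                out += patch.reshape(-1, Cin) @ w.data[i, j]
        out = out.reshape(N, H, W, Cout)
        if b is not None:
            out += b.data

        def bwd(g):
            g2 = g.reshape(-1, Cout)
            if b is not None and b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, i : i + H, j : j + W, :]
                        gw[i, j] = patch.reshape(-1, Cin).T @ g2
                w._accumulate(gw)
            if a.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, i : i + H, j : j + W, :] += (
                            g2 @ w.data[i, j].T
                        ).reshape(N, H, W, Cin)
                a._accumulate(gxp[:, ph : ph + H, pw : pw + W, :])

        return Tensor._make(out, (a, w, b), bwd, Tensor._needs(a, w, b))

    def avg_pool2x2(self) -> "Tensor":
        a = self
        N, H, W, C = a.shape
        if H % 2 or W % 2:
            raise ValueError(f"avg_pool2x2 needs even spatial dims, got {H}x{W}")
        out = a.data.reshape(N, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

        def bwd(g):
            if a.requires_grad:
                gg = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
                a._accumulate(gg)

        return Tensor._make(out, (a,), bwd, a.requires_grad)

    def upsample_nearest2x(self) -> "Tensor":
        a = self
        out = np.repeat(np.repeat(a.data, 2, axis=1), 2, axis=2)

        def bwd(g):
            if a.requires_grad:
                N, H2, W2, C = g.shape
                a._accumulate(
                    g.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))
                )

        return Tensor._make(out, (a,), bwd, a.requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd, Tensor._needs(*tensors))


def a_mod(ax: int, ndim: int) -> int:
    return ax % ndim


def _axis_size(shape: tuple[int, ...], axis) -> int:
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = 1
    for ax in axes:
        n *= shape[a_mod(ax, len(shape))]
    return n
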