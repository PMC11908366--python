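"""Perceptual image distance through a fixed random convolutional feature
stack.

A feature-space distance in the LPIPS family: both images are pushed through
the same frozen convolutional pyramid and the mean squared feature
difference is accumulated over levels.  The filters are random (fixed seed),
not learned — random convolutional features are a long-standing baseline for
perceptual similarity, require no external weights, and satisfy
``d(x, x) = 0`` and ``d >= 0`` by construction.  Any callable with the same
contract (e.g. a true pretrained LPIPS wrapper) can be plugged in wherever a
perceptual metric is accepted.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import Conv2d, Module

__all__ = ["RandomFeaturePerceptual"]


class RandomFeaturePerceptual(Module):
    """Frozen random conv pyramid; callable on arrays or autodiff tensors.

    Parameters
    ----------
    channels : feature width per level.
    levels : number of conv+pool levels (receptive field grows 2x per level).
    seed : filter seed; two instances with the same seed are identical.
    """

    def __init__(self, channels: int = 8, levels: int = 3, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.dtype = dtype
        self.convs = []
        c_in = 1
        for _ in range(levels):
            conv = Conv2d(c_in, channels, 3, rng, dtype)
            for p in conv.parameters():  # frozen: metric, not a model
                p.requires_grad = False
            self.convs.append(conv)
            c_in = channels

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for lvl, conv in enumerate(self.convs):
            h = conv(h).silu()
            feats.append(h)
            if lvl < self.levels - 1:
                n, hh, ww, c = h.shape
                if hh % 2 == 0 and ww % 2 == 0:
                    h = h.avg_pool2x2()
        return feats

    def distance_t(self, a: Tensor, b: Tensor) -> Tensor:
        """Differentiable distance between ``(N, H, W, 1)`` tensors."""
        total = None
        for fa, fb in zip(self.features(a), self.features(b)):
            d = fa - fb
            term = (d * d).mean()
            total = term if total is None else total + term
        return total

    def __call__(self, a: np.ndarray, b: np.ndarray) -> float:
        """Plain-array API: perceptual distance between two 2-D images."""
        a = np.asarray(a, dtype=self.dtype)
        b = np.asarray(b, dtype=self.dtype)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        ta = Tensor(a[None, :, :, None])
        tb = Tensor(b[None, :, :, None])
        return float(self.distance_t(ta, tb).data)
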