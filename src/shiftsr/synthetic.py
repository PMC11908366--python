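"""Synthetic paired HR/LR phantom slices.

Emulates the data regime the method targets: smooth anatomy-like 2-D slices
(soft-edged ellipse composites, in the spirit of skull-stripped quantitative
brain maps — tissue inside a foreground disk, exact zeros outside) degraded
by image-space downsampling by an integer factor per axis and nearest-
neighbor re-upsampling onto the HR grid.  Presets mirror the two study
settings: x4 per axis (brain) and x3 in-plane (prostate).

What it does *not* emulate: MR acquisition physics (coil profiles, k-space
undersampling, bias fields) or 3-D through-plane resolution loss — slices
are independent 2-D images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .diffusion import PairedSlice

__all__ = [
    "PhantomSpec",
    "DegradeSpec",
    "make_phantom",
    "degrade",
    "make_pair",
    "make_dataset",
    "make_split",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy-emulating phantom parameters.

    size : HR grid extent in pixels (square slices).
    n_ellipses : number of soft-edged elliptical blobs composited.
    intensity_range : normalized output interval for foreground tissue.
    mask_radius_frac : radius of the circular foreground disk as a fraction
        of ``size`` (everything outside is exactly the background value 0,
        emulating a skull-stripping mask).
    noise_sd : additive Gaussian acquisition-noise level (normalized units).
    seed : phantom seed; generation is deterministic per seed.
    """

    size: int = 64
    n_ellipses: int = 6
    intensity_range: tuple[float, float] = (0.0, 1.0)
    mask_radius_frac: float = 0.45
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.intensity_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"intensity_range must be finite and ordered, got {self.intensity_range}")
        if self.size < 8:
            raise ValueError(f"phantom size must be >= 8, got {self.size}")


@dataclass(frozen=True)
class DegradeSpec:
    """Integer per-axis degradation factors; brain preset 4x4, prostate 3x3.

    ``antialias=True`` averages each ``factor_y x factor_x`` block before the
    nearest-neighbor re-upsampling (emulating an anti-aliased resampler);
    ``False`` picks the top-left sample of each block.
    """

    factor_y: int = 4
    factor_x: int = 4
    antialias: bool = True

    def __post_init__(self):
        if self.factor_y < 1 or self.factor_x < 1:
            raise ValueError(f"factors must be >= 1, got ({self.factor_y}, {self.factor_x})")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one HR phantom slice and its binary foreground mask."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    r_mask = spec.mask_radius_frac * n
    mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r_mask**2

    img = np.zeros((n, n))
    for _ in range(spec.n_ellipses):
        # centers concentrated inside the mask; axes span coarse-to-fine scales
        ecy = cy + rng.uniform(-0.6, 0.6) * r_mask
        ecx = cx + rng.uniform(-0.6, 0.6) * r_mask
        ay = rng.uniform(0.08, 0.45) * r_mask
        ax = rng.uniform(0.08, 0.45) * r_mask
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0], p=[0.3, 0.7])
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - ecy) * ct + (xx - ecx) * st
        v = -(yy - ecy) * st + (xx - ecx) * ct
        d = (u / ay) ** 2 + (v / ax) ** 2
        img += amp * expit((1.0 - d) / 0.15)  # soft ellipse edge

    img = gaussian_filter(img, sigma=1.0)
    img += spec.noise_sd * rng.standard_normal(img.shape)

    lo, hi = spec.intensity_range
    fg = img[mask]
    span = fg.max() - fg.min()
    if span <= 0:  # degenerate (e.g. n_ellipses=0, noise_sd=0)
        img = np.full_like(img, 0.5 * (lo + hi))
    else:
        img = lo + (hi - lo) * (img - fg.min()) / span
    img = np.clip(img, lo, hi)
    img[~mask] = 0.0
    return img, mask


def degrade(hr: np.ndarray, spec: DegradeSpec) -> np.ndarray:
    """Downsample by the integer factors, then nearest-neighbor upsample back.

    The output lives on the HR grid and is piecewise constant over
    ``factor_y x factor_x`` blocks.
    """
    hr = np.asarray(hr, dtype=np.float64)
    fy, fx = spec.factor_y, spec.factor_x
    h, w = hr.shape
    if h % fy or w % fx:
        raise ValueError(f"factors ({fy}, {fx}) do not divide image shape ({h}, {w})")
    if spec.antialias:
        small = hr.reshape(h // fy, fy, w // fx, fx).mean(axis=(1, 3))
    else:
        small = hr[::fy, ::fx]
    return np.kron(small, np.ones((fy, fx)))


def make_pair(phantom_spec: PhantomSpec, degrade_spec: DegradeSpec) -> PairedSlice:
    """One paired slice: phantom HR, degraded LR, recomputed residual."""
    if phantom_spec.size % degrade_spec.factor_y or phantom_spec.size % degrade_spec.factor_x:
        raise ValueError(
            f"phantom size {phantom_spec.size} not divisible by degradation "
            f"factors ({degrade_spec.factor_y}, {degrade_spec.factor_x})"
        )
    hr, mask = make_phantom(phantom_spec)
    lr = degrade(hr, degrade_spec)
    return PairedSlice(hr=hr, lr=lr, mask=mask)


def make_dataset(
    n: int,
    phantom_spec: PhantomSpec = PhantomSpec(),
    degrade_spec: DegradeSpec = DegradeSpec(),
    seed: int = 0,
) -> list[PairedSlice]:
    """``n`` independent pairs with per-slice seeds derived from ``seed``."""
    if n <= 0:
        raise ValueError(f"dataset size must be positive, got {n}")
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [
        make_pair(replace(phantom_spec, seed=int(s)), degrade_spec) for s in seeds
    ]


def make_split(
    n_train: int,
    n_test: int,
    phantom_spec: PhantomSpec = PhantomSpec(),
    degrade_spec: DegradeSpec = DegradeSpec(),
    seed: int = 0,
) -> tuple[list[PairedSlice], list[PairedSlice]]:
    """Non-overlapping train/test sets from disjoint seed streams."""
    ss_train, ss_test = np.random.SeedSequence(seed).spawn(2)
    train_seeds = ss_train.generate_state(n_train) % (2**31)
    test_seeds = ss_test.generate_state(n_test) % (2**31)
    train = [make_pair(replace(phantom_spec, seed=int(s)), degrade_spec) for s in train_seeds]
    test = [make_pair(replace(phantom_spec, seed=int(s)), degrade_spec) for s in test_seeds]
    return train, test
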