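"""Residual-shifting diffusion: forward kernels, posterior, few-step sampler.

The forward process degrades a high-resolution image ``x_HR`` toward its
(pre-upsampled) low-resolution counterpart ``x_LR`` by injecting the residual
``e0 = x_LR - x_HR`` plus Gaussian noise along the shifting sequence:

* stepwise kernel:  ``x_t = x_{t-1} + alpha_t * e0 + gamma * sqrt(alpha_t) * eps``
* closed-form marginal: ``x_t = x_HR + beta_t * e0 + gamma * sqrt(beta_t) * eps``

so the terminal distribution centers on the LR image instead of pure noise.
The reverse transition between any two schedule levels ``t_hi > t_lo`` is the
product of two Gaussians and hence Gaussian itself; substituting the network's
clean-image estimate for ``x_HR`` in its mean gives the sampler.  Because
``beta_0 = 0``, the final transition collapses deterministically onto the
estimate, which is what makes sampling in very few steps exact for a perfect
denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .schedule import NoiseSchedule

__all__ = [
    "PairedSlice",
    "DiffusionState",
    "forward_step",
    "forward_marginal",
    "posterior_params",
    "reverse_sample",
]


@dataclass
class PairedSlice:
    """An aligned HR/LR slice pair on the same pixel grid.

    ``e0`` is always recomputed as ``lr - hr`` (never trusted from the
    caller); ``mask`` is an optional binary foreground map (1 = tissue).
    """

    hr: np.ndarray
    lr: np.ndarray
    e0: np.ndarray = field(init=False)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=np.float64)
        self.lr = np.asarray(self.lr, dtype=np.float64)
        if self.hr.ndim != 2:
            raise ValueError(f"expected 2-D slices, got ndim={self.hr.ndim}")
        if self.hr.shape != self.lr.shape:
            raise ValueError(f"hr shape {self.hr.shape} != lr shape {self.lr.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.hr.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != image shape {self.hr.shape}"
                )
        self.e0 = self.lr - self.hr

    @property
    def shape(self) -> tuple[int, int]:
        return self.hr.shape


@dataclass
class DiffusionState:
    """An image together with its diffusion time index (0 = clean)."""

    x: np.ndarray
    t: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.t < 0:
            raise IndexError(f"time index must be >= 0, got {self.t}")


def _check_noise(noise: Optional[np.ndarray], shape: tuple[int, ...],
                 rng: Optional[np.random.Generator]) -> np.ndarray:
    if noise is None:
        gen = rng if rng is not None else np.random.default_rng()
        return gen.standard_normal(shape)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != shape:
        raise ValueError(f"noise shape {noise.shape} != image shape {shape}")
    return noise


def forward_step(
    prev: DiffusionState,
    e0: np.ndarray,
    schedule: NoiseSchedule,
    noise: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> DiffusionState:
    """One stepwise forward transition ``x_{t-1} -> x_t``.

    ``x_t = x_{t-1} + alpha_t * e0 + gamma * sqrt(alpha_t) * eps`` where
    ``t = prev.t + 1``.  Pass ``noise`` to fix ``eps`` (e.g. zeros for the
    deterministic drift), otherwise it is drawn from ``rng``.
    """
    t = prev.t + 1
    if not 1 <= t <= schedule.T:
        raise IndexError(f"forward step to t={t} outside [1, {schedule.T}]")
    e0 = np.asarray(e0, dtype=np.float64)
    if e0.shape != prev.x.shape:
        raise ValueError(f"e0 shape {e0.shape} != state shape {prev.x.shape}")
    eps = _check_noise(noise, prev.x.shape, rng)
    a = schedule.alpha(t)
    x_t = prev.x + a * e0 + schedule.gamma * np.sqrt(a) * eps
    return DiffusionState(x=x_t, t=t)


def forward_marginal(
    pair: PairedSlice,
    t: int,
    schedule: NoiseSchedule,
    noise: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> DiffusionState:
    """Sample the closed-form marginal ``q(x_t | x_HR, x_LR)`` directly.

    ``x_t = x_HR + beta_t * e0 + gamma * sqrt(beta_t) * eps``; equivalent in
    distribution to composing ``forward_step`` ``t`` times but needs a single
    draw.
    """
    if not 1 <= t <= schedule.T:
        raise IndexError(f"t={t} outside [1, {schedule.T}]")
    eps = _check_noise(noise, pair.hr.shape, rng)
    b = schedule.beta(t)
    x_t = pair.hr + b * pair.e0 + schedule.gamma * np.sqrt(b) * eps
    return DiffusionState(x=x_t, t=t)


def posterior_params(
    x_t: np.ndarray,
    x0_hat: np.ndarray,
    t_hi: int,
    t_lo: int,
    schedule: NoiseSchedule,
) -> tuple[np.ndarray, float]:
    """Mean and (scalar) variance of the reverse transition ``t_hi -> t_lo``.

    With ``b_hi = beta_{t_hi}``, ``b_lo = beta_{t_lo}`` (``beta_0 = 0``) and
    ``a = b_hi - b_lo``:

    * mean     = ``(b_lo / b_hi) * x_t + (a / b_hi) * x0_hat``
    * variance = ``gamma**2 * a * b_lo / b_hi``

    For adjacent steps (``t_lo = t_hi - 1``) this is exactly the
    product-of-Gaussians posterior with mean
    ``(beta_{t-1}/beta_t) x_t + (alpha_t/beta_t) x_HR`` and variance
    ``gamma**2 alpha_t beta_{t-1} / beta_t``; for wider gaps it is the same
    construction applied to the closed-form marginals, which is what makes
    any subsequence of the training schedule a valid sampling path.
    """
    if not 0 <= t_lo < t_hi <= schedule.T:
        raise IndexError(f"need 0 <= t_lo < t_hi <= {schedule.T}, got ({t_hi}, {t_lo})")
    x_t = np.asarray(x_t, dtype=np.float64)
    x0_hat = np.asarray(x0_hat, dtype=np.float64)
    if x_t.shape != x0_hat.shape:
        raise ValueError(f"x_t shape {x_t.shape} != x0_hat shape {x0_hat.shape}")
    b_hi = schedule.beta(t_hi)
    b_lo = schedule.beta(t_lo)
    a = b_hi - b_lo
    mean = (b_lo / b_hi) * x_t + (a / b_hi) * x0_hat
    var = schedule.gamma**2 * a * b_lo / b_hi
    return mean, float(var)


def reverse_sample(
    lr: np.ndarray,
    denoiser: Callable[[np.ndarray, np.ndarray, int], np.ndarray],
    schedule: NoiseSchedule,
    steps: Optional[Sequence[int]] = None,
    rng_seed: int = 0,
    return_trajectory: bool = False,
):
    """Few-step reverse sampling from a low-resolution image.

    Initializes ``x_T ~ Normal(lr, gamma**2 * beta_T)`` and walks the step
    subsequence downward; at each transition the denoiser's clean-image
    estimate ``x0_hat = denoiser(x_t, lr, t)`` enters the posterior mean, and
    Gaussian noise scaled by the posterior standard deviation is injected at
    every transition except the final one (``beta_0 = 0`` forces zero
    variance there).  Deterministic for a fixed ``rng_seed``.

    Parameters
    ----------
    steps : increasing step indices ending at ``schedule.T``; defaults to the
        full ``1..T``.  A subsequence of length ``S`` performs exactly ``S``
        reverse transitions.
    return_trajectory : also return the list of intermediate states.
    """
    lr = np.asarray(lr, dtype=np.float64)
    if steps is None:
        steps = list(range(1, schedule.T + 1))
    steps = [int(s) for s in steps]
    if not steps or steps[-1] != schedule.T:
        raise ValueError(f"step subsequence must end at T={schedule.T}, got {steps}")
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise ValueError(f"step subsequence must be strictly increasing, got {steps}")
    if not 1 <= steps[0]:
        raise IndexError(f"steps must lie in [1, {schedule.T}], got {steps}")

    rng = np.random.default_rng(rng_seed)
    gamma = schedule.gamma
    x = lr + gamma * np.sqrt(schedule.beta_T) * rng.standard_normal(lr.shape)
    trajectory = [DiffusionState(x=x, t=schedule.T)]

    # walk t_hi over the subsequence (descending); t_lo is the next one down,
    # ending at 0 where the posterior collapses onto the estimate
    descending = steps[::-1]
    for i, t_hi in enumerate(descending):
        t_lo = descending[i + 1] if i + 1 < len(descending) else 0
        x0_hat = np.asarray(denoiser(x, lr, t_hi), dtype=np.float64)
        if x0_hat.shape != lr.shape:
            raise ValueError(
                f"denoiser returned shape {x0_hat.shape}, expected {lr.shape}"
            )
        mean, var = posterior_params(x, x0_hat, t_hi, t_lo, schedule)
        if var > 0.0:
            x = mean + np.sqrt(var) * rng.standard_normal(lr.shape)
        else:
            x = mean
        trajectory.append(DiffusionState(x=x, t=t_lo))

    if return_trajectory:
        return x, trajectory
    return x
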