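"""Residual-shifting noise schedule.

The forward process moves a high-resolution image toward its low-resolution
counterpart along a monotone *shifting sequence* ``beta_1 < ... < beta_T``:
by step ``t`` the mean has absorbed ``beta_t`` of the residual
``e0 = x_LR - x_HR`` and the variance has grown to ``gamma**2 * beta_t``.
The per-step increments ``alpha_t = beta_t - beta_{t-1}`` (with
``alpha_1 = beta_1``) drive the stepwise transition kernel.

The schedule is geometric: ``beta_1`` is pinned near zero through the
smallness target ``gamma * sqrt(beta_1) = kappa`` and the remaining entries
interpolate to the terminal value on a log scale with growth exponent ``p``
(smaller ``p`` front-loads the shift, i.e. larger ``beta_t`` at interior
steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "build_schedule", "select_sampling_timesteps"]

#: Defaults used throughout the package: 15 training steps, growth exponent
#: 0.3, noise scale 2, smallness target 0.04 and terminal value 0.9999.
DEFAULT_T = 15
DEFAULT_P = 0.3
DEFAULT_GAMMA = 2.0
DEFAULT_KAPPA = 0.04
DEFAULT_BETA_T = 0.9999


@dataclass(frozen=True)
class NoiseSchedule:
    """Realized shifting sequence plus the hyper-parameters that built it.

    Attributes
    ----------
    T : int
        Number of diffusion steps (>= 2).
    p : float
        Growth-rate exponent of the geometric interpolation.
    gamma : float
        Noise scale; the marginal variance at step ``t`` is
        ``gamma**2 * beta_t``.
    kappa : float
        Smallness target: ``gamma * sqrt(beta_1) == kappa``.
    betas : np.ndarray
        ``beta_1 .. beta_T`` (shape ``(T,)``), strictly increasing.
    alphas : np.ndarray
        Increments ``alpha_1 = beta_1``, ``alpha_t = beta_t - beta_{t-1}``.
    beta0 : float
        Convention ``beta_0 = 0`` so the ``t=1`` reverse transition collapses
        deterministically onto the clean estimate.
    """

    T: int
    p: float
    gamma: float
    kappa: float
    betas: np.ndarray
    alphas: np.ndarray
    beta0: float = field(default=0.0)

    def beta(self, t: int) -> float:
        """``beta_t`` for ``t`` in ``[0, T]`` (``beta_0 == 0``)."""
        if not 0 <= t <= self.T:
            raise IndexError(f"t={t} outside [0, {self.T}]")
        return self.beta0 if t == 0 else float(self.betas[t - 1])

    def alpha(self, t: int) -> float:
        """``alpha_t`` for ``t`` in ``[1, T]``."""
        if not 1 <= t <= self.T:
            raise IndexError(f"t={t} outside [1, {self.T}]")
        return float(self.alphas[t - 1])

    @property
    def beta_T(self) -> float:
        return float(self.betas[-1])

    def fingerprint(self) -> str:
        """Stable hash of the defining parameters.

        Checkpoints embed this so a model can never be sampled under a
        schedule it was not trained with (the posterior coefficients are
        schedule-dependent).
        """
        import hashlib

        key = f"T={self.T};p={self.p!r};gamma={self.gamma!r};kappa={self.kappa!r};betaT={self.beta_T!r}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def build_schedule(
    T: int = DEFAULT_T,
    p: float = DEFAULT_P,
    gamma: float = DEFAULT_GAMMA,
    kappa: float = DEFAULT_KAPPA,
    beta_T: float = DEFAULT_BETA_T,
) -> NoiseSchedule:
    """Construct the geometric shifting sequence.

    ``beta_1 = (kappa / gamma)**2`` and, for ``t >= 2``,

    ``beta_t = beta_1 * exp(((t - 1) / (T - 1))**p * log(beta_T / beta_1))``.

    The closed form is evaluated for every ``t`` in ``[1, T]``; at the
    endpoints it reduces analytically to ``beta_1`` and ``beta_T``, so no
    special-casing is needed.

    Raises
    ------
    ValueError
        If ``T < 2``, ``p <= 0``, or ``beta_T`` does not satisfy
        ``(kappa/gamma)**2 < beta_T <= 1``.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if p <= 0:
        raise ValueError(f"growth exponent p must be > 0, got {p}")
    beta1 = (kappa / gamma) ** 2
    if not 0.0 < beta1 < beta_T <= 1.0:
        raise ValueError(
            f"need 0 < (kappa/gamma)^2 < beta_T <= 1; got beta_1={beta1!r}, beta_T={beta_T!r}"
        )
    t = np.arange(1, T + 1, dtype=np.float64)
    frac = ((t - 1.0) / (T - 1.0)) ** p
    betas = beta1 * np.exp(frac * np.log(beta_T / beta1))
    # pin the endpoints exactly (the closed form hits them to rounding only)
    betas[0] = beta1
    betas[-1] = beta_T
    if not np.all(np.diff(betas) > 0):  # impossible for valid inputs
        raise AssertionError("schedule is not strictly increasing")
    alphas = np.diff(betas, prepend=0.0)
    return NoiseSchedule(T=T, p=p, gamma=gamma, kappa=kappa, betas=betas, alphas=alphas)


def select_sampling_timesteps(schedule: NoiseSchedule, S: int) -> list[int]:
    """Pick ``S`` strictly increasing step indices ending at ``T``.

    Few-step sampling traverses a subsequence of the training schedule; the
    generalized posterior makes any subsequence valid, and we use evenly
    spaced indices (in ``t``) that always include ``T``.  ``S == T`` returns
    the full ``1..T``; ``S == 1`` returns ``[T]`` (a single collapse).
    """
    T = schedule.T
    if not 1 <= S <= T:
        raise ValueError(f"S must lie in [1, {T}], got {S}")
    if S == 1:
        return [T]
    idx = np.round(np.linspace(1, T, S)).astype(int)
    steps = sorted(set(int(i) for i in idx))
    assert len(steps) == S and steps[-1] == T
    return steps
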