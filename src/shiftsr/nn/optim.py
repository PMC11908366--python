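"""Rectified Adam (RAdam).

Adam whose adaptive step is switched off while the variance estimate is
still untrustworthy (early steps) and rectified afterwards; removes the need
for ad-hoc warmup of the *adaptive* term (the learning-rate warmup schedule
is separate, see :mod:`shiftsr.training`).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["RAdam"]


class RAdam:
    def __init__(self, params: list[Tensor], lr: float = 3e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        b1t, b2t = b1**t, b2**t
        rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho > 4.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1t)
            if r is not None:
                v_hat = np.sqrt(v / (1.0 - b2t))
                p.data -= (self.lr * r) * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
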