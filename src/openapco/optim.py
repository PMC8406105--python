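"""Gradient-descent optimizers: rectified Adam wrapped by Lookahead.

RAdam rectifies the variance of the adaptive learning rate in early
training (falling back to un-adapted momentum SGD while the second-moment
estimate is unreliable); Lookahead keeps a slow copy of the weights and
every ``sync_period`` steps interpolates it toward the fast weights by
``alpha``, then restarts the fast weights from it.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["RAdam", "Lookahead"]


class RAdam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = self.b1**self.t
        b2t = self.b2**self.t
        rho_t = self.rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            m_hat = m / (1.0 - b1t)
            if rho_t > 4.0:  # variance of the adaptive lr is tractable
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:  # warmup: plain momentum update
                p.data -= self.lr * m_hat


class Lookahead:
    """Slow-weights wrapper around an inner optimizer."""

    def __init__(self, inner: RAdam, sync_period: int = 5, alpha: float = 0.5):
        self.inner = inner
        self.sync_period = sync_period
        self.alpha = alpha
        self.slow = [p.data.copy() for p in inner.params]
        self.k = 0

    @property
    def params(self) -> list[Tensor]:
        return self.inner.params

    @property
    def lr(self) -> float:
        return self.inner.lr

    @lr.setter
    def lr(self, value: float) -> None:
        self.inner.lr = value

    def zero_grad(self) -> None:
        self.inner.zero_grad()

    def step(self) -> None:
        self.inner.step()
        self.k += 1
        if self.k % self.sync_period == 0:
            for slow, p in zip(self.slow, self.inner.params):
                slow += self.alpha * (p.data - slow)
                p.data[...] = slow

    def sync_state(self) -> None:
        """Re-anchor the slow weights at the current fast weights."""
        for slow, p in zip(self.slow, self.inner.params):
            slow[...] = p.data
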