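"""Optimizers: Adam, RAdam, and Ranger (RAdam + Lookahead), plus cosine decay.

Only parameters with ``requires_grad=True`` are updated, which is how backbone
freezing is realized.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import DTYPE
from .layers import Parameter

__all__ = ["Adam", "RAdam", "Ranger", "cosine_lr"]


class _AdamBase:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            self._update(i, p)

    def _update(self, i: int, p: Parameter) -> None:  # pragma: no cover
        raise NotImplementedError


class Adam(_AdamBase):
    def _update(self, i: int, p: Parameter) -> None:
        mhat = self.m[i] / (1 - self.beta1 ** self.t)
        vhat = self.v[i] / (1 - self.beta2 ** self.t)
        p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


class RAdam(_AdamBase):
    """Rectified Adam: variance rectification of the adaptive learning rate."""

    def _update(self, i: int, p: Parameter) -> None:
        t = self.t
        beta2t = self.beta2 ** t
        rho_inf = 2 / (1 - self.beta2) - 1
        rho = rho_inf - 2 * t * beta2t / (1 - beta2t)
        mhat = self.m[i] / (1 - self.beta1 ** t)
        if rho > 4:
            vhat = np.sqrt(self.v[i] / (1 - beta2t))
            r = math.sqrt(((rho - 4) * (rho - 2) * rho_inf)
                          / ((rho_inf - 4) * (rho_inf - 2) * rho))
            p.data -= (self.lr * r * mhat / (vhat + self.eps)).astype(DTYPE)
        else:
            p.data -= (self.lr * mhat).astype(DTYPE)


class Ranger(RAdam):
    """RAdam with Lookahead slow weights (k steps, interpolation alpha)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, lookahead_k: int = 6,
                 lookahead_alpha: float = 0.5):
        super().__init__(params, lr=lr, betas=betas, eps=eps,
                         weight_decay=weight_decay)
        self.lookahead_k = lookahead_k
        self.lookahead_alpha = lookahead_alpha
        self.slow = [p.data.copy() for p in self.params]

    def step(self) -> None:
        super().step()
        if self.t % self.lookahead_k == 0:
            a = self.lookahead_alpha
            for i, p in enumerate(self.params):
                self.slow[i] += a * (p.data - self.slow[i])
                p.data = self.slow[i].copy()


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine decay from ``base_lr`` to 0 over ``total_steps``."""
    if total_steps <= 0:
        return base_lr
    frac = min(step / total_steps, 1.0)
    return 0.5 * base_lr * (1 + math.cos(math.pi * frac))
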