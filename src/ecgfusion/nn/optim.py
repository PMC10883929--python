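"""Optimizers for the NumPy layer library."""

from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["Adam", "SGD"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params: list[Param], lr: float = 1e-2, momentum: float = 0.0):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            b *= self.momentum
            b += p.grad
            p.value -= self.lr * b

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
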