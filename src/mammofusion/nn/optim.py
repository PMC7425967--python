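"""Stochastic gradient descent with momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD"]


class SGD:
    """Classic momentum SGD: v <- m*v + (g + wd*w); w <- w - lr*v."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        if lr < 0:
            raise ValueError("lr must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
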