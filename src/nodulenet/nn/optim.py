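"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    """``v <- mu*v - lr*g;  w <- w + v`` over an explicit parameter list.

    Only parameters handed to the constructor are ever updated, which is how
    stage-wise freezing is implemented: build the optimizer over the subset
    that should learn.
    """

    def __init__(self, params: list[tuple[str, Parameter]], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = [(n, p) for n, p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = {n: np.zeros_like(p.value) for n, p in self.params}

    def step(self):
        for name, p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v = self._vel[name]
            v *= self.momentum
            v -= self.lr * g
            p.value += v

    def zero_grad(self):
        for _, p in self.params:
            p.grad[...] = 0.0
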