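"""Gradient-descent optimizers (Adam and RMSProp) for :class:`~filternet.nn.core.Parameter` lists.

Weight decay is the classic L2 formulation (decay added to the gradient before
the adaptive update), matching the convention of mainstream deep-learning
Adam implementations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "RMSProp", "make_optimizer"]


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSProp:
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = alpha
        self.eps = eps
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.value -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, params, lr: float, weight_decay: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr, weight_decay=weight_decay)
    if name == "rmsprop":
        return RMSProp(params, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; expected 'adam' or 'rmsprop'")
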