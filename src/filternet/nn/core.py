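"""Minimal explicit-backprop building blocks.

Every module caches what it needs during ``forward`` and consumes that cache in
``backward``.  All arrays are float64, channel-major ``(batch, channels, length)``.
There is no autograd graph: the network classes wire the backward pass by hand,
which keeps the dependency surface to NumPy alone and makes every gradient
auditable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Module"]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Parameter({self.name or 'unnamed'}, shape={self.value.shape})"


class Module:
    """Base class: ``forward(x, train, rng)`` then ``backward(grad)``."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x, train: bool = False, rng=None):
        return self.forward(x, train=train, rng=rng)
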