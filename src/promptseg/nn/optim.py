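"""AdamW optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """AdamW: Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr at epoch 0 to 0 at `total_epochs`."""
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    frac = min(max(epoch / total_epochs, 0.0), 1.0)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))
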