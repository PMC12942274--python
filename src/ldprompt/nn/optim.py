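"""AdamW optimizer and the cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from lr0 to 0 over `total_epochs` (epoch is 0-based)."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))


class AdamW:
    """Adam with decoupled weight decay; weight_decay=0 recovers plain Adam."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
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
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            scale = getattr(p, "lr_scale", 1.0)
            p.data = p.data - self.lr * scale * update
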