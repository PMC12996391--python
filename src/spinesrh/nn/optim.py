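"""Optimizers and learning-rate schedules for the numpy network stack."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with decoupled constant hyperparameters.

    Parameters are the ``Tensor`` leaves of a model; ``step`` consumes the
    accumulated ``.grad`` arrays and leaves gradients untouched (call
    ``zero_grad`` on the model between steps).
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              min_frac: float = 0.05) -> float:
    """Cosine decay from ``base_lr`` to ``min_frac * base_lr``."""
    if total_steps <= 1:
        return base_lr
    frac = 0.5 * (1 + np.cos(np.pi * min(step, total_steps) / total_steps))
    return base_lr * (min_frac + (1 - min_frac) * frac)
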