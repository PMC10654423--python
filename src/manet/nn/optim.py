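"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (Kingma & Ba defaults)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= (self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size=30, gamma=0.1):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.step_size = int(step_size)
        self.gamma = float(gamma)

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * self.gamma ** (epoch // self.step_size)

    def set_epoch(self, epoch: int):
        self.optimizer.lr = self.lr_at(epoch)
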