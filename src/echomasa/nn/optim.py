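"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled weight decay Adam."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class StepLR:
    """Multiply the learning rate by ``gamma`` at each milestone epoch."""

    def __init__(self, optimizer: AdamW, milestones=(30, 45), gamma=0.1):
        self.optimizer = optimizer
        self.milestones = set(milestones)
        self.gamma = gamma
        self.epoch = 0

    def step_epoch(self) -> None:
        self.epoch += 1
        if self.epoch in self.milestones:
            self.optimizer.lr *= self.gamma
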