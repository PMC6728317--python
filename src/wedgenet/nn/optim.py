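"""Optimizers and the warmup/decay learning-rate schedule used for both GANs."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr=4e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr=4e-4, alpha=0.99, eps=1e-8, weight_decay=1e-4,
                 momentum=0.0):
        super().__init__(params, lr, weight_decay)
        self.alpha = alpha
        self.eps = eps
        self.momentum = momentum
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.buf = [np.zeros_like(p.data) for p in self.params] if momentum else None

    def step(self):
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            sq = self.sq[i]
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            upd = g / (np.sqrt(sq) + self.eps)
            if self.momentum:
                self.buf[i] = self.momentum * self.buf[i] + upd
                upd = self.buf[i]
            p.data -= self.lr * upd


def lr_for_epoch(epoch: int, base_lr: float = 4e-4,
                 warmup_lrs: tuple[float, ...] = (1e-4, 2e-4, 4e-4),
                 decay_epochs: tuple[int, ...] = (20, 28),
                 decay_factor: float = 0.1) -> float:
    """Learning rate for a 1-based epoch index.

    The schedule ramps through ``warmup_lrs`` over the first epochs, holds at
    ``base_lr``, then multiplies by ``decay_factor`` at the start of each epoch
    listed in ``decay_epochs``.  With the defaults: 1e-4, 2e-4, then 4e-4 held
    until epoch 19, 4e-5 for epochs 20-27 and 4e-6 from epoch 28 on.
    """
    if epoch < 1:
        raise ValueError("epoch index is 1-based")
    if epoch <= len(warmup_lrs):
        lr = warmup_lrs[epoch - 1]
    else:
        lr = base_lr
    for d in sorted(decay_epochs):
        if epoch >= d:
            lr *= decay_factor
    return lr
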