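"""Optimizers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np


class RMSProp:
    """Root-mean-square propagation with the conventional defaults
    (smoothing constant 0.99, epsilon 1e-8, no momentum)."""

    def __init__(self, params, lr: float = 1e-4, alpha: float = 0.99,
                 eps: float = 1e-8):
        self.params = list(params)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= (self.lr * g / (np.sqrt(sq) + self.eps)).astype(p.data.dtype)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored score has
    not improved for ``patience`` consecutive epochs (maximization)."""

    def __init__(self, optimizer: RMSProp, factor: float = 0.1, patience: int = 2,
                 min_lr: float = 1e-8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, score: float) -> bool:
        """Register an epoch score; returns True if the rate was reduced."""
        if score > self.best:
            self.best = score
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
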