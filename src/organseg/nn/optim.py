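"""Adam optimizer and plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored metric
    (higher is better) has not improved for ``patience`` epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 5,
                 min_delta: float = 1e-4) -> None:
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Record one epoch's metric; returns True if the LR was reduced."""
        if metric > self.best + self.min_delta:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False
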