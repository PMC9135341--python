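"""Optimizers operating in place on parameter/gradient array pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "NesterovSGD"]


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class NesterovSGD:
    """SGD with Nesterov momentum (momentum 0 gives plain SGD)."""

    def __init__(self, lr: float = 1e-3, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.lr, self.momentum = lr, momentum
        self._vel: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._vel is None:
            self._vel = [np.zeros_like(p) for p in params]
        mu = self.momentum
        for p, g, v in zip(params, grads, self._vel):
            v *= mu
            v -= self.lr * g
            p += mu * v - self.lr * g
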