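"""Optimizers over lists of parametrized layers."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, layers, lr: float):
        self.layers = list(layers)
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, layers, lr: float, momentum: float = 0.9):
        super().__init__(layers, lr)
        self.momentum = momentum
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()}
                     for l in self.layers]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self._vel):
            for k, p in layer.params.items():
                v = vel[k]
                v *= self.momentum
                v -= self.lr * layer.grads[k]
                p += v


class Adam(Optimizer):
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(layers, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in self.layers]

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * (g * g)
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
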