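"""Adam and SGD for the layer parameter lists of :mod:`mlecg.nn.layers`."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, parameters, lr):
        # parameters: list of (layer, param-name) handles
        self.parameters = parameters
        self.lr = lr

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, parameters, lr=0.001, momentum=0.0):
        super().__init__(parameters, lr)
        self.momentum = momentum
        self._v = [None] * len(parameters)

    def step(self):
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name]
            if self.momentum > 0:
                if self._v[i] is None:
                    self._v[i] = np.zeros_like(g)
                self._v[i] = self.momentum * self._v[i] - self.lr * g
                layer.params[name] += self._v[i]
            else:
                layer.params[name] -= self.lr * g


class Adam(Optimizer):
    def __init__(self, parameters, lr=0.001, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(parameters, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [None] * len(parameters)
        self._v = [None] * len(parameters)
        self._t = 0

    def step(self):
        self._t += 1
        b1t = 1 - self.b1 ** self._t
        b2t = 1 - self.b2 ** self._t
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name]
            if self._m[i] is None:
                self._m[i] = np.zeros_like(g)
                self._v[i] = np.zeros_like(g)
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / b1t
            vhat = self._v[i] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, parameters, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(parameters, lr=lr)
    if name == "sgd":
        return SGD(parameters, lr=lr)
    raise ValueError(f"unknown optimizer {name!r} (use 'Adam' or 'SGD')")
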