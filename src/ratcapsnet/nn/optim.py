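"""Optimizers for the NumPy layer stack."""

from __future__ import annotations

import numpy as np

from .layers import Module


class Adam:
    def __init__(self, modules: dict[str, Module], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.modules = modules
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for name, mod in modules.items():
            for key, p in mod.params.items():
                self.m[(name, key)] = np.zeros_like(p)
                self.v[(name, key)] = np.zeros_like(p)

    def zero_grad(self) -> None:
        for mod in self.modules.values():
            mod.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, mod in self.modules.items():
            for key, p in mod.params.items():
                g = mod.grads[key]
                m = self.m[(name, key)]
                v = self.v[(name, key)]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
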