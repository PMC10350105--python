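"""Minimal dense neural-network primitives with hand-written backprop.

Just what the physics-informed VAE needs: fully connected layers with tanh
hidden activations, gradient accumulation, and an Adam optimizer.  Forward
passes cache activations; ``backward`` consumes the upstream gradient and
returns the input gradient while accumulating parameter gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam"]


class Dense:
    """Affine layer y = x W + b with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            self.W = np.zeros((n_in, n_out))
        else:
            # Xavier/Glorot scaling for tanh trunks
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.W.T

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW[...] = 0.0
        self.gb[...] = 0.0


class MLP:
    """Dense stack with tanh between layers; linear (optionally zero-init) head."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, zero_init_head: bool = True):
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng, zero_init=last and zero_init_head))
        self._h = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._h = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                x = np.tanh(x)
                self._h.append(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            dy = self.layers[i].backward(dy)
            if i > 0:
                dy = dy * (1.0 - self._h[i - 1] ** 2)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


class Adam:
    """Adam over a list of (array, grad) pairs; updates arrays in place."""

    def __init__(self, params, lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
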