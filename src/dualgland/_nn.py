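"""Minimal numpy feed-forward network core with manual backprop.

Small dense generators/discriminators are entirely adequate at desk scale
(32-64 px images) and keep the package free of deep-learning framework
dependencies.  Layers cache their forward inputs; ``backward`` consumes the
upstream gradient and accumulates parameter gradients.  Adam with global
gradient-norm clipping matches the training configuration used throughout.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 init: str = "xavier"):
        if init == "xavier":  # Xavier uniform
            lim = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-lim, lim, size=(n_in, n_out))
        else:  # Kaiming normal
            self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=True):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, g):
        self.dW += self._x.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class LeakyReLU:
    def __init__(self, alpha=0.2):
        self.alpha = alpha
        self._m = None

    def forward(self, x, train=True):
        m = x >= 0
        if train:
            self._m = m
        return np.where(m, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._m, g, self.alpha * g)

    def params(self):
        return []


class Sigmoid:
    def __init__(self):
        self._y = None

    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    def params(self):
        return []


class Dropout:
    """Inverted dropout; deterministic given the generator's rng stream."""

    def __init__(self, rng: np.random.Generator, rate: float):
        self.rng = rng
        self.rate = rate
        self._mask = None

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class MLP:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self):
        for layer in self.layers:
            for _, grad in layer.params():
                grad[...] = 0.0

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def get_weights(self):
        return [np.array(p) for layer in self.layers for (p, _) in layer.params()]

    def set_weights(self, weights):
        flat = [p for layer in self.layers for (p, _) in layer.params()]
        for p, w in zip(flat, weights):
            p[...] = w


class Adam:
    def __init__(self, net: MLP, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8,
                 l2=0.0, clip_norm=None):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2 = l2
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p) for (p, _) in net.params()]
        self.v = [np.zeros_like(p) for (p, _) in net.params()]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        params = self.net.params()
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float(np.sum(g ** 2)) for (_, g) in params))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                for (_, g) in params:
                    g *= scale
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (p, g) in enumerate(params):
            if self.l2 > 0:
                g = g + self.l2 * p
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g ** 2
            p -= lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
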