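"""Minimal numpy neural-network primitives.

Dense / batch-norm / ReLU layers with analytic backward passes and an
Adam optimiser — just enough to train the triplet-loss embedding head
and keep everything deterministic under a seed.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.ggamma = (grad * xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        gx = grad * self.gamma
        if not self._training:
            return gx / std
        m = grad.shape[0]
        return (
            gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)
        ) / std if m > 1 else gx / std

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.ggamma, self.gbeta]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def state(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend(p.copy() for p in l.params)
            if isinstance(l, BatchNorm):
                out.extend([l.running_mean.copy(), l.running_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]):
        it = iter(state)
        for l in self.layers:
            for p in l.params:
                p[...] = next(it)
            if isinstance(l, BatchNorm):
                l.running_mean[...] = next(it)
                l.running_var[...] = next(it)


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
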