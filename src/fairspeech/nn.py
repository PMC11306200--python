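"""Minimal feedforward neural-network core (numpy, manual backprop).

The two networks in this package — a small softmax classifier and an
autoencoder with adversarial heads — are tiny (hundreds of units), trained
on tabular feature matrices, and must be bit-reproducible given a seed.
This module provides just the pieces they need: dense layers with He
initialization, ReLU, softmax cross-entropy, mean-squared-error, and Adam.

Gradients flow through explicit ``backward`` calls; each :class:`Dense`
caches its last input and accumulates parameter gradients, which
:class:`Adam` consumes.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Affine layer ``x @ W + b`` with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sequential:
    """A plain chain of layers with symmetric forward/backward."""

    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def dense_layers(self) -> list[Dense]:
        return [l for l in self.layers if isinstance(l, Dense)]

    def zero_grad(self) -> None:
        for l in self.dense_layers:
            l.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels ``y``; returns (loss, dlogits)."""
    p = softmax(logits)
    n = len(y)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_checksum(nets) -> float:
    """Deterministic scalar summarizing all weights (for reproducibility tests)."""
    total = 0.0
    for net in nets:
        for layer in net.dense_layers:
            total += float(np.sum(layer.W)) + float(np.sum(layer.b))
    return total


class Standardizer:
    """Per-feature z-scoring with parameters frozen from the training rows."""

    def __init__(self):
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
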