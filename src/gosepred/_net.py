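"""Minimal dense-network core with manual gradients.

The ordinal prediction networks here are small (a token-embedding or dense
trunk of at most a few hidden layers feeding a 6- or 7-node output head),
so forward/backward passes are written directly in NumPy: ReLU hidden
layers with He initialisation, inverted dropout, Adam updates, and
early stopping on a validation loss with best-weight restoration.
"""

from __future__ import annotations

import numpy as np


class MLPCore:
    """Fully connected trunk: layer_sizes[0] -> ... -> layer_sizes[-1].

    ReLU after every layer except the last (the head's transform is applied
    by the caller); optional inverted dropout on hidden activations.
    """

    def __init__(self, layer_sizes, rng: np.random.Generator, dropout: float = 0.0):
        self.dropout = dropout
        self.W, self.b = [], []
        for d_in, d_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / d_in)
            self.W.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params_flat(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        cache = {"inputs": [], "masks": []}
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            cache["inputs"].append(h)
            z = h @ W + b
            if i < last:
                h = np.maximum(z, 0.0)
                if train and self.dropout > 0.0:
                    mask = (rng.uniform(size=h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                else:
                    mask = None
                cache["masks"].append((z, mask))
            else:
                h = z
        return h, cache

    def backward(self, dout: np.ndarray, cache):
        """Returns (gradients aligned with :attr:`params`, gradient wrt input)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        grad = dout
        for i in range(len(self.W) - 1, -1, -1):
            h_in = cache["inputs"][i]
            gW[i] = h_in.T @ grad
            gb[i] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
            if i > 0:
                z, mask = cache["masks"][i - 1]
                if mask is not None:
                    grad = grad * mask
                grad = grad * (z > 0)
        return gW + gb, grad


class Adam:
    """Adaptive-moment gradient descent over a flat list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class EarlyStopper:
    """Track the best validation loss and stop after ``patience`` bad epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad = 0
        self.best_params: list[np.ndarray] | None = None

    def update(self, loss: float, params) -> bool:
        """Record an epoch; returns True when training should stop."""
        if loss < self.best - 1e-9:
            self.best = loss
            self.bad = 0
            self.best_params = [p.copy() for p in params]
            return False
        self.bad += 1
        return self.bad >= self.patience


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
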