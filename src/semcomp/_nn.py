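"""Minimal feed-forward building blocks with hand-derived gradients.

Only what the autoencoders need: dense layers with sigmoid or identity
activations and an Adam optimizer.  Everything is float32 and fully
deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """y = act(x W + b) with cached forward pass for backprop."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        if activation not in ("sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        y = x @ self.W + self.b
        if self.activation == "sigmoid":
            y = sigmoid(y)
        if cache:
            self._x, self._y = x, y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward before forward")
        if self.activation == "sigmoid":
            dy = dy * self._y * (1.0 - self._y)
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class MLP:
    """Stack of dense layers; hidden layers sigmoid, final layer linear."""

    def __init__(self, n_in: int, hidden: list[int], n_out: int, rng: np.random.Generator):
        sizes = [n_in] + list(hidden)
        self.layers = [
            Dense(a, b, "sigmoid", rng) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.layers.append(Dense(sizes[-1], n_out, "linear", rng))

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= (self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)).astype(p.dtype)
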