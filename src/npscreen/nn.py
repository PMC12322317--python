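"""Minimal feed-forward building blocks (numpy, manual backprop).

Tanh hidden layers, linear outputs, Adam updates.  Just enough machinery
for the autoencoder and the semi-supervised generative classifier; gradient
correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Fully-connected net: tanh on hidden layers, linear output layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (output, cache of layer inputs for backward)."""
        cache = [x]
        h = x
        for i in range(self.n_layers):
            W, b = self.params[2 * i], self.params[2 * i + 1]
            h = h @ W + b
            if i < self.n_layers - 1:
                h = np.tanh(h)
            cache.append(h)
        return h, cache

    def backward(self, cache: list[np.ndarray], dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop ``dout`` (grad wrt output); returns (dinput, param grads)."""
        grads: list[np.ndarray] = [None] * len(self.params)
        d = dout
        for i in range(self.n_layers - 1, -1, -1):
            h_in = cache[i]
            if i < self.n_layers - 1:
                # cache[i+1] stores tanh activations for hidden layers
                d = d * (1.0 - cache[i + 1] ** 2)
            W = self.params[2 * i]
            grads[2 * i] = h_in.T @ d
            grads[2 * i + 1] = d.sum(axis=0)
            d = d @ W.T
        return d, grads


class Adam:
    """Adam over a flat list of parameter arrays (shared across nets)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
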