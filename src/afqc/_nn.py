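"""Minimal 1-D convolutional network machinery (forward, backprop, Adam).

Self-contained and deterministic: every source of randomness (weight
initialization, dropout masks) is an explicit ``numpy.random.Generator``.
Data layout is ``(batch, length, channels)``.  Weights use uniform fan-in
initialization, U(-sqrt(6/fan_in), +sqrt(6/fan_in)).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "AvgPool1D", "ReLU", "Dropout", "Flatten", "Dense",
           "Sequential", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self):
        return []


class Conv1D(Layer):
    """Valid (no padding) strided 1-D convolution; W has shape (k, C_in, C_out)."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, l2: float = 0.0):
        self.k, self.s, self.l2 = kernel, stride, l2
        fan_in = kernel * c_in
        self.W = _fan_in_uniform(rng, (kernel, c_in, c_out), fan_in)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        B, L, C = x.shape
        l_out = (L - self.k) // self.s + 1
        # (B, L-k+1, C, k) -> strided -> (B, l_out, k, C) -> (B, l_out, k*C)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        cols = cols[:, ::self.s].transpose(0, 1, 3, 2)
        self._cols = np.ascontiguousarray(cols).reshape(B, l_out, -1)
        self._in_shape = x.shape
        Wf = self.W.reshape(-1, self.W.shape[-1])
        return self._cols @ Wf + self.b

    def backward(self, dy):
        B, l_out, c_out = dy.shape
        Wf = self.W.reshape(-1, c_out)
        self.dW = (np.einsum("blf,blo->fo", self._cols, dy)
                   .reshape(self.W.shape))
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db = dy.sum(axis=(0, 1))
        dcols = (dy @ Wf.T).reshape(B, l_out, self.k, -1)
        dx = np.zeros(self._in_shape)
        for ki in range(self.k):
            dx[:, ki: ki + self.s * l_out: self.s, :] += dcols[:, :, ki, :]
        return dx

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.W ** 2)) if self.l2 else 0.0

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class AvgPool1D(Layer):
    def __init__(self, kernel: int, stride: int):
        self.k, self.s = kernel, stride

    def forward(self, x, training, rng):
        B, L, C = x.shape
        l_out = (L - self.k) // self.s + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        self._in_shape = x.shape
        self._l_out = l_out
        return cols[:, ::self.s].mean(axis=-1)

    def backward(self, dy):
        dx = np.zeros(self._in_shape)
        share = dy / self.k
        for ki in range(self.k):
            dx[:, ki: ki + self.s * self._l_out: self.s, :] += share
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _fan_in_uniform(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.layers
                   if isinstance(layer, Conv1D))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_and_grads()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (p, _), saved in zip(self.params_and_grads(), state):
            p[...] = saved


class Adam:
    def __init__(self, net: Sequential, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params_and_grads()]
        self.v = [np.zeros_like(p) for p, _ in net.params_and_grads()]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.net.params_and_grads()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
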