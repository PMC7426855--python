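"""A small, vectorised 1-D convolutional network engine on numpy.

Implements exactly the layer set the gait model needs — 1-D convolution with
same-padding, ReLU, batch normalization, max pooling, inverted dropout, a
dense head — with explicit backward passes and an RMSProp optimizer.  All
arithmetic is float32 and every forward/backward reduces to BLAS matmuls via
im2col, so a 47K-parameter network trains in seconds per epoch on one CPU.

Conventions: activations have shape (batch, time, channels); convolution
same-padding follows the keras rule for even kernels (pad left = (F-1)//2,
pad right = F//2); batch-norm statistics are taken over the batch and time
axes jointly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base layer: ``params`` yields (array, grad, l2_weight) triples."""

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


class Conv1D(Layer):
    """1-D convolution, ``filters`` output channels, kernel ``length``, same-padding.

    Each filter spans the full input depth D, so it carries length·D + 1
    weights including its bias.
    """

    def __init__(self, in_channels: int, filters: int, length: int,
                 l2: float = 0.0, rng: np.random.Generator | None = None):
        self.D = in_channels
        self.O = filters
        self.F = length
        self.l2 = float(l2)
        rng = rng or np.random.default_rng(0)
        fan_in = self.F * self.D
        self.W = (rng.standard_normal((fan_in, self.O)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(self.O, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pad = ((self.F - 1) // 2, self.F // 2)

    def _im2col(self, x: np.ndarray, pad: tuple[int, int], F: int) -> np.ndarray:
        N, T, D = x.shape
        xp = np.pad(x, ((0, 0), pad, (0, 0)))
        cols = sliding_window_view(xp, F, axis=1)      # (N, T, D, F)
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(N * T, F * D)

    def forward(self, x, training, rng):
        self._shape = x.shape
        self._cols = self._im2col(x.astype(DTYPE, copy=False), self._pad, self.F)
        N, T, _ = x.shape
        y = self._cols @ self.W + self.b
        return y.reshape(N, T, self.O)

    def backward(self, grad):
        N, T, D = self._shape
        g = grad.reshape(N * T, self.O).astype(DTYPE, copy=False)
        self.dW = self._cols.T @ g
        if self.l2:
            self.dW += (2.0 * self.l2) * self.W
        self.db = g.sum(axis=0)
        # dx = full correlation of grad with the flipped kernel
        padl, padr = self._pad
        gcols = self._im2col(grad.astype(DTYPE, copy=False),
                             (self.F - 1 - padl, padl), self.F)
        Wback = np.ascontiguousarray(
            self.W.reshape(self.F, self.D, self.O)[::-1].transpose(0, 2, 1)
        ).reshape(self.F * self.O, self.D)
        dx = gcols @ Wback
        return dx.reshape(N, T, D)

    def params(self):
        return [(self.W, lambda: self.dW, self.l2), (self.b, lambda: self.db, 0.0)]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = (x - mu) * self._inv_std
        self._m = x.shape[0] * x.shape[1]
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat = self._xhat
        self.dgamma = np.sum(grad * xhat, axis=(0, 1))
        self.dbeta = np.sum(grad, axis=(0, 1))
        dxhat = grad * self.gamma
        m = self._m
        return (self._inv_std / m) * (
            m * dxhat
            - np.sum(dxhat, axis=(0, 1))
            - xhat * np.sum(dxhat * xhat, axis=(0, 1))
        )

    def params(self):
        return [(self.gamma, lambda: self.dgamma, 0.0),
                (self.beta, lambda: self.dbeta, 0.0)]

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; a trailing remainder is dropped."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x, training, rng):
        N, T, D = x.shape
        T2 = T // self.r
        self._shape = x.shape
        xr = x[:, :T2 * self.r].reshape(N, T2, self.r, D)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        N, T, D = self._shape
        T2 = grad.shape[1]
        out = np.zeros((N, T2, self.r, D), dtype=DTYPE)
        np.put_along_axis(out, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        full = np.zeros(self._shape, dtype=DTYPE)
        full[:, :T2 * self.r] = out.reshape(N, T2 * self.r, D)
        return full


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(DTYPE)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(DTYPE)


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, l2: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.l2 = float(l2)

    def forward(self, x, training, rng):
        self._x = x.astype(DTYPE, copy=False)
        return self._x @ self.W + self.b

    def backward(self, grad):
        g = grad.astype(DTYPE, copy=False)
        self.dW = self._x.T @ g
        if self.l2:
            self.dW += (2.0 * self.l2) * self.W
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, lambda: self.dW, self.l2), (self.b, lambda: self.db, 0.0)]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class Network:
    """A plain sequential network with explicit train/eval modes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        out = x.astype(DTYPE, copy=False)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        """Total trainable parameter count (conv/dense weights+biases, BN gamma/beta)."""
        return sum(p.size for p, _, _ in self.params())

    def l2_loss(self) -> float:
        return float(sum(l2 * np.sum(p.astype(np.float64) ** 2)
                         for p, _, l2 in self.params() if l2))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _, _), w in zip(self.params(), weights):
            p[...] = w


class RMSProp:
    """Root-mean-square propagation with the keras defaults (rho 0.9, eps 1e-7)."""

    def __init__(self, rho: float = 0.9, eps: float = 1e-7):
        self.rho = rho
        self.eps = eps
        self._v: list[np.ndarray] | None = None

    def step(self, network: Network, lr: float) -> None:
        params = network.params()
        if self._v is None:
            self._v = [np.zeros_like(p) for p, _, _ in params]
        for v, (p, grad_fn, _) in zip(self._v, params):
            g = grad_fn()
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= (lr * g / (np.sqrt(v) + self.eps)).astype(p.dtype)
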