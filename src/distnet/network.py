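"""Minimal convolutional-network engine (numpy, manual backprop).

Implements exactly the layers the distance-prediction architecture needs —
same-padded 2D convolution (im2col), batch normalisation, ReLU, spatial
dropout-free elementwise dropout, residual blocks — plus an Adam optimiser.
Tensors are NCHW.  The network is fully convolutional, so one set of
weights serves any sequence length.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "BatchNorm2D", "ReLU", "Dropout", "ResidualBlock",
           "Sequential", "Adam"]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list:
        """List of [param, grad] pairs (arrays updated in place)."""
        return []

    def num_params(self) -> int:
        return sum(p.size for p, _ in self.parameters())


class Conv2D(Layer):
    """Same-padded k x k convolution with bias, He-initialised."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.cin, self.cout, self.k = cin, cout, kernel
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = rng.normal(0.0, std, size=(cin * kernel * kernel, cout))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, -1)
        y = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._shape = (N, C, H, W)
        return y.reshape(N, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        p = self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(N * H * W, self.cout)
        self.dW += self._cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(N, H, W, C, self.k, self.k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di:di + H, dj:dj + W] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + H, p:p + W]

    def parameters(self) -> list:
        return [[self.W, self.dW], [self.b, self.db]]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma[None, :, None, None] * xhat \
            + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        self._cache = None
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def parameters(self) -> list:
        return [[self.gamma, self.dgamma], [self.beta, self.dbeta]]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class ResidualBlock(Layer):
    """BN -> ReLU -> 3x3 conv -> dropout -> ReLU -> 3x3 conv, with identity skip."""

    def __init__(self, channels: int, kernel: int, dropout_rate: float,
                 rng: np.random.Generator):
        self.layers = [
            BatchNorm2D(channels),
            ReLU(),
            Conv2D(channels, channels, kernel, rng),
            Dropout(dropout_rate, rng),
            ReLU(),
            Conv2D(channels, channels, kernel, rng),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return x + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return dy + g

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.parameters()]


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam with bias correction, updating parameters in place."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
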