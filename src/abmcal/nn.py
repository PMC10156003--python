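"""Minimal NumPy neural-network layers with manual backprop.

Just enough machinery for a small convolutional projection network:
stride-2 3x3 convolutions (im2col), ReLU, dense layers, and Adam.
Gradient correctness is pinned down by numerical finite-difference
checks in the test suite.  Arrays are NHWC.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, zero padding, arbitrary stride, He init."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = Param(rng.normal(0.0, std, (k * k * cin, cout)))
        # small positive bias avoids dead ReLUs and all-zero projections
        self.b = Param(np.full(cout, 0.01))
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        N, H, W, C = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((N, Ho, Wo, k, k, C))
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, di, dj, :] = xp[:, di:di + Ho * s:s, dj:dj + Wo * s:s, :]
        cols = cols.reshape(N, Ho, Wo, k * k * C)
        self._cols = cols
        self._xshape = x.shape
        self._padshape = xp.shape
        return cols @ self.W.value + self.b.value

    def backward(self, dout):
        N, H, W, C = self._xshape
        k, s, p = self.k, self.stride, self.pad
        Ho, Wo = dout.shape[1], dout.shape[2]
        K = k * k * C
        self.W.grad += self._cols.reshape(-1, K).T @ dout.reshape(-1, self.cout)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        dcols = (dout @ self.W.value.T).reshape(N, Ho, Wo, k, k, C)
        dxp = np.zeros(self._padshape)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + Ho * s:s, dj:dj + Wo * s:s, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, p:p + H, p:p + W, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / nin)
        self.W = Param(rng.normal(0.0, std, (nin, nout)))
        self.b = Param(np.full(nout, 0.01))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match network parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
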