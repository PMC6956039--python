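"""Feed-forward layers (valid 2-D convolution, batch-norm, pooling, dense).

Tensor layout for the convolutional stack is ``(N, F, C, T)``: batch,
feature maps, channel extent, time extent.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class: stateless API, caches kept on the instance."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def conv_valid(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Valid (unpadded) cross-correlation over the (channel, time) axes.

    x: (N, Fin, C, T); w: (Fout, Fin, kc, kt); output (N, Fout, C-kc+1, T-kt+1).
    Implemented as a sum of batched matmuls over the (small) kernel offsets,
    which is much faster than an im2col einsum for 1x5 / 5x1 kernels.
    """
    kc, kt = w.shape[2], w.shape[3]
    if kc > x.shape[2] or kt > x.shape[3]:
        raise ValueError(
            f"filter ({kc}, {kt}) larger than input extents ({x.shape[2]}, {x.shape[3]})"
        )
    n, fin, c, t = x.shape
    fout = w.shape[0]
    co, to = c - kc + 1, t - kt + 1
    acc = np.zeros((n, fout, co * to))
    for h in range(kc):
        for v in range(kt):
            xs = np.ascontiguousarray(x[:, :, h : h + co, v : v + to]).reshape(n, fin, -1)
            acc += np.matmul(w[:, :, h, v], xs)
    y = acc.reshape(n, fout, co, to)
    if b is not None:
        y += b[None, :, None, None]
    return y


class Conv2dValid(Layer):
    def __init__(self, fin: int, fout: int, kc: int, kt: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / (fin * kc * kt))
        self.w = Param("conv.w", rng.uniform(-bound, bound, size=(fout, fin, kc, kt)))
        self.b = Param("conv.b", np.zeros(fout))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return conv_valid(x, self.w.value, self.b.value)

    def backward(self, dy):
        x, w = self._x, self.w.value
        fout, fin, kc, kt = w.shape
        n, _, c, t = x.shape
        co, to = c - kc + 1, t - kt + 1
        dy_c = np.ascontiguousarray(dy).reshape(n, fout, -1)
        dx = np.zeros_like(x)
        for h in range(kc):
            for v in range(kt):
                xs = np.ascontiguousarray(x[:, :, h : h + co, v : v + to]).reshape(n, fin, -1)
                self.w.grad[:, :, h, v] += np.matmul(dy_c, xs.transpose(0, 2, 1)).sum(axis=0)
                dxs = np.matmul(w[:, :, h, v].T, dy_c).reshape(n, fin, co, to)
                dx[:, :, h : h + co, v : v + to] += dxs
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    """Per-feature-map normalization over batch, channel, and time axes."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param("bn.gamma", np.ones(num_features))
        self.beta = Param("bn.beta", np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, rng=None):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not training:
            return dy * g * inv_std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=axes)[None, :, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        return inv_std[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x, training=False, rng=None):
        neg = self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        y = np.where(x > 0, x, neg)
        self._cache = (x, y)
        return y

    def backward(self, dy):
        x, y = self._cache
        return dy * np.where(x > 0, 1.0, y + self.alpha)


class MaxPoolChan(Layer):
    """Max pooling along the channel axis, window == stride == ``size``."""

    def __init__(self, size: int):
        self.size = size
        self._cache = None

    def forward(self, x, training=False, rng=None):
        s = self.size
        n, f, c, t = x.shape
        if c % s != 0:
            raise ValueError(f"channel extent {c} not divisible by pool size {s}")
        xr = x.reshape(n, f, c // s, s, t)
        arg = xr.argmax(axis=3)
        y = np.take_along_axis(xr, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (x.shape, arg)
        return y

    def backward(self, dy):
        (n, f, c, t), arg = self._cache
        s = self.size
        dxr = np.zeros((n, f, c // s, s, t))
        np.put_along_axis(dxr, arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        return dxr.reshape(n, f, c, t)


class AvgPoolChan(Layer):
    """Average pooling along the channel axis, window == stride == ``size``."""

    def __init__(self, size: int):
        self.size = size
        self._shape = None

    def forward(self, x, training=False, rng=None):
        s = self.size
        n, f, c, t = x.shape
        if c % s != 0:
            raise ValueError(f"channel extent {c} not divisible by pool size {s}")
        self._shape = x.shape
        return x.reshape(n, f, c // s, s, t).mean(axis=3)

    def backward(self, dy):
        n, f, c, t = self._shape
        s = self.size
        return np.repeat(dy[:, :, :, None, :] / s, s, axis=3).reshape(n, f, c, t)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / din)
        self.w = Param("dense.w", rng.uniform(-bound, bound, size=(dout, din)))
        self.b = Param("dense.b", np.zeros(dout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value
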