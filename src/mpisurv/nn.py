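"""A compact numpy neural-network engine for the risk-score models.

Layers implement explicit ``forward``/``backward`` passes with cached
activations; convolutions use im2col/col2im so the heavy lifting is BLAS
matrix multiplication.  Everything is float64, fully deterministic given the
initialization generator, and sized for the desk-scale profiles this package
trains (tens of channels, 32 px slices).

The engine exposes: Conv2d, Linear, ReLU, GlobalAvgPool, residual blocks,
sequential composition, and Adam.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. normalization running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, oh*ow) patch matrix."""
    n, c, hp, wp = xp.shape
    sN, sC, sH, sW = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, oh, ow),
        strides=(sN, sC, sH, sW, sH * stride, sW * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, oh * ow)


class Conv2d(Layer):
    """k x k convolution with 'same' padding and He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, pad: int | None = None):
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k, s, oh, ow)           # (n, c*k*k, oh*ow)
        Wm = self.W.value.reshape(self.W.value.shape[0], -1)
        out = np.einsum("fc,ncl->nfl", Wm, cols, optimize=True)
        out = out.reshape(n, -1, oh, ow) + self.b.value[None, :, None, None]
        if train:
            self._cache = (cols, (n, c, h, w), (oh, ow))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        f = dout.shape[1]
        dflat = dout.reshape(n, f, oh * ow)
        Wm = self.W.value.reshape(f, -1)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum("nfl,ncl->fc", dflat, cols,
                                 optimize=True).reshape(self.W.value.shape)
        dcols = np.einsum("fc,nfl->ncl", Wm, dflat, optimize=True)
        dcols = dcols.reshape(n, c, k, k, oh, ow)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    Uses batch statistics in training mode and exponential running averages
    in inference mode, as in standard residual networks.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv, x.shape)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ((x - self.running_mean[None, :, None, None])
                    * inv[None, :, None, None])
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        std = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, std, (d_in, d_out)))
        self.b = Param(np.zeros(d_out)) if bias else None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-BN-relu-conv-BN with an identity (or strided 1x1) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = (Conv2d(c_in, c_out, 1, stride, rng, pad=0)
                     if (stride != 1 or c_in != c_out) else None)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        ps = (self.conv1.params() + self.bn1.params()
              + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def buffers(self) -> list[np.ndarray]:
        return self.bn1.buffers() + self.bn2.buffers()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(
                self.conv1.forward(x, train), train), train), train), train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(main + short, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        dshort = d if self.proj is None else self.proj.backward(d)
        return dmain + dshort


class Adam:
    """Adaptive-moment-estimation optimizer (bias-corrected)."""

    def __init__(self, params: Sequence[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
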