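"""Minimal NumPy CNN engine (NCHW layout).

Provides exactly the layers the shallow U-Net autoencoder and the DenseNet
head need: 2-D convolution (im2col/tensordot), batch normalization, ReLU,
max/average pooling, nearest-neighbour upsampling, dense layers, softmax
and MSE losses, and an Adam optimizer.  Forward/backward passes are fully
deterministic; all parameter initialization flows from one seeded
generator.

This is deliberately small: desk-scale inputs (tens of channels, <=224
pixels) and batch training on a single CPU, not a general autodiff system.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "BatchNorm2D", "ReLU", "MaxPool2D", "GlobalAvgPool",
    "Upsample2D", "Dense", "Flatten", "Sequential", "Adam",
    "softmax", "softmax_cross_entropy", "mse_loss",
]


class Layer:
    """Base layer: ``params()`` yields [(array, grad-array), ...]."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad="same", rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad == "same" else int(pad)
        fan_in = c_in * kernel * kernel
        self.W = _he_init(rng, (c_out, c_in, kernel, kernel), fan_in)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def out_size(self, n):
        return (n + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp_shape = xp.shape
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._cols = cols  # (n, c, ho, wo, k, k)
        y = np.tensordot(cols, self.W, axes=([1, 4, 5], [1, 2, 3]))
        y = y.transpose(0, 3, 1, 2) + self.b[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, grad):
        n, co, ho, wo = grad.shape
        k, s, p = self.k, self.stride, self.pad
        self.db[...] = grad.sum(axis=(0, 2, 3))
        # dW[o,c,i,j] = sum_{n,y,x} cols[n,c,y,x,i,j] * grad[n,o,y,x]
        self.dW[...] = np.tensordot(grad, self._cols,
                                    axes=([0, 2, 3], [0, 2, 3]))
        dxp = np.zeros(self._xp_shape)
        # scatter-add per kernel offset (k*k strided adds, vectorized)
        for i in range(k):
            for j in range(k):
                # contribution of grad to x_padded[:, :, i + s*y, j + s*x]
                contrib = np.tensordot(grad, self.W[:, :, i, j], axes=([1], [0]))
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    contrib.transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2D(Layer):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma[None, :, None, None] * self._xhat + \
            self.beta[None, :, None, None]

    def backward(self, grad):
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = grad * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3),
                                                       keepdims=True))
        return dx / self._std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        self.k = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        self._x_shape = x.shape
        wins = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._wins_shape = wins.shape
        flat = wins.reshape(*wins.shape[:4], k * k)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, ho, wo = grad.shape
        k, s, p = self.k, self.stride, self.pad
        dx = np.zeros(self._x_shape)
        iy, ix = np.divmod(self._arg, k)
        ny, cy, yy, xx = np.indices(grad.shape)
        np.add.at(dx, (ny, cy, yy * s + iy, xx * s + ix), grad)
        if p:
            return dx[:, :, p:-p, p:-p]
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).copy()


class Upsample2D(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor=2):
        self.f = factor

    def forward(self, x, train=True):
        f = self.f
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, grad):
        f = self.f
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a flat [(param, grad), ...] list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def mse_loss(pred, target):
    """Mean squared error; returns (loss, dpred)."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size
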