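"""Minimal CPU neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays in NCHW layout (dense layers on NC).
Each layer caches what its backward pass needs during ``forward``; calling
``backward`` returns the gradient with respect to the layer input, which is
what lets the attribution code read gradients at any depth of a network.

This is a deliberately small engine: convolution is im2col + BLAS matmul,
pooling is the non-overlapping reshape trick, and there is no graph
autodiff — networks compose layers explicitly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: a layer owns parameters, their gradients, and a cache."""

    def params(self):  # list of (array, grad) pairs, same order every call
        return []

    def state(self):
        """Arrays to persist in a checkpoint (trainables + buffers)."""
        return [p for p, _ in self.params()]

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Layer):
    """3x3-style convolution with 'same' zero padding and integer stride."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        self.k, self.stride = int(kernel), int(stride)
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (out_ch, in_ch * self.k * self.k), in_ch * self.k * self.k)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x):
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (N, C, Ho', Wo', k, k) then stride subsampling
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (ho, wo, xp.shape)

    def forward(self, x, train: bool):
        x = np.ascontiguousarray(x, dtype=F32)
        cols, (ho, wo, padded_shape) = self._im2col(x)
        out = cols @ self.W.T + self.b
        n = x.shape[0]
        self._cache = (cols, x.shape, padded_shape, ho, wo)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, padded_shape, ho, wo = self._cache
        n, _, h, w = x_shape
        k, s = self.k, self.stride
        p = k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.dW[...] = dflat.T @ cols
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W).reshape(n, ho, wo, self.in_ch, k, k)
        dxp = np.zeros(padded_shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(ch, dtype=F32)
        self.beta = np.zeros(ch, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train: bool):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(F32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        axes = (0, 2, 3)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0).astype(F32)


class MaxPool2d(Layer):
    """Non-overlapping max pooling; input sides must divide by the pool size."""

    def __init__(self, size=2):
        self.size = int(size)

    def forward(self, x, train: bool):
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"pool size {s} does not divide input {h}x{w}")
        xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // s, w // s, s * s)
        idx = np.argmax(xr, axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        s = self.size
        dxr = np.zeros((n, c, h // s, w // s, s * s), dtype=F32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalMaxPool(Layer):
    """Spatial global max pooling: (N, C, H, W) -> (N, C)."""

    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = np.argmax(flat, axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h * w), dtype=F32)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h, w)


class Dense(Layer):
    def __init__(self, in_units, out_units, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (in_units, out_units), in_units)
        self.b = np.zeros(out_units, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference so prediction is deterministic."""

    def __init__(self, rate, rng=None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling (decoder path of the U-Net)."""

    def forward(self, x, train: bool):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy and the gradient w.r.t. logits.

    labels: int array of class indices, shape (N,).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(F32)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on per-pixel logits; returns loss, dlogits."""
    p = sigmoid(logits)
    eps = 1e-7
    loss = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)).mean()
    grad = ((p - targets) / targets.size).astype(F32)
    return float(loss), grad


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= corr * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
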