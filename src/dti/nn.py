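"""Minimal seeded neural-network primitives (numpy, manual backprop).

Implements exactly the layers the two model families need: dense,
1-D convolution (im2col), batch normalization, inverted dropout, ReLU
and flatten, plus an Adam optimizer.  Everything is float32 and fully
deterministic for a fixed construction/dropout random stream, which is
what the end-to-end reproducibility contracts rely on.

Array layout: convolutional tensors are (batch, length, channels);
dense activations are (batch, features).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1D", "BatchNorm", "Dropout", "ReLU", "Flatten", "L2Normalize",
    "Sequential", "Adam", "sigmoid", "bce_with_logits",
]

F32 = np.float32


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy from logits; returns (loss, dL/dz)."""
    z = z.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.shape[0]
    return loss, grad.astype(F32)


class Layer:
    def params(self):
        return []

    def grads(self):
        return []

    def state(self):
        """Arrays to persist beyond trainable params (e.g. BN running stats)."""
        return []

    def forward(self, x, train):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, fan_in, fan_out, rng, w_std=None, bias_init=0.0):
        std = np.sqrt(2.0 / fan_in) if w_std is None else w_std
        self.W = rng.normal(0.0, std, (fan_in, fan_out)).astype(F32)
        self.b = np.full(fan_out, bias_init, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Conv1D(Layer):
    """Valid-padding 1-D convolution with stride, via im2col."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        std = np.sqrt(2.0 / (kernel * in_ch))
        self.W = rng.normal(0.0, std, (kernel * in_ch, out_ch)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch

    @staticmethod
    def out_length(length, kernel, stride):
        return (length - kernel) // stride + 1

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        B, L, C = x.shape
        k, s = self.kernel, self.stride
        out_len = self.out_length(L, k, s)
        # windows: (B, out_len, k, C) -> columns (B*out_len, k*C)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)[:, ::s]
        # win is (B, out_len, C, k); put kernel before channel to match W
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            B * out_len, k * C)
        self._col, self._in_shape = col, (B, L, C)
        y = col @ self.W + self.b
        return y.reshape(B, out_len, self.out_ch)

    def backward(self, g):
        B, L, C = self._in_shape
        k, s = self.kernel, self.stride
        out_len = g.shape[1]
        gf = g.reshape(B * out_len, self.out_ch)
        self.gW[...] = self._col.T @ gf
        self.gb[...] = gf.sum(axis=0)
        gcol = (gf @ self.W.T).reshape(B, out_len, k, C)
        gx = np.zeros((B, L, C), dtype=g.dtype)
        for t in range(k):
            gx[:, t:t + s * out_len:s, :] += gcol[:, :, t, :]
        return gx


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, position)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._axes = axes
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        axes = self._axes
        N = np.prod([g.shape[a] for a in axes])
        self.ggamma[...] = (g * self._xhat).sum(axis=axes)
        self.gbeta[...] = g.sum(axis=axes)
        gx = (self.gamma * self._inv_std / N) * (
            N * g - g.sum(axis=axes) - self._xhat * (g * self._xhat).sum(axis=axes)
        )
        return gx.astype(g.dtype)


class Dropout(Layer):
    """Inverted dropout driven by a shared seeded generator."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class L2Normalize(Layer):
    """Project rows onto the unit sphere (standard triplet-embedding head)."""

    def __init__(self, eps=1e-12):
        self.eps = eps

    def forward(self, x, train):
        self._norm = np.linalg.norm(x, axis=1, keepdims=True) + self.eps
        self._u = x / self._norm
        return self._u

    def backward(self, g):
        return (g - self._u * np.sum(g * self._u, axis=1, keepdims=True)) / self._norm


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state_arrays(self):
        arrays = []
        for layer in self.layers:
            arrays.extend(layer.params())
            arrays.extend(layer.state())
        return arrays

    def get_state(self):
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state):
        for dst, src in zip(self.state_arrays(), state, strict=True):
            dst[...] = src


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p[...] = p - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
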