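"""Minimal feed-forward network engine (numpy, manual backprop).

Implements exactly the layers the compact EEG backbones need: temporal
convolution shared across channels, spatial (cross-channel) convolution,
depthwise and pointwise 1-D convolutions, batch normalization, ELU /
squaring / safe-log nonlinearities, average and max pooling, dropout, a
dense layer and softmax cross-entropy, plus the Adam optimizer.

All convolutions are "valid" (no padding).  Shapes follow two layouts:

* 4-D ``(batch, filters, channels, time)`` right after the temporal
  convolution, while the EEG channel axis still exists;
* 3-D ``(batch, features, time)`` once a spatial layer has collapsed the
  channel axis.

Everything is deterministic given the ``numpy.random.Generator`` passed
in: initialization, dropout masks and batch order derive from it alone,
so runs are bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "TemporalConv",
    "SpatialConv",
    "DepthwiseSpatialConv",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm",
    "Square",
    "SafeLog",
    "ELU",
    "AvgPool1d",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: forward caches what backward needs; params() exposes
    (value, grad) pairs for the optimizer."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class TemporalConv(Layer):
    """Temporal convolution applied identically to every EEG channel.

    Input (B, C, T) -> output (B, F, C, T-K+1).  Weight (F, K), bias (F,).
    """

    def __init__(self, n_filters: int, kernel_len: int, rng: np.random.Generator):
        self.F, self.K = n_filters, kernel_len
        self.W = glorot_uniform(rng, (self.F, self.K), self.K, self.F)
        self.b = np.zeros(self.F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[-1] < self.K:
            raise ValueError(f"kernel {self.K} longer than time axis {x.shape[-1]}")
        self._win = sliding_window_view(x, self.K, axis=-1)  # (B, C, T', K)
        out = np.tensordot(self._win, self.W, axes=([3], [1]))  # (B, C, T', F)
        out = out.transpose(0, 3, 1, 2)
        return out + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, F, C, Tp = g.shape
        win = self._win  # (B, C, T', K)
        gT = g.transpose(1, 0, 2, 3).reshape(F, -1)  # (F, B*C*T')
        self.dW[...] = gT @ win.reshape(-1, self.K)
        self.db[...] = g.sum(axis=(0, 2, 3))
        # dx[b,c,s+k] += sum_f g[b,f,c,s] W[f,k]: accumulate per kernel tap
        # to avoid materializing the (B,F,C,T,K) correlation tensor
        gW = np.tensordot(g, self.W, axes=([1], [0]))  # (B, C, T', K)
        T = Tp + self.K - 1
        dx = np.zeros((B, C, T), dtype=g.dtype)
        for k in range(self.K):
            dx[:, :, k : k + Tp] += gW[..., k]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class SpatialConv(Layer):
    """Spatial filtering spanning all channels (and temporal filters).

    Input (B, F, C, T) -> output (B, S, T).  Weight (S, F, C), bias (S,).
    """

    def __init__(self, n_out: int, n_filters_in: int, n_channels: int, rng: np.random.Generator):
        self.S, self.F, self.C = n_out, n_filters_in, n_channels
        fan_in = self.F * self.C
        self.W = glorot_uniform(rng, (self.S, self.F, self.C), fan_in, self.S)
        self.b = np.zeros(self.S)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, F, C, T = x.shape
        self._xr = x.reshape(B, F * C, T)
        Wr = self.W.reshape(self.S, F * C)
        out = np.einsum("si,bit->bst", Wr, self._xr, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, S, T = g.shape
        FC = self._xr.shape[1]
        dWr = np.einsum("bst,bit->si", g, self._xr, optimize=True)
        self.dW[...] = dWr.reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 2))
        Wr = self.W.reshape(S, FC)
        dxr = np.einsum("bst,si->bit", g, Wr, optimize=True)
        return dxr.reshape(B, self.F, self.C, T)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class DepthwiseSpatialConv(Layer):
    """Depthwise spatial convolution: D spatial filters per temporal map.

    Input (B, F, C, T) -> output (B, F*D, T).  Weight (F, D, C), no bias
    (a batch norm follows in the EEGNet-style block).
    """

    def __init__(self, n_filters_in: int, depth_multiplier: int, n_channels: int, rng):
        self.F, self.D, self.C = n_filters_in, depth_multiplier, n_channels
        self.W = glorot_uniform(rng, (self.F, self.D, self.C), self.C, self.D)
        self.dW = np.zeros_like(self.W)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        out = np.einsum("bfct,fdc->bfdt", x, self.W, optimize=True)
        B, F, D, T = out.shape
        return out.reshape(B, F * D, T)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, FD, T = g.shape
        gr = g.reshape(B, self.F, self.D, T)
        self.dW[...] = np.einsum("bfdt,bfct->fdc", gr, self._x, optimize=True)
        return np.einsum("bfdt,fdc->bfct", gr, self.W, optimize=True)

    def params(self):
        return [(self.W, self.dW)]


class Conv1d(Layer):
    """Standard 1-D convolution (B, Fin, T) -> (B, Fout, T-K+1)."""

    def __init__(self, n_out: int, n_in: int, kernel_len: int, rng: np.random.Generator):
        self.Fo, self.Fi, self.K = n_out, n_in, kernel_len
        fan_in = n_in * kernel_len
        self.W = glorot_uniform(rng, (self.Fo, self.Fi, self.K), fan_in, self.Fo)
        self.b = np.zeros(self.Fo)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[-1] < self.K:
            raise ValueError(f"kernel {self.K} longer than time axis {x.shape[-1]}")
        self._win = sliding_window_view(x, self.K, axis=-1)  # (B, Fi, T', K)
        out = np.tensordot(self._win, self.W, axes=([1, 3], [1, 2]))  # (B, T', Fo)
        return out.transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW[...] = np.einsum("bot,bitk->oik", g, self._win, optimize=True)
        self.db[...] = g.sum(axis=(0, 2))
        B, Fo, Tp = g.shape
        gW = np.tensordot(g, self.W, axes=([1], [0]))  # (B, T', Fi, K)
        dx = np.zeros((B, self.Fi, Tp + self.K - 1), dtype=g.dtype)
        gW = gW.transpose(0, 2, 1, 3)  # (B, Fi, T', K)
        for k in range(self.K):
            dx[:, :, k : k + Tp] += gW[..., k]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class DepthwiseConv1d(Layer):
    """Per-feature-map temporal convolution (B, M, T) -> (B, M, T-K+1)."""

    def __init__(self, n_maps: int, kernel_len: int, rng: np.random.Generator):
        self.M, self.K = n_maps, kernel_len
        self.W = glorot_uniform(rng, (self.M, self.K), self.K, 1)
        self.dW = np.zeros_like(self.W)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[-1] < self.K:
            raise ValueError(f"kernel {self.K} longer than time axis {x.shape[-1]}")
        self._win = sliding_window_view(x, self.K, axis=-1)  # (B, M, T', K)
        return np.einsum("bmtk,mk->bmt", self._win, self.W, optimize=True)

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW[...] = np.einsum("bmt,bmtk->mk", g, self._win, optimize=True)
        B, M, Tp = g.shape
        dx = np.zeros((B, M, Tp + self.K - 1), dtype=g.dtype)
        for k in range(self.K):
            dx[:, :, k : k + Tp] += g * self.W[None, :, k : k + 1]
        return dx

    def params(self):
        return [(self.W, self.dW)]


class BatchNorm(Layer):
    """Batch normalization over every axis except the feature axis (1)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _bshape(self, ndim: int) -> tuple:
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) * self._inv.reshape(sh)
        self._axes = axes
        self._n = x.size // x.shape[1]
        self._training = training
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, g: np.ndarray) -> np.ndarray:
        sh = self._bshape(g.ndim)
        self.dgamma[...] = (g * self._xhat).sum(axis=self._axes)
        self.dbeta[...] = g.sum(axis=self._axes)
        gi = g * self.gamma.reshape(sh)
        if not self._training:
            return gi * self._inv.reshape(sh)
        n = self._n
        s1 = gi.sum(axis=self._axes).reshape(sh)
        s2 = (gi * self._xhat).sum(axis=self._axes).reshape(sh)
        return self._inv.reshape(sh) * (gi - s1 / n - self._xhat * s2 / n)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Square(Layer):
    def forward(self, x, training):
        self._x = x
        return x * x

    def backward(self, g):
        return 2.0 * self._x * g


class SafeLog(Layer):
    """log(max(x, eps)); pairs with squaring + average pooling to realize
    the log-bandpower feature of the shallow backbone."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, training):
        self._xc = np.maximum(x, self.eps)
        return np.log(self._xc)

    def backward(self, g):
        return g / self._xc


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self.alpha * self._expm1, x)

    def backward(self, g):
        return np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0) * g


class AvgPool1d(Layer):
    """Average pooling along the last axis with given length and stride."""

    def __init__(self, pool_len: int, stride: int):
        self.L, self.s = pool_len, stride

    def forward(self, x, training):
        T = x.shape[-1]
        if T < self.L:
            raise ValueError(f"pool length {self.L} longer than time axis {T}")
        self._T = T
        win = sliding_window_view(x, self.L, axis=-1)[..., :: self.s, :]
        return win.mean(axis=-1)

    def backward(self, g):
        dx = np.zeros(g.shape[:-1] + (self._T,), dtype=g.dtype)
        P = g.shape[-1]
        for p in range(P):
            dx[..., p * self.s : p * self.s + self.L] += g[..., p : p + 1] / self.L
        return dx


class MaxPool1d(Layer):
    def __init__(self, pool_len: int, stride: int):
        self.L, self.s = pool_len, stride

    def forward(self, x, training):
        T = x.shape[-1]
        if T < self.L:
            raise ValueError(f"pool length {self.L} longer than time axis {T}")
        self._T = T
        win = sliding_window_view(x, self.L, axis=-1)[..., :: self.s, :]
        self._arg = win.argmax(axis=-1)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        dx = np.zeros(g.shape[:-1] + (self._T,), dtype=g.dtype)
        P = g.shape[-1]
        lead = int(np.prod(g.shape[:-1]))
        dxf = dx.reshape(lead, self._T)
        gf = g.reshape(lead, P)
        argf = self._arg.reshape(lead, P)
        rows = np.repeat(np.arange(lead), P)
        cols = (argf + self.s * np.arange(P)[None, :]).ravel()
        np.add.at(dxf, (rows, cols), gf.ravel())
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.rate).astype(x.dtype)
        self._mask = keep / x.dtype.type(1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + batch-norm running stats),
        for checkpointing."""
        out = [p for p, _ in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.extend([layer.running_mean, layer.running_var])
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(B), labels] + eps).mean()
    g = p.copy()
    g[np.arange(B), labels] -= 1.0
    return float(loss), g / B


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
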