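"""Minimal CPU neural-network engine used by the residual classifier.

Implements exactly the operations the classifier needs — 2D convolution,
batch normalization, leaky ReLU, global average pooling, a linear head,
weighted softmax cross-entropy and Adam — each with a hand-written backward
pass.  Tensors are laid out NHWC (channels last) so the convolution inner
loops stream over contiguous memory; the convolution runs through small
numba-compiled kernels when numba is importable and falls back to an
im2col/BLAS path otherwise.  Everything is float32 by default and fully
deterministic for a seeded ``numpy.random.Generator``.

The public entry point is :class:`Model` (a layer stack with forward /
backward / parameter access / state (de)serialization); the residual
architecture itself is assembled in :mod:`singlehit.cnn`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "GlobalAvgPool",
    "Linear",
    "PreActResBlock",
    "Model",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # non-parameter persistent state (e.g. BN running stats)
    def extra_state(self) -> list[np.ndarray]:
        return []

    def set_extra_state(self, arrays: list[np.ndarray]) -> None:
        pass


# ---------------------------------------------------------------------------
# Convolution kernels (NHWC)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @_njit(fastmath=True)
    def _conv_fwd(xp, wt, sh, sw, ho, wo):
        # xp (n, hp, wp, c), wt (k, k, c, f) -> (n, ho, wo, f); SIMD over f
        n, hp, wp, c = xp.shape
        k, f = wt.shape[0], wt.shape[3]
        out = np.zeros((n, ho, wo, f), dtype=xp.dtype)
        for b in range(n):
            for i in range(ho):
                for j in range(wo):
                    orow = out[b, i, j]
                    for ki in range(k):
                        for kj in range(k):
                            xrow = xp[b, i * sh + ki, j * sw + kj]
                            for ci in range(c):
                                xv = xrow[ci]
                                wrow = wt[ki, kj, ci]
                                for o in range(f):
                                    orow[o] += xv * wrow[o]
        return out

    @_njit(fastmath=True)
    def _conv_bwd(xp, wt, dy, sh, sw):
        n, hp, wp, c = xp.shape
        k, f = wt.shape[0], wt.shape[3]
        ho, wo = dy.shape[1], dy.shape[2]
        dw = np.zeros_like(wt)
        dxp = np.zeros_like(xp)
        for b in range(n):
            for i in range(ho):
                for j in range(wo):
                    drow = dy[b, i, j]
                    for ki in range(k):
                        for kj in range(k):
                            xrow = xp[b, i * sh + ki, j * sw + kj]
                            dxrow = dxp[b, i * sh + ki, j * sw + kj]
                            for ci in range(c):
                                xv = xrow[ci]
                                wrow = wt[ki, kj, ci]
                                dwrow = dw[ki, kj, ci]
                                acc = np.float32(0.0)
                                for o in range(f):
                                    g = drow[o]
                                    dwrow[o] += g * xv
                                    acc += g * wrow[o]
                                dxrow[ci] += acc
        return dw, dxp


if _HAVE_NUMBA:

    @_njit(fastmath=True)
    def _bn_stats(x2d):
        m, c = x2d.shape
        s = np.zeros(c, dtype=np.float64)
        s2 = np.zeros(c, dtype=np.float64)
        for i in range(m):
            row = x2d[i]
            for j in range(c):
                v = row[j]
                s[j] += v
                s2[j] += v * v
        mean = s / m
        var = s2 / m - mean * mean
        return mean, np.maximum(var, 0.0)

    @_njit(fastmath=True)
    def _bn_apply(x2d, mean, inv_std, gamma, beta):
        m, c = x2d.shape
        xhat = np.empty_like(x2d)
        y = np.empty_like(x2d)
        for i in range(m):
            for j in range(c):
                h = (x2d[i, j] - mean[j]) * inv_std[j]
                xhat[i, j] = h
                y[i, j] = gamma[j] * h + beta[j]
        return xhat, y

    @_njit(fastmath=True)
    def _bn_bwd(dy2d, xhat2d, inv_std, gamma, train):
        m, c = dy2d.shape
        dgamma = np.zeros(c, dtype=dy2d.dtype)
        dbeta = np.zeros(c, dtype=dy2d.dtype)
        for i in range(m):
            for j in range(c):
                dgamma[j] += dy2d[i, j] * xhat2d[i, j]
                dbeta[j] += dy2d[i, j]
        dx = np.empty_like(dy2d)
        if train:
            for i in range(m):
                for j in range(c):
                    dyg = dy2d[i, j] * gamma[j]
                    dx[i, j] = inv_std[j] * (
                        dyg - gamma[j] * dbeta[j] / m
                        - xhat2d[i, j] * gamma[j] * dgamma[j] / m)
        else:
            for i in range(m):
                for j in range(c):
                    dx[i, j] = dy2d[i, j] * gamma[j] * inv_std[j]
        return dgamma, dbeta, dx

    @_njit(fastmath=True)
    def _lrelu_fwd(x1d, slope):
        y = np.empty_like(x1d)
        for i in range(x1d.size):
            v = x1d[i]
            y[i] = v if v > 0 else slope * v
        return y

    @_njit(fastmath=True)
    def _lrelu_bwd(x1d, dy1d, slope):
        dx = np.empty_like(dy1d)
        for i in range(dy1d.size):
            dx[i] = dy1d[i] if x1d[i] > 0 else slope * dy1d[i]
        return dx


def _im2col_nhwc(xp, k, sh, sw, ho, wo):
    n, hp, wp, c = xp.shape
    cols = np.empty((n, ho, wo, k * k * c), dtype=xp.dtype)
    pos = 0
    for ki in range(k):
        for kj in range(k):
            cols[..., pos : pos + c] = xp[:, ki : ki + ho * sh : sh,
                                          kj : kj + wo * sw : sw, :]
            pos += c
    return cols


class Conv2d(Layer):
    """2D convolution (NHWC), He-initialized; bias off when BN follows.

    Weight layout is ``(c_out, k, k, c_in)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride=(1, 1),
                 pad: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 use_numba: bool | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = tuple(int(s) for s in stride)
        self.pad = (kernel // 2) if pad is None else pad
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = Param(rng.normal(0.0, std, (c_out, kernel, kernel, c_in)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype)) if bias else None
        if use_numba is None:
            use_numba = _HAVE_NUMBA and dtype == np.float32
        self.use_numba = use_numba and _HAVE_NUMBA
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        n, h, w_in, c = x.shape
        k, (sh, sw), p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // sh + 1
        wo = (w_in + 2 * p - k) // sw + 1
        if self.use_numba:
            wt = np.ascontiguousarray(self.w.value.transpose(1, 2, 3, 0))
            y = _conv_fwd(xp, wt, sh, sw, ho, wo)
            cols = None
        else:
            cols = _im2col_nhwc(xp, k, sh, sw, ho, wo)
            f = self.w.value.shape[0]
            wmat = self.w.value.reshape(f, -1)  # (f, k*k*c) matches col order
            y = (cols.reshape(-1, k * k * c) @ wmat.T).reshape(n, ho, wo, f)
        if self.b is not None:
            y += self.b.value
        self._cache = (x.shape, xp, cols, ho, wo)
        return y

    def backward(self, dy):
        x_shape, xp, cols, ho, wo = self._cache
        n, h, w_in, c = x_shape
        k, (sh, sw), p = self.kernel, self.stride, self.pad
        f = self.w.value.shape[0]
        if self.use_numba:
            wt = np.ascontiguousarray(self.w.value.transpose(1, 2, 3, 0))
            dw, dxp = _conv_bwd(xp, wt, np.ascontiguousarray(dy), sh, sw)
            self.w.grad += dw.transpose(3, 0, 1, 2)
        else:
            dyf = dy.reshape(-1, f)
            dw = dyf.T @ cols.reshape(-1, k * k * c)
            self.w.grad += dw.reshape(self.w.value.shape)
            dcols = (dyf @ self.w.value.reshape(f, -1)).reshape(n, ho, wo, k * k * c)
            dxp = np.zeros_like(xp)
            pos = 0
            for ki in range(k):
                for kj in range(k):
                    dxp[:, ki : ki + ho * sh : sh, kj : kj + wo * sw : sw, :] += \
                        dcols[..., pos : pos + c]
                    pos += c
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 1, 2))
        return dxp[:, p : p + h, p : p + w_in, :] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization over the (batch, row, col) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def extra_state(self):
        return [self.running_mean, self.running_var]

    def set_extra_state(self, arrays):
        self.running_mean, self.running_var = arrays[0], arrays[1]

    def forward(self, x, train):
        fast = _HAVE_NUMBA and x.dtype == np.float32
        c = x.shape[-1]
        if train:
            if fast:
                mean, var = _bn_stats(np.ascontiguousarray(x).reshape(-1, c))
            else:
                mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
                var = x.var(axis=(0, 1, 2), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        if fast:
            xhat2d, y2d = _bn_apply(np.ascontiguousarray(x).reshape(-1, c),
                                    mean.astype(x.dtype), inv_std,
                                    self.gamma.value, self.beta.value)
            self._cache = (xhat2d, inv_std, train, x.shape)
            return y2d.reshape(x.shape)
        xhat = (x - mean.astype(x.dtype)) * inv_std
        y = self.gamma.value * xhat + self.beta.value
        self._cache = (xhat, inv_std, train, x.shape)
        return y

    def backward(self, dy):
        xhat, inv_std, train, shape = self._cache
        if _HAVE_NUMBA and dy.dtype == np.float32 and xhat.ndim == 2:
            c = shape[-1]
            dgamma, dbeta, dx2d = _bn_bwd(
                np.ascontiguousarray(dy).reshape(-1, c), xhat, inv_std,
                self.gamma.value, train)
            self.gamma.grad += dgamma
            self.beta.grad += dbeta
            return dx2d.reshape(shape)
        axes = (0, 1, 2)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value
        if not train:
            return dy * g * inv_std
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dyg = dy * g
        t1 = dyg.sum(axis=axes, keepdims=True)
        t2 = (dyg * xhat).sum(axis=axes, keepdims=True)
        return inv_std * (dyg - t1 / m - xhat * t2 / m)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._x = None

    def forward(self, x, train):
        self._x = x
        if _HAVE_NUMBA and x.dtype == np.float32:
            flat = np.ascontiguousarray(x).reshape(-1)
            return _lrelu_fwd(flat, np.float32(self.slope)).reshape(x.shape)
        # max(x, slope*x) equals leaky ReLU for any slope < 1
        return np.maximum(x, np.asarray(self.slope, x.dtype) * x)

    def backward(self, dy):
        x = self._x
        if _HAVE_NUMBA and dy.dtype == np.float32 and x.dtype == np.float32:
            dx = _lrelu_bwd(np.ascontiguousarray(x).reshape(-1),
                            np.ascontiguousarray(dy).reshape(-1),
                            np.float32(self.slope))
            return dx.reshape(dy.shape)
        return np.where(x > 0, dy, np.asarray(self.slope, dy.dtype) * dy)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, std, (c_in, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class PreActResBlock(Layer):
    """Pre-activation residual block: BN -> LReLU -> conv -> BN -> LReLU -> conv.

    The identity shortcut becomes a strided 1x1 projection (applied to the
    pre-activated input) whenever the stride or channel count changes.
    """

    def __init__(self, c_in: int, c_out: int, stride=(1, 1), slope: float = 0.01,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.bn1 = BatchNorm2d(c_in, dtype=dtype)
        self.act1 = LeakyReLU(slope)
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(c_out, dtype=dtype)
        self.act2 = LeakyReLU(slope)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng, dtype=dtype)
        self.proj = None
        if tuple(stride) != (1, 1) or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, dtype=dtype)

    def _sublayers(self):
        subs = [self.bn1, self.act1, self.conv1, self.bn2, self.act2, self.conv2]
        if self.proj is not None:
            subs.append(self.proj)
        return subs

    def params(self):
        return [p for sub in self._sublayers() for p in sub.params()]

    def extra_state(self):
        return [a for sub in self._sublayers() for a in sub.extra_state()]

    def set_extra_state(self, arrays):
        i = 0
        for sub in self._sublayers():
            n = len(sub.extra_state())
            sub.set_extra_state(arrays[i : i + n])
            i += n

    def forward(self, x, train):
        h1 = self.act1.forward(self.bn1.forward(x, train), train)
        out = self.conv1.forward(h1, train)
        out = self.conv2.forward(self.act2.forward(self.bn2.forward(out, train), train), train)
        sc = self.proj.forward(h1, train) if self.proj is not None else x
        return out + sc

    def backward(self, dy):
        d_main = self.conv1.backward(
            self.bn2.backward(self.act2.backward(self.conv2.backward(dy)))
        )
        if self.proj is not None:
            d_h1 = d_main + self.proj.backward(dy)
            return self.bn1.backward(self.act1.backward(d_h1))
        return self.bn1.backward(self.act1.backward(d_main)) + dy


class Model(Layer):
    """A plain layer stack with parameter access and state (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def extra_state(self):
        return [a for layer in self.layers for a in layer.extra_state()]

    def set_extra_state(self, arrays):
        i = 0
        for layer in self.layers:
            n = len(layer.extra_state())
            layer.set_extra_state(arrays[i : i + n])
            i += n

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value for p in self.params()] + self.extra_state()

    def set_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        self.set_extra_state([np.asarray(a) for a in arrays[len(ps):]])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights=(0.5, 0.5)
) -> tuple[float, np.ndarray]:
    """Per-class-weighted cross entropy; returns (loss, dlogits).

    ``loss = sum_i w[y_i] * (-log p_i[y_i]) / sum_i w[y_i]``; with equal class
    weights this is exactly the plain mean cross-entropy.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    p_true = probs[np.arange(n), labels]
    loss = float(np.sum(w * -np.log(np.maximum(p_true, 1e-12))) / wsum)
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(logits.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= (self.lr * update).astype(p.value.dtype)
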