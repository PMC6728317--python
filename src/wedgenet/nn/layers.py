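"""Minimal feed-forward layers with explicit forward caches and hand-written backprop.

All tensors are ``float32`` arrays in ``(batch, channels, height, width)``
layout.  Every layer follows the same functional contract::

    y, cache = layer.forward(x, train=True)
    dx = layer.backward(dy, cache)          # accumulates into parameter .grad

Caches are returned to the caller rather than stored on the layer, so the
same layer instance can be run several times per training step (e.g. a GAN
discriminator evaluated on real and fake batches) without clobbering state.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def kaiming_normal(rng: np.random.Generator, shape, fan_in, gain=np.sqrt(2.0)):
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via an offset-loop im2col.

    Supports stride and dilation; padding defaults to "same" for stride 1
    (``pad='auto'`` computes ``(k-1)*dilation // 2`` per axis).
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad="auto", dilation=1,
                 rng=None, init_scale=1.0, bias=True, name="conv"):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.dh, self.dw = _pair(dilation)
        if pad == "auto":
            pad = ((self.kh - 1) * self.dh // 2, (self.kw - 1) * self.dw // 2)
        self.ph, self.pw = _pair(pad)
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * self.kh * self.kw
        w = kaiming_normal(rng, (out_ch, in_ch, self.kh, self.kw), fan_in) * init_scale
        self.weight = Parameter(w, name + ".weight")
        self.bias = Parameter(np.zeros(out_ch), name + ".bias") if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, xp, hout, wout):
        b, c = xp.shape[:2]
        cols = np.empty((b, c, self.kh, self.kw, hout, wout), dtype=DTYPE)
        for i in range(self.kh):
            hi = i * self.dh
            for j in range(self.kw):
                wj = j * self.dw
                cols[:, :, i, j] = xp[:, :, hi:hi + self.sh * hout:self.sh,
                                      wj:wj + self.sw * wout:self.sw]
        return cols

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        hout = (h + 2 * self.ph - (self.kh - 1) * self.dh - 1) // self.sh + 1
        wout = (w + 2 * self.pw - (self.kw - 1) * self.dw - 1) // self.sw + 1
        cols = self._im2col(xp, hout, wout).reshape(b, c * self.kh * self.kw, hout * wout)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y = np.matmul(wmat, cols).reshape(b, self.out_ch, hout, wout)
        if self.bias is not None:
            y += self.bias.data[:, None, None]
        return y, (cols, x.shape)

    def backward(self, dy, cache):
        cols, xshape = cache
        b, c, h, w = xshape
        _, _, hout, wout = dy.shape
        dyf = dy.reshape(b, self.out_ch, hout * wout)
        # weight/bias grads
        dw = np.einsum("bol,bkl->ok", dyf, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        # input grad
        wmat = self.weight.data.reshape(self.out_ch, -1)
        dcols = np.matmul(wmat.T, dyf).reshape(b, c, self.kh, self.kw, hout, wout)
        dxp = np.zeros((b, c, h + 2 * self.ph, w + 2 * self.pw), dtype=DTYPE)
        for i in range(self.kh):
            hi = i * self.dh
            for j in range(self.kw):
                wj = j * self.dw
                dxp[:, :, hi:hi + self.sh * hout:self.sh,
                    wj:wj + self.sw * wout:self.sw] += dcols[:, :, i, j]
        if self.ph or self.pw:
            dxp = dxp[:, :, self.ph:self.ph + h, self.pw:self.pw + w]
        return dxp


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = DTYPE(slope)

    def forward(self, x, train=True):
        neg = x < 0
        y = np.where(neg, x * self.slope, x)
        return y, neg

    def backward(self, dy, cache):
        return np.where(cache, dy * self.slope, dy)


class GroupNorm(Layer):
    """Per-sample group normalization with learnable affine parameters."""

    def __init__(self, channels, groups=4, eps=1e-5, name="gn"):
        if channels % groups:
            raise ValueError(f"groups ({groups}) must divide channels ({channels})")
        self.g, self.c, self.eps = groups, channels, eps
        self.gamma = Parameter(np.ones(channels), name + ".gamma")
        self.beta = Parameter(np.zeros(channels), name + ".beta")

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        xg = x.reshape(b, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(b, c, h, w)
        y = xhat * self.gamma.data[:, None, None] + self.beta.data[:, None, None]
        return y.astype(DTYPE), (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        b, c, h, w = dy.shape
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.data[:, None, None]).reshape(b, self.g, -1)
        xg = xhat.reshape(b, self.g, -1)
        n = xg.shape[2]
        dx = inv / n * (n * dxhat - dxhat.sum(axis=2, keepdims=True)
                        - xg * (dxhat * xg).sum(axis=2, keepdims=True))
        return dx.reshape(b, c, h, w).astype(DTYPE)


class BatchNorm2d(Layer):
    """Batch normalization with running statistics for deterministic inference."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, name="bn"):
        self.c, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(np.ones(channels), name + ".gamma")
        self.beta = Parameter(np.zeros(channels), name + ".beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        y = xhat * self.gamma.data[:, None, None] + self.beta.data[:, None, None]
        return y.astype(DTYPE), (xhat.astype(DTYPE), inv.astype(DTYPE), train)

    def backward(self, dy, cache):
        xhat, inv, train = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[:, None, None]
        if not train:
            return (dxhat * inv[:, None, None]).astype(DTYPE)
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = inv[:, None, None] / n * (n * dxhat - s1 - xhat * s2)
        return dx.astype(DTYPE)


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling; spatial dims must be even."""

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=4)
        y = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy, cache):
        idx, (b, c, h, w) = cache
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=4)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)


class UpsampleNearest2x(Layer):
    def forward(self, x, train=True):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, None

    def backward(self, dy, cache):
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy, cache):
        b, c, h, w = cache
        return np.broadcast_to(dy[:, :, None, None] / (h * w), cache).astype(DTYPE)


class GlobalMaxPool(Layer):
    def forward(self, x, train=True):
        b, c, h, w = x.shape
        flat = x.reshape(b, c, -1)
        idx = flat.argmax(axis=2)
        return np.take_along_axis(flat, idx[..., None], axis=2)[..., 0], (idx, x.shape)

    def backward(self, dy, cache):
        idx, shape = cache
        b, c = idx.shape
        dflat = np.zeros((b, c, shape[2] * shape[3]), dtype=DTYPE)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=2)
        return dflat.reshape(shape)


class Linear(Layer):
    def __init__(self, in_f, out_f, rng=None, name="linear"):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(kaiming_normal(rng, (out_f, in_f), in_f, gain=1.0),
                                name + ".weight")
        self.bias = Parameter(np.zeros(out_f), name + ".bias")

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        return x @ self.weight.data.T + self.bias.data, x

    def backward(self, dy, cache):
        self.weight.grad += dy.T @ cache
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=True):
        caches = []
        for l in self.layers:
            x, c = l.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(dy, c)
        return dy
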