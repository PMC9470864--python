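"""A small CPU 3D conv-net engine: layers, manual backprop and Adam.

Tensors are float32 numpy arrays shaped ``(N, C, D, H, W)``. Convolutions
are evaluated as im2col + BLAS matmul; the data gradient of a strided
convolution is computed as a stride-1 convolution of the zero-dilated
output gradient with the flipped, transposed kernel, so every heavy op is
a matrix product. Layers cache what backward needs only when called with
``train=True``; evaluation passes keep peak memory low.

Gradient correctness of every layer is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """x (N,C,D,H,W) -> cols (N, C*k^3, P) and the output spatial shape.

    Filled by k^3 strided slice copies (contiguous inner axis), which is much
    faster than transposing a sliding-window view.
    """
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    n, c, d, h, w = x.shape
    do = (d - k) // s + 1
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    P = do * ho * wo
    cols = np.empty((n, c, k * k * k, P), dtype=x.dtype)
    j = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                sl = x[
                    :, :,
                    dz : dz + (do - 1) * s + 1 : s,
                    dy : dy + (ho - 1) * s + 1 : s,
                    dx : dx + (wo - 1) * s + 1 : s,
                ]
                cols[:, :, j, :] = sl.reshape(n, c, P)
                j += 1
    return cols.reshape(n, c * k * k * k, P), (do, ho, wo)


def _conv_raw(x: np.ndarray, w: np.ndarray, s: int, p: int):
    """Correlate x with w (Cout, Cin, k, k, k); returns y and the cols buffer."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    cols, out_sp = _im2col(x, k, s, p)
    y = np.matmul(w.reshape(cout, cin * k**3), cols)  # (N, Cout, P)
    n = x.shape[0]
    return y.reshape(n, cout, *out_sp), cols


def _conv_backward_data(gy: np.ndarray, w: np.ndarray, s: int, p: int, in_spatial):
    """Gradient w.r.t. the conv input, as a stride-1 conv of the dilated gy."""
    k = w.shape[2]
    n, cout = gy.shape[:2]
    if s > 1:
        dil = tuple((d - 1) * s + 1 for d in gy.shape[2:])
        gyd = np.zeros((n, cout, *dil), dtype=gy.dtype)
        gyd[:, :, ::s, ::s, ::s] = gy
    else:
        gyd = gy
    left = k - 1 - p
    pads = [(0, 0), (0, 0)]
    for ax in range(3):
        right = in_spatial[ax] + p - gyd.shape[2 + ax]
        pads.append((left, max(0, right)))
    gyd = np.pad(gyd, pads)
    w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    gx, _ = _conv_raw(gyd, w_t, 1, 0)
    return gx[:, :, : in_spatial[0], : in_spatial[1], : in_spatial[2]]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """k x k x k convolution, stride s, symmetric zero padding p (default k//2)."""

    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None):
        self.cin, self.cout, self.k = int(cin), int(cout), int(k)
        self.s = int(stride)
        self.p = self.k // 2 if pad is None else int(pad)
        rng = rng or np.random.default_rng(0)
        fan_in = self.cin * self.k**3
        self.w = Param(he_init(rng, (self.cout, fan_in), fan_in))
        self.b = Param(np.zeros(self.cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n = x.shape[0]
        if self.k == 1 and self.s == 1:
            xr = x.reshape(n, self.cin, -1)
            y = np.matmul(self.w.value, xr)
            y += self.b.value[None, :, None]
            if train:
                self._cache = ("k1", xr, x.shape)
            return y.reshape(n, self.cout, *x.shape[2:])
        cols, out_sp = _im2col(x, self.k, self.s, self.p)
        y = np.matmul(self.w.value, cols)  # (N, Cout, P)
        y += self.b.value[None, :, None]
        if train:
            self._cache = ("gen", cols, x.shape)
        return y.reshape(n, self.cout, *out_sp)

    def backward(self, gy):
        kind, cached, x_shape = self._cache
        n = gy.shape[0]
        g = gy.reshape(n, self.cout, -1)
        self.b.grad += g.sum(axis=(0, 2))
        # cached is (N, CK, P) for both paths; BLAS handles the strided transpose.
        self.w.grad += np.matmul(g, cached.transpose(0, 2, 1)).sum(axis=0)
        if kind == "k1":
            gx = np.matmul(self.w.value.T, g)
            return gx.reshape(x_shape)
        w5 = self.w.value.reshape(self.cout, self.cin, self.k, self.k, self.k)
        return _conv_backward_data(gy, w5, self.s, self.p, x_shape[2:])


class ConvTranspose2x(Layer):
    """Transposed convolution with kernel 2, stride 2: exact 2x upsampling."""

    def __init__(self, cin, cout, rng=None):
        self.cin, self.cout = int(cin), int(cout)
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (self.cin, self.cout * 8), self.cin))
        self.b = Param(np.zeros(self.cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, c, d, h, w_ = x.shape
        xr = x.reshape(n, c, -1).transpose(0, 2, 1)  # (N, P, Cin)
        y = xr @ self.w.value  # (N, P, Cout*8)
        y = y.reshape(n, d, h, w_, self.cout, 2, 2, 2)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, self.cout, 2 * d, 2 * h, 2 * w_)
        y += self.b.value[None, :, None, None, None]
        if train:
            self._cache = (xr, (n, c, d, h, w_))
        return y

    def backward(self, gy):
        xr, (n, c, d, h, w_) = self._cache
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        g = gy.reshape(n, self.cout, d, 2, h, 2, w_, 2)
        g = g.transpose(0, 2, 4, 6, 1, 3, 5, 7).reshape(n, d * h * w_, self.cout * 8)
        self.w.grad += np.einsum("npk,npc->ck", g, xr, optimize=True)
        gx = g @ self.w.value.T  # (N, P, Cin)
        return gx.transpose(0, 2, 1).reshape(n, c, d, h, w_)


class InstanceNorm(Layer):
    """Per-(sample, channel) normalization over the spatial axes, with affine."""

    def __init__(self, c, eps=1e-5):
        self.c = int(c)
        self.eps = float(eps)
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        n, c = x.shape[:2]
        xr = x.reshape(n, c, -1)
        mu = xr.mean(axis=2, keepdims=True)
        var = xr.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xr - mu) * inv
        y = xhat * self.gamma.value[None, :, None] + self.beta.value[None, :, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, gy):
        xhat, inv, shape = self._cache
        n, c = shape[:2]
        g = gy.reshape(n, c, -1)
        self.gamma.grad += (g * xhat).sum(axis=(0, 2))
        self.beta.grad += g.sum(axis=(0, 2))
        gsc = g * self.gamma.value[None, :, None]
        m1 = gsc.mean(axis=2, keepdims=True)
        m2 = (gsc * xhat).mean(axis=2, keepdims=True)
        gx = inv * (gsc - m1 - xhat * m2)
        return gx.reshape(shape).astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(np.float32)
        return np.maximum(x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, gprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Chain a gradient w.r.t. softmax outputs back to the logits."""
    dot = (gprobs * probs).sum(axis=axis, keepdims=True)
    return (probs * (gprobs - dot)).astype(np.float32)


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.wd = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.wd:
                g = g + self.wd * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
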