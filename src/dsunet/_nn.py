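"""Minimal NumPy neural-network engine.

Implements exactly the operations the depthwise-separable U-Net classifier and
the desk-scale GAN need: depthwise / pointwise convolution, batch
normalization, ReLU, 2x2 average pooling, 2x bilinear upsampling, dense
layers, global average pooling, softmax cross-entropy, and an Adam optimizer.
All tensors are NCHW (batch, channels, height, width) internally; the public
modules state their contracts in H x W x C terms and convert at the boundary.

Every layer supports ``forward`` / ``backward`` with explicit caches.  Layers
used inside the GAN discriminator additionally support ``gp_forward``: the
adjoint pass needed to differentiate a gradient penalty with respect to the
weights.  With ReLU as the only nonlinearity the activation masks are
piecewise constant, so treating them as fixed during the second pass gives
the exact penalty gradient almost everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "DepthwiseConv3x3",
    "PointwiseConv",
    "BatchNorm",
    "ReLU",
    "Sigmoid",
    "AvgPool2",
    "BilinearUp2",
    "GlobalAvgPool",
    "Dense",
    "Adam",
    "linear_interp_matrix",
    "bilinear_resize",
    "softmax",
    "softmax_cross_entropy",
    "he_normal",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# interpolation matrices (shared by image resize and network upsampling)
# ---------------------------------------------------------------------------

def linear_interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Corner-aligned 1-D linear interpolation matrix of shape (n_out, n_in).

    Output sample i reads input coordinate ``i * (n_in - 1) / (n_out - 1)``
    (the corner-aligned convention: first and last samples coincide).  Rows
    sum to one, so constants are preserved exactly.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("interpolation sizes must be >= 1")
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    if n_out == 1:
        # degenerate target: read the first input sample
        A[0, 0] = 1.0
        return A
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(src).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = src - lo
    A[np.arange(n_out), lo] = 1.0 - frac
    A[np.arange(n_out), lo + 1] += frac
    return A


def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable corner-aligned bilinear resize of an (H, W) or (H, W, C) array."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return bilinear_resize(img[:, :, None], out_h, out_w)[:, :, 0]
    Ah = linear_interp_matrix(img.shape[0], out_h)
    Aw = linear_interp_matrix(img.shape[1], out_w)
    return np.einsum("ih,hwc,jw->ijc", Ah, img, Aw, optimize=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class DepthwiseConv3x3(Layer):
    """Per-channel 3x3 convolution, stride 1, padding 1, no bias."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.channels = channels
        if rng is None:
            k = np.zeros((channels, 3, 3))
        else:
            k = he_normal(rng, (channels, 3, 3), fan_in=9)
        self.kernel = Param(k)
        self._xp = None
        self._gy = None

    def params(self):
        return [self.kernel]

    def forward(self, x, training=True):
        N, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"channel mismatch: got {C}, expected {self.channels}")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        k = self.kernel.value
        y = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                y += k[:, i, j][None, :, None, None] * xp[:, :, i:i + H, j:j + W]
        self._xp = xp
        return y

    def backward(self, gy):
        N, C, H, W = gy.shape
        xp = self._xp
        k = self.kernel.value
        for i in range(3):
            for j in range(3):
                self.kernel.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", gy, xp[:, :, i:i + H, j:j + W], optimize=True)
        gyp = np.pad(gy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gx = np.zeros_like(gy)
        for i in range(3):
            for j in range(3):
                gx += k[:, i, j][None, :, None, None] * gyp[:, :, 2 - i:2 - i + H, 2 - j:2 - j + W]
        self._gy = gy
        return gx

    def gp_forward(self, u, scale=1.0):
        # adjoint of the input-gradient map; weight contribution pairs the
        # stored backward grad with the incoming adjoint
        N, C, H, W = u.shape
        up = np.pad(u, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gy = self._gy
        k = self.kernel.value
        for i in range(3):
            for j in range(3):
                self.kernel.grad[:, i, j] += scale * np.einsum(
                    "nchw,nchw->c", gy, up[:, :, i:i + H, j:j + W], optimize=True)
        uy = np.zeros_like(u)
        for i in range(3):
            for j in range(3):
                uy += k[:, i, j][None, :, None, None] * up[:, :, i:i + H, j:j + W]
        return uy


class PointwiseConv(Layer):
    """1x1 convolution mixing channels, no bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        if rng is None:
            k = np.zeros((c_in, c_out))
        else:
            k = he_normal(rng, (c_in, c_out), fan_in=c_in)
        self.kernel = Param(k)
        self._x = None
        self._gy = None

    def params(self):
        return [self.kernel]

    def forward(self, x, training=True):
        if x.shape[1] != self.c_in:
            raise ValueError(f"channel mismatch: got {x.shape[1]}, expected {self.c_in}")
        self._x = x
        return np.einsum("nchw,ck->nkhw", x, self.kernel.value, optimize=True)

    def backward(self, gy):
        self.kernel.grad += np.einsum("nchw,nkhw->ck", self._x, gy, optimize=True)
        self._gy = gy
        return np.einsum("nkhw,ck->nchw", gy, self.kernel.value, optimize=True)

    def gp_forward(self, u, scale=1.0):
        self.kernel.grad += scale * np.einsum("nchw,nkhw->ck", u, self._gy, optimize=True)
        return np.einsum("nchw,ck->nkhw", u, self.kernel.value, optimize=True)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with mini-batch statistics (population variance)
    and updates running estimates with momentum 0.1; evaluation mode uses the
    running estimates, making inference deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=True):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, inv_std, training, shape = self._cache
        N, C, H, W = shape
        M = N * H * W
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        g = gy * self.gamma.value[None, :, None, None]
        if not training:
            return g * inv_std[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3))
        sum_gx = (g * xhat).sum(axis=(0, 2, 3))
        gx = (g - (sum_g[None, :, None, None] + xhat * sum_gx[None, :, None, None]) / M)
        return gx * inv_std[None, :, None, None]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)

    def gp_forward(self, u, scale=1.0):
        return np.where(self._mask, u, 0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, training=True):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class AvgPool2(Layer):
    """2x2 average pooling with stride 2.  Requires even spatial dimensions."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=True):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"average pooling needs even spatial dims, got {H}x{W}")
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, gy):
        N, C, H, W = self._shape
        g = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) / 4.0
        return g

    def gp_forward(self, u, scale=1.0):
        N, C, H, W = u.shape
        return u.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix(n: int) -> np.ndarray:
    A = _UP_CACHE.get(n)
    if A is None:
        A = linear_interp_matrix(n, 2 * n)
        _UP_CACHE[n] = A
    return A


class BilinearUp2(Layer):
    """2x bilinear upsampling (corner-aligned); linear, constant-preserving."""

    def __init__(self):
        self._hw = None

    def forward(self, x, training=True):
        N, C, H, W = x.shape
        self._hw = (H, W)
        Ah, Aw = _up_matrix(H), _up_matrix(W)
        return np.einsum("ih,nchw,jw->ncij", Ah, x, Aw, optimize=True)

    def backward(self, gy):
        H, W = self._hw
        Ah, Aw = _up_matrix(H), _up_matrix(W)
        return np.einsum("ih,ncij,jw->nchw", Ah, gy, Aw, optimize=True)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._hw = None

    def forward(self, x, training=True):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        H, W = self._hw
        return np.broadcast_to(gy[:, :, None, None], gy.shape + (H, W)).copy() / (H * W)

    def gp_forward(self, u, scale=1.0):
        return u.mean(axis=(2, 3))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        self.d_in, self.d_out = d_in, d_out
        W = np.zeros((d_in, d_out)) if rng is None else he_normal(rng, (d_in, d_out), fan_in=d_in)
        self.weight = Param(W)
        self.bias = Param(np.zeros(d_out)) if bias else None
        self._x = None
        self._gy = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=True):
        self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, gy):
        self.weight.grad += self._x.T @ gy
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=0)
        self._gy = gy
        return gy @ self.weight.value.T

    def gp_forward(self, u, scale=1.0):
        # the bias does not enter the input-gradient map
        self.weight.grad += scale * (u.T @ self._gy)
        return u @ self.weight.value


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
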