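"""Dense 2-D layers with explicit forward/backward passes.

All arrays are NCHW float32.  Convolutions are stride-1, same-padding,
implemented by im2col + BLAS matmul; the depthwise variant uses the
nine-shift formulation, vectorized over channels.  Layers cache what
their backward pass needs, so one backward must follow each forward.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def _im2col(x: np.ndarray, k: int, p: int) -> np.ndarray:
    # (N, C, H, W) -> (N, C*k*k, H*W)
    N, C, H, W = x.shape
    if k == 1:
        return x.reshape(N, C, H * W)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)
                                ).reshape(N, C * k * k, H * W)


def _col2im(dcols: np.ndarray, x_shape, k: int, p: int) -> np.ndarray:
    N, C, H, W = x_shape
    if k == 1:
        return dcols.reshape(N, C, H, W)
    d = dcols.reshape(N, C, k, k, H, W)
    dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += d[:, :, i, j]
    return dxp[:, :, p:p + H, p:p + W]


class Conv2D:
    """Stride-1 same-padding convolution (kernel 3 or 1)."""

    def __init__(self, rng, cin: int, cout: int, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        self.p = k // 2
        self.w = Parameter(he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Parameter(np.zeros(cout, dtype=DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        N, C, H, W = x.shape
        cols = _im2col(x, self.k, self.p)
        self._cols = cols
        out = np.matmul(self.w.value, cols) + self.b.value[:, None]
        return out.reshape(N, self.cout, H, W)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._x_shape
        gym = gy.reshape(N, self.cout, H * W)
        self.w.grad += np.matmul(gym, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += gym.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, gym)
        self._cols = None
        return _col2im(dcols, self._x_shape, self.k, self.p)


class DepthwiseConv2D:
    """Per-channel 3x3 convolution (depth multiplier 1)."""

    def __init__(self, rng, channels: int, k: int = 3):
        self.c, self.k, self.p = channels, k, k // 2
        self.w = Parameter(he_init(rng, (channels, k, k), k * k))
        self.b = Parameter(np.zeros(channels, dtype=DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        self._xp = xp
        out = np.zeros((N, C, H, W), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                out += self.w.value[:, i, j][None, :, None, None] \
                    * xp[:, :, i:i + H, j:j + W]
        return out + self.b.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._x_shape
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                self.w.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", gy, self._xp[:, :, i:i + H, j:j + W])
                dxp[:, :, i:i + H, j:j + W] += \
                    self.w.value[:, i, j][None, :, None, None] * gy
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self._xp = None
        return dxp[:, :, self.p:self.p + H, self.p:self.p + W]


class GroupNorm:
    """Group normalization over channel groups (batch-size independent).

    Normalizes each sample over (C/G channels x H x W) per group, then
    applies a learned per-channel affine.  No running statistics, so
    training and inference behave identically and runs are
    deterministic.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.c = channels
        self.g = min(groups, channels)
        while channels % self.g:
            self.g -= 1
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        self._shape = x.shape
        xg = x.reshape(N, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) * self._inv).reshape(N, C, H, W)
        return self._xhat * self.gamma.value[None, :, None, None] \
            + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        self.gamma.grad += (gy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        dxhat = (gy * self.gamma.value[None, :, None, None]) \
            .reshape(N, self.g, -1)
        xhat = self._xhat.reshape(N, self.g, -1)
        m = dxhat.shape[2]
        dx = (dxhat - dxhat.mean(axis=2, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=2, keepdims=True)) * self._inv
        self._xhat = None
        return dx.reshape(N, C, H, W).astype(DTYPE)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0)


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        self._x_shape = x.shape
        cand = x.reshape(N, C, H // 2, 2, W // 2, 2) \
                .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        self._arg = cand.argmax(axis=-1)
        return np.take_along_axis(cand, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._x_shape
        d = np.zeros((N, C, H // 2, W // 2, 4), dtype=gy.dtype)
        np.put_along_axis(d, self._arg[..., None], gy[..., None], axis=-1)
        return d.reshape(N, C, H // 2, W // 2, 2, 2) \
                .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, C, H, W = gy.shape
        return gy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adaptive-moment optimizer (step 1e-3, moment decays 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
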