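"""Minimal numpy neural-network primitives used by the convolutional autoencoder.

Implements exactly the layer set the channel-wise CAE needs — 3x3 "same"
convolution, batch normalisation, ReLU, 2x2 max pooling, 2x nearest-neighbour
upsampling — plus the Adam optimiser. Convolutions are evaluated as im2col
matrix products so the heavy lifting is one BLAS GEMM per layer; tensors are
kept in NHWC layout throughout, which lets im2col be nine contiguous strided
copies instead of a gather.

All layers operate on (n, h, w, c) float32 arrays and provide
`forward(x, train)` / `backward(grad)` with cached activations. This is
deliberately small: not a general autograd, just enough machinery to train a
~200k-parameter autoencoder on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3x3",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Sequential",
    "Adam",
    "count_params",
]

_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (output size == input size).

    Weight layout: (9 * c_in, c_out); row block k corresponds to tap offset
    ``_OFFSETS[k]``. ``input_grad=False`` skips the gradient w.r.t. the input
    (valid for the first layer of a network).
    """

    #: im2col buffers above this many elements switch to the shift path
    _COLS_LIMIT = 2_500_000

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, input_grad: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad
        # He initialisation for the ReLU regime that follows almost every conv
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = Param(rng.normal(0.0, std, size=(9 * c_in, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cols: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _use_shift(self, x: np.ndarray) -> bool:
        # shift-accumulate wins when the im2col buffer would be large and the
        # output is narrower than the unrolled input
        return (9 * x.size > self._COLS_LIMIT
                and 2 * self.c_out < 9 * self.c_in)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
        for k, (i, j) in enumerate(_OFFSETS):
            cols[..., k * c:(k + 1) * c] = xp[:, i:i + h, j:j + w, :]
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self._use_shift(x):
            return self._forward_shift(x, train)
        n, h, w, c = x.shape
        cols = self._im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        y = cols @ self.w.data + self.b.data
        return y.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._x is not None:
            return self._backward_shift(grad)
        n, h, w, c = self._shape
        g2 = grad.reshape(n * h * w, self.c_out)
        self.w.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return None
        dcols = (g2 @ self.w.data.T).reshape(n, h, w, 9 * c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=grad.dtype)
        for k, (i, j) in enumerate(_OFFSETS):
            dxp[:, i:i + h, j:j + w, :] += dcols[..., k * c:(k + 1) * c]
        return dxp[:, 1:-1, 1:-1, :]

    # -- shift-accumulate path: y[p,q] = sum_k x[p+di, q+dj] @ W_k ---------

    def _forward_shift(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        x2 = x.reshape(-1, c)
        y = np.empty((n, h, w, self.c_out), dtype=x.dtype)
        y[...] = self.b.data
        for k, (i, j) in enumerate(_OFFSETS):
            di, dj = i - 1, j - 1
            t = (x2 @ self.w.data[k * c:(k + 1) * c]).reshape(
                n, h, w, self.c_out)
            ra, rb = max(0, -di), min(h, h - di)
            ca, cb = max(0, -dj), min(w, w - dj)
            y[:, ra:rb, ca:cb] += t[:, ra + di:rb + di, ca + dj:cb + dj]
        if train:
            self._x, self._shape = x, x.shape
        return y

    def _backward_shift(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        x2 = self._x.reshape(-1, c)
        g2 = grad.reshape(-1, self.c_out)
        gpad = np.pad(grad, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self.b.grad += g2.sum(axis=0)
        dx = np.zeros(self._shape, dtype=grad.dtype) if self.input_grad else None
        for k, (i, j) in enumerate(_OFFSETS):
            di, dj = i - 1, j - 1
            gs = gpad[:, 1 - di:1 - di + h, 1 - dj:1 - dj + w, :]
            self.w.grad[k * c:(k + 1) * c] += x2.T @ gs.reshape(-1, self.c_out)
            if dx is not None:
                u = (g2 @ self.w.data[k * c:(k + 1) * c].T).reshape(n, h, w, c)
                ra, rb = max(0, di), min(h, h + di)
                ca, cb = max(0, dj), min(w, w + dj)
                dx[:, ra:rb, ca:cb] += u[:, ra - di:rb - di, ca - dj:cb - dj]
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (n, h, w)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.data
        gm = g.mean(axis=(0, 1, 2))
        gxm = (g * xhat).mean(axis=(0, 1, 2))
        return inv * (g - gm - xhat * gxm)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (halves h and w).

    On ties the gradient is routed to the first of the four window positions
    (row-major) attaining the maximum.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        quads = (x[:, 0::2, 0::2], x[:, 0::2, 1::2],
                 x[:, 1::2, 0::2], x[:, 1::2, 1::2])
        y = np.maximum(np.maximum(quads[0], quads[1]),
                       np.maximum(quads[2], quads[3]))
        if train:
            self._quads, self._y, self._inshape = quads, y, x.shape
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        taken = np.zeros(grad.shape, dtype=bool)
        views = (dx[:, 0::2, 0::2], dx[:, 0::2, 1::2],
                 dx[:, 1::2, 0::2], dx[:, 1::2, 1::2])
        for q, v in zip(self._quads, views):
            m = (q == self._y) & ~taken
            v[m] = grad[m]
            taken |= m
        self._quads = self._y = None
        return dx


class Upsample2(Layer):
    """2x nearest-neighbour upsampling (doubles h and w)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


def count_params(layers) -> int:
    """Total number of trainable scalars (conv weights/biases, BN gamma/beta)."""
    if isinstance(layers, Layer):
        layers = [layers]
    return int(sum(p.data.size for lay in layers for p in lay.params()))


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
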