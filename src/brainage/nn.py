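"""Minimal NumPy neural-network engine for 3D convolutional regression.

Implements exactly the layers a small volumetric residual regressor needs —
3D convolution, batch normalisation, ReLU, residual blocks, global average
pooling, a linear head — together with reverse-mode gradients and an Adam
optimiser.  Forward passes use :func:`numpy.lib.stride_tricks.sliding_window_view`
so convolutions reduce to a single ``einsum``; backward passes are written by
hand and are checked against finite differences in the test suite.

Tensors follow the ``(N, C, D, H, W)`` layout.  All layers operate in the
dtype of their parameters (float32 by default; float64 is used for gradient
checking).
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "GlobalAvgPool3d",
    "Linear",
    "ResidualBlock3d",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: layers expose ``forward``/``backward`` and their params."""

    def params(self) -> Iterator[Param]:
        return iter(())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution with 'same'-style zero padding (pad = kernel // 2).

    Output spatial size is ``ceil(dim / stride)`` for odd kernels, which keeps
    shapes predictable across stride-2 downsampling stages.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel ** 3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.w = Param(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._win = None
        self._in_shape = None

    def params(self) -> Iterator[Param]:
        yield self.w
        yield self.b

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.kernel
        self._in_shape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        if s > 1:
            win = win[:, :, ::s, ::s, ::s]
        self._win = win if train else None
        out = np.einsum("ncdhwijk,ocijk->nodhw", win, self.w.value, optimize=True)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._win is None:
            raise RuntimeError("backward called without a training-mode forward")
        p, s, k = self.pad, self.stride, self.kernel
        self.w.grad += np.einsum("nodhw,ncdhwijk->ocijk", grad, self._win, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        n, _, D, H, W = self._in_shape
        gxp = np.zeros((n, self.c_in, D + 2 * p, H + 2 * p, W + 2 * p), dtype=grad.dtype)
        Do, Ho, Wo = grad.shape[2:]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    contrib = np.einsum("nodhw,oc->ncdhw", grad,
                                        self.w.value[:, :, i, j, l], optimize=True)
                    gxp[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s] += contrib
        self._win = None
        if p:
            return gxp[:, :, p:p + D, p:p + H, p:p + W]
        return gxp


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over the (N, D, H, W) axes.

    Batch statistics are used in training mode; exponential running averages
    (momentum 0.1) are used at inference.
    """

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._xhat = None
        self._istd = None

    def params(self) -> Iterator[Param]:
        yield self.gamma
        yield self.beta

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * istd[None, :, None, None, None]
        if train:
            self._xhat, self._istd = xhat, istd
        out = self.gamma.value[None, :, None, None, None] * xhat
        return out + self.beta.value[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        g_sum = grad.sum(axis=axes)
        gx_sum = (grad * xhat).sum(axis=axes)
        self.gamma.grad += gx_sum
        self.beta.grad += g_sum
        coef = (self.gamma.value * istd / m)[None, :, None, None, None]
        gx = coef * (m * grad
                     - g_sum[None, :, None, None, None]
                     - xhat * gx_sum[None, :, None, None, None])
        self._xhat = self._istd = None
        return gx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)  # propagates NaN, unlike a where-mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, grad, 0.0).astype(grad.dtype, copy=False)
        self._mask = None
        return gx


class GlobalAvgPool3d(Layer):
    """Mean over the spatial axes: (N, C, D, H, W) -> (N, C)."""

    def __init__(self):
        self._spatial = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d, h, w = self._spatial
        m = d * h * w
        return np.broadcast_to(grad[:, :, None, None, None] / m,
                               grad.shape + (d, h, w)).astype(grad.dtype, copy=True)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(1.0 / n_in)
        self.w = Param(rng.normal(0.0, std, (n_out, n_in)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self._x = None

    def params(self) -> Iterator[Param]:
        yield self.w
        yield self.b

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        gx = grad @ self.w.value
        self._x = None
        return gx


class _Identity(Layer):
    def forward(self, x, train):
        return x

    def backward(self, grad):
        return grad


class _Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> Iterator[Param]:
        for layer in self.layers:
            yield from layer.params()

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock3d(Layer):
    """Pre-ResNet-style block: conv-BN-ReLU-conv-BN plus a skip, then ReLU.

    When the block changes resolution (stride > 1) or channel count, the skip
    path is a strided 1x1x1 convolution (with its own BN when enabled).
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator,
                 use_batch_norm: bool = True, dtype=np.float32):
        def bn(c):
            return BatchNorm3d(c, dtype=dtype) if use_batch_norm else _Identity()

        self.main = _Sequential([
            Conv3d(c_in, c_out, 3, stride, rng, dtype),
            bn(c_out),
            ReLU(),
            Conv3d(c_out, c_out, 3, 1, rng, dtype),
            bn(c_out),
        ])
        if stride != 1 or c_in != c_out:
            self.skip: Layer = _Sequential([Conv3d(c_in, c_out, 1, stride, rng, dtype),
                                            bn(c_out)])
        else:
            self.skip = _Identity()
        self.out_relu = ReLU()

    def params(self) -> Iterator[Param]:
        yield from self.main.params()
        yield from self.skip.params()

    def forward(self, x, train):
        return self.out_relu.forward(self.main.forward(x, train) + self.skip.forward(x, train),
                                     train)

    def backward(self, grad):
        grad = self.out_relu.backward(grad)
        return self.main.backward(grad) + self.skip.backward(grad)


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.param_list = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.param_list]
        self._v = [np.zeros_like(p.value) for p in self.param_list]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.param_list, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.param_list:
            p.zero_grad()
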