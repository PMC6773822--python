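"""Minimal convolutional-network core in numpy.

Implements exactly the layer set the translation network needs — 2-D
convolution (stride 1 and 2), 2x2 stride-2 transpose convolution, batch
normalization and Leaky ReLU — each with an explicit backward pass, plus the
Adam optimizer.  Convolutions are evaluated as matrix products on im2col
patch matrices so the heavy lifting runs through BLAS; the kernel-position
loops touch at most kernel_size^2 slices and are negligible.

Layout convention throughout: (N, C, H, W) float32 tensors.  Layers cache
what their backward pass needs on ``forward(..., training=True)``; backward
accumulates parameter gradients into ``Param.grad`` (call ``zero_grad``
between steps) and returns the gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Patch matrix (N, C*k*k, oh*ow) from a padded input (N, C, Hp, Wp)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(
    dcols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int, oh: int, ow: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """2-D convolution with square kernel, 'same'-style padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        dtype=np.float32,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        self.w = Param(np.zeros((out_channels, in_channels, kernel, kernel), dtype=dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.pad - self.kernel) // self.stride + 1
        ow = (w + 2 * self.pad - self.kernel) // self.stride + 1
        return oh, ow

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad))) if self.pad else x
        cols = _im2col(xp, self.kernel, self.stride, oh, ow)
        wmat = self.w.value.reshape(self.out_channels, -1)
        y = wmat @ cols + self.b.value[:, None]
        if training:
            self._cache = (cols, x.shape, (oh, ow))
        return y.reshape(n, self.out_channels, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, (oh, ow) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_channels, oh * ow)
        self.w.grad += (dyf @ cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=(0, 2))
        wmat = self.w.value.reshape(self.out_channels, -1)
        dcols = wmat.T @ dyf
        return _col2im(dcols, xshape, self.kernel, self.stride, self.pad, oh, ow)


class ConvTranspose2d(Layer):
    """Transpose convolution with kernel == stride (non-overlapping upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 2, dtype=np.float32) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel  # also the stride
        self.w = Param(np.zeros((in_channels, out_channels, kernel, kernel), dtype=dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        y = np.empty((n, self.out_channels, h * k, w * k), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                # (n,c,h,w) x (c,f) -> (n,h,w,f) -> (n,f,h,w)
                y[:, :, i::k, j::k] = np.tensordot(
                    x, self.w.value[:, :, i, j], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        y += self.b.value[None, :, None, None]
        if training:
            self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        k = self.kernel
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                dy_ij = dy[:, :, i::k, j::k]
                self.w.grad[:, :, i, j] += np.tensordot(x, dy_ij, axes=([0, 2, 3], [0, 2, 3]))
                dx += np.tensordot(dy_ij, self.w.value[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n, _, h, w = dy.shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx.astype(dy.dtype, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        mask = x >= 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
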