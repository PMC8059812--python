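"""Minimal numpy layer framework with manual backpropagation.

Implements exactly the operations the adversarial autoencoder needs:
stride-1 "same" convolutions, 2x2 max pooling and nearest-neighbour
upsampling, batch normalization, dense layers, leaky-ReLU/tanh
nonlinearities, and an Adam optimizer.  Tensors are NCHW for spatial
layers.  Every layer caches what its backward pass needs; gradients are
accumulated into ``Param.grad`` and consumed by :class:`Adam`.

Correctness of the backward passes is pinned by finite-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64  # training precision

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "Upsample2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "LeakyReLU",
    "Tanh",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "bce_with_logits",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init, suits leaky-ReLU stacks
        self.W = Param(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Param(rng.standard_normal((c_out, c_in, kernel, kernel)) * scale)
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.pad = kernel // 2
        self._xp: np.ndarray | None = None

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        out = np.einsum("nchwij,ocij->nohw", win, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad):
        p = self.pad
        win = sliding_window_view(self._xp, (self.kernel, self.kernel), axis=(2, 3))
        self.W.grad += np.einsum("nchwij,nohw->ocij", win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gp, (self.kernel, self.kernel), axis=(2, 3))
        w_flip = self.W.value[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", gwin, w_flip, optimize=True)

    def params(self):
        return [self.W, self.b]


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Upsample2d(Layer):
    """2x2 nearest-neighbour upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _BatchNormBase(Layer):
    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._axes: tuple[int, ...] = (0,)

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v

    def forward(self, x, train=True):
        axes = self._axes
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv)
        self._xhat, self._inv, self._train = xhat, inv, train
        self._m = x.size // mean.size
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, grad):
        axes = self._axes
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self._shape(self.gamma.value)
        if not self._train:
            return g * self._shape(inv)
        sum_g = g.sum(axis=axes, keepdims=True)
        sum_gx = (g * xhat).sum(axis=axes, keepdims=True)
        return (self._shape(inv) / m) * (m * g - sum_g - xhat * sum_gx)

    def params(self):
        return [self.gamma, self.beta]


class BatchNorm2d(_BatchNormBase):
    def __init__(self, n_channels: int, **kw):
        super().__init__(n_channels, **kw)
        self._axes = (0, 2, 3)

    def _shape(self, v):
        return np.asarray(v).reshape(1, -1, 1, 1) if np.ndim(v) <= 1 else v


class BatchNorm1d(_BatchNormBase):
    pass


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape, batch axis implied

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0], *self.shape))

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on raw logits.

    Returns (mean loss, gradient w.r.t. logits).
    """
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    sig = 1.0 / (1.0 + np.exp(-logits))
    return float(loss.mean()), (sig - targets) / logits.size
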