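"""Minimal reverse-mode layer library for small staged sensory models.

Every layer implements ``forward(x)`` (caching what backward needs) and
``backward(grad_out) -> grad_in``; trainable layers also accumulate parameter
gradients so the toy zoo can be briefly trained with plain SGD.  All layers
operate on a leading batch axis and are deterministic, which is what the
metamer machinery requires: gradient descent happens in *input* space, with
model weights frozen.

Shapes follow the (N, C, H, W) / (N, C, T) convention internally; conversion
from user-facing H×W×C images happens at the model boundary.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Normalize",
    "Conv2d",
    "Conv1d",
    "ReLU",
    "AvgPool2d",
    "AvgPool1d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "PowerCompress",
    "Downsample1d",
    "softmax",
    "cross_entropy_grad",
]


class Layer:
    """Base class: stateless apart from parameters and the forward cache."""

    trainable: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Normalize(Layer):
    """Per-channel (x - mean) / std, differentiable, inside the graph.

    Mirrors dataset normalization being part of the model so that synthesis
    gradients flow through it.
    """

    def __init__(self, mean, std, channel_axis: int = 1):
        self.mean = np.asarray(mean, dtype=np.float64)
        self.std = np.asarray(std, dtype=np.float64)
        if np.any(self.std <= 0):
            raise ValueError("std must be positive")
        self.channel_axis = channel_axis

    def _shaped(self, arr: np.ndarray, ndim: int) -> np.ndarray:
        if arr.ndim == 0:
            return arr
        shape = [1] * ndim
        shape[self.channel_axis] = arr.shape[0]
        return arr.reshape(shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._ndim = x.ndim
        return (x - self._shaped(self.mean, x.ndim)) / self._shaped(self.std, x.ndim)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad / self._shaped(self.std, self._ndim)


def _sliding_patches_2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C, Ho, Wo, k, k) view, no copy."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """Valid-mode 2-D convolution (cross-correlation) with bias."""

    trainable = True

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._patches = np.ascontiguousarray(
            _sliding_patches_2d(x, self.kernel, self.stride))  # (N,C,Ho,Wo,k,k)
        out = np.tensordot(self._patches, self.W, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += np.tensordot(grad, self._patches, axes=([0, 2, 3], [0, 2, 3]))
        self.gb += grad.sum(axis=(0, 2, 3))
        gx = np.zeros(self._x_shape, dtype=np.float64)
        # scatter grad * W back onto input positions
        contrib = np.tensordot(grad, self.W, axes=(1, 0))  # (N,Ho,Wo,C,k,k)
        k, s = self.kernel, self.stride
        n_out_h, n_out_w = grad.shape[2], grad.shape[3]
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + n_out_h * s:s, j:j + n_out_w * s:s] += \
                    contrib[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class Conv1d(Layer):
    """Valid-mode 1-D convolution over (N, C, T)."""

    trainable = True

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, weight: np.ndarray | None = None,
                 frozen: bool = False):
        if weight is not None:
            self.W = np.array(weight, dtype=np.float64)
            out_ch, in_ch, kernel = self.W.shape
        else:
            rng = rng or np.random.default_rng(0)
            fan_in = in_ch * kernel
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = kernel
        self.trainable = not frozen

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self._col = np.ascontiguousarray(win[:, :, ::self.stride])  # (N,C,To,k)
        out = np.tensordot(self._col, self.W, axes=([1, 3], [1, 2]))  # (N,To,O)
        return np.ascontiguousarray(out.transpose(0, 2, 1)) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.trainable:
            self.gW += np.tensordot(grad, self._col, axes=([0, 2], [0, 2]))
            self.gb += grad.sum(axis=(0, 2))
        gx = np.zeros(self._x_shape, dtype=np.float64)
        contrib = np.tensordot(grad, self.W, axes=(1, 0))  # (N,To,C,k)
        s, k = self.stride, self.kernel
        n_out = grad.shape[2]
        for j in range(k):
            gx[:, :, j:j + n_out * s:s] += contrib[:, :, :, j].transpose(0, 2, 1)
        return gx

    def params(self):
        return [self.W, self.b] if self.trainable else []

    def grads(self):
        return [self.gW, self.gb] if self.trainable else []


class SharedKernelConv1d(Layer):
    """Depthwise 1-D convolution applying one fixed kernel to every channel
    (the envelope lowpass of the auditory front end)."""

    def __init__(self, kernel: np.ndarray):
        self.kernel = np.asarray(kernel, dtype=np.float64)
        self.k = self.kernel.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        n_out = x.shape[2] - self.k + 1
        out = np.zeros(x.shape[:2] + (n_out,))
        for j in range(self.k):  # slice-accumulate: no im2col copy needed
            out += x[:, :, j:j + n_out] * self.kernel[j]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._x_shape)
        n_out = grad.shape[2]
        for j in range(self.k):
            gx[:, :, j:j + n_out] += grad * self.kernel[j]
        return gx


class ReLU(Layer):
    """Rectifier.  ``override`` makes backward the identity — used only while
    synthesizing a metamer matched at this rectifier's output, where zero
    initial activations would otherwise kill the gradient."""

    def __init__(self):
        self.override = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.override:
            return grad
        return grad * self._mask


class AvgPool2d(Layer):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"pool size {k} does not divide spatial dims {(h, w)}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.k
        g = grad[:, :, :, None, :, None] / (k * k)
        return np.broadcast_to(g, (n, c, h // k, k, w // k, k)).reshape(n, c, h, w)


class AvgPool1d(Layer):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        k = self.k
        t_trim = (t // k) * k
        self._in_shape = x.shape
        self._t_trim = t_trim
        return x[:, :, :t_trim].reshape(n, c, t_trim // k, k).mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, t = self._in_shape
        k = self.k
        gx = np.zeros(self._in_shape)
        g = grad[:, :, :, None] / k
        gx[:, :, :self._t_trim] = np.broadcast_to(
            g, (n, c, self._t_trim // k, k)).reshape(n, c, self._t_trim)
        return gx


class GlobalAvgPool(Layer):
    """Mean over all trailing spatial/temporal axes -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        axes = tuple(range(2, x.ndim))
        self._n_avg = int(np.prod([x.shape[a] for a in axes])) if axes else 1
        return x.mean(axis=axes) if axes else x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.reshape(grad.shape + (1,) * (len(self._in_shape) - 2)) / self._n_avg
        return np.broadcast_to(g, self._in_shape).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class PowerCompress(Layer):
    """y = (x + eps)^p on non-negative input; the compressive nonlinearity of
    the auditory front end (p = 0.3 by default)."""

    def __init__(self, p: float = 0.3, eps: float = 1e-8):
        self.p = p
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xe = np.maximum(x, 0.0) + self.eps
        self._pos = x > 0
        return self._xe ** self.p

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.p * self._xe ** (self.p - 1.0) * self._pos


class Downsample1d(Layer):
    def __init__(self, stride: int):
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x[:, :, ::self.stride].copy()

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape)
        gx[:, :, ::self.stride] = grad
        return gx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n
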