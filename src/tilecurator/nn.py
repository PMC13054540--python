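"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the convolutional autoencoder needs — strided
convolution, transposed convolution, batch normalization, LeakyReLU,
sigmoid — plus an Adam optimizer. Arrays are channels-first ``(B, C, H, W)``
float32 throughout. Each layer caches what its backward pass needs on
``forward(..., training=True)``; gradients accumulate into ``layer.grads``.

This is deliberately small and CPU-oriented: convolutions are evaluated as
einsums over strided sliding-window views, and transposed convolutions are
reduced to ordinary convolutions of a zero-stuffed input, so the whole stack
is verifiable by finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterless layers need only forward/backward."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _conv_forward(xp: np.ndarray, weight: np.ndarray, stride: int) -> np.ndarray:
    """Valid convolution of a pre-padded input. xp: (B,C,Hp,Wp), weight: (F,C,k,k)."""
    k = weight.shape[2]
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.einsum("bcxykl,fckl->bfxy", win, weight, optimize=True)


def _conv_backward(
    xp: np.ndarray, weight: np.ndarray, stride: int, grad_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of _conv_forward w.r.t. the padded input and the weight."""
    k = weight.shape[2]
    ho, wo = grad_out.shape[2:]
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    d_weight = np.einsum("bfxy,bcxykl->fckl", grad_out, win, optimize=True)
    d_xp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            d_xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += np.einsum(
                "bfxy,fc->bcxy", grad_out, weight[:, :, i, j], optimize=True
            )
    return d_xp, d_weight


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_channels * kernel * kernel
        # He initialization suits the LeakyReLU activations used downstream
        w = rng.standard_normal((out_channels, in_channels, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._xp: np.ndarray | None = None

    def forward(self, x, training=False):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if training:
            self._xp = xp
        out = _conv_forward(xp, self.params["w"], self.stride)
        return out + self.params["b"][None, :, None, None]

    def backward(self, grad):
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        d_xp, d_w = _conv_backward(self._xp, self.params["w"], self.stride, grad)
        self.grads["w"] += d_w
        p = self.padding
        return d_xp[:, :, p : d_xp.shape[2] - p, p : d_xp.shape[3] - p] if p else d_xp


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution via zero-stuffing.

    Output size is ``(H - 1) * stride + kernel - 2 * padding + output_padding``;
    with kernel 3, padding 1, stride 2, output_padding 1 this exactly doubles
    the spatial size, mirroring a stride-2 Conv2d.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, output_padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        self.output_padding = output_padding
        if output_padding >= stride:
            raise ValueError("output_padding must be smaller than stride")
        fan_in = in_channels * kernel * kernel
        w = rng.standard_normal((out_channels, in_channels, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._xs_padded: np.ndarray | None = None

    def _stuff(self, x):
        b, c, h, w = x.shape
        s, op = self.stride, self.output_padding
        pad = self.kernel - 1 - self.padding
        hs, ws = (h - 1) * s + 1 + op, (w - 1) * s + 1 + op
        xs = np.zeros((b, c, hs + 2 * pad, ws + 2 * pad), dtype=x.dtype)
        xs[:, :, pad : pad + hs : s, pad : pad + ws : s] = x
        return xs

    def forward(self, x, training=False):
        xs = self._stuff(x)
        if training:
            self._xs_padded = xs
            self._in_shape = x.shape
        out = _conv_forward(xs, self.params["w"], stride=1)
        return out + self.params["b"][None, :, None, None]

    def backward(self, grad):
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        d_xs, d_w = _conv_backward(self._xs_padded, self.params["w"], 1, grad)
        self.grads["w"] += d_w
        _, _, h, w = self._in_shape
        s = self.stride
        pad = self.kernel - 1 - self.padding
        return d_xs[:, :, pad : pad + (h - 1) * s + 1 : s, pad : pad + (w - 1) * s + 1 : s]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
            self._xhat, self._inv_std = xhat, inv_std
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv_std[None, :, None, None]
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._xhat, self._inv_std
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        d_xhat = grad * g
        sum_d = d_xhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (d_xhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv_std[None, :, None, None] * (d_xhat - sum_d / n - xhat * sum_dx / n)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.slope = negative_slope

    def forward(self, x, training=False):
        if training:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for layer in self.layers:
            for k in layer.grads:
                layer.grads[k][...] = 0.0

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{prefix}{i}.{k}"] = v
            if isinstance(layer, BatchNorm2d):
                out[f"{prefix}{i}.running_mean"] = layer.running_mean
                out[f"{prefix}{i}.running_var"] = layer.running_var
        return out

    def load_named_params(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{prefix}{i}.{k}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{prefix}{i}.running_mean"]
                layer.running_var[...] = state[f"{prefix}{i}.running_var"]


class Adam:
    """Adam optimizer over the trainable params of one or more Sequentials."""

    def __init__(self, modules: list[Sequential], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._slots = []  # (param, grad, m, v)
        for module in modules:
            for layer in module.layers:
                for k in layer.params:
                    p = layer.params[k]
                    self._slots.append((p, layer.grads[k], np.zeros_like(p), np.zeros_like(p)))

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in self._slots:
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
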