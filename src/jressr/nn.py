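"""Minimal CPU neural-network layers with explicit backpropagation.

Implements exactly what the super-resolution generator and patch
discriminator need: 3x3 same-padded convolutions (via sliding windows and
einsum), leaky ReLU, 2x nearest-neighbour upsampling and 2x average
pooling, plus an Adam optimizer.  Every layer caches its forward inputs and
returns the input gradient from ``backward``; parameter gradients
accumulate on the layer.  Gradients are validated against finite
differences in the test suite.

Tensors are NCHW float64 internally (float32 in/out at the model surface);
batch sizes and feature counts here are small enough that float64 keeps
the training numerics simple.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "LeakyReLU", "UpsampleNearest2x", "UpsampleBilinear2x",
           "AvgPool2x", "Sequential", "Adam"]


class Layer:
    """Base class: forward caches, backward returns d(loss)/d(input)."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 convolution with zero 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, init_scale: float = 1.0,
                 bias: bool = True):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        # He-style init scaled for leaky ReLU chains; init_scale lets the
        # final layer of a residual branch start near zero.
        std = init_scale * np.sqrt(2.0 / fan_in)
        self.weight = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel))
        self.has_bias = bias
        self.bias = np.zeros(out_ch)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self.kernel = kernel
        self._cache_windows: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (N, C, H, W, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        self._cache_windows = win
        self._in_shape = x.shape
        out = np.einsum("nchwij,ocij->nohw", win, self.weight, optimize=True)
        if self.has_bias:
            out += self.bias[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        win = self._cache_windows
        self.d_weight += np.einsum("nchwij,nohw->ocij", win, grad, optimize=True)
        if self.has_bias:
            self.d_bias += grad.sum(axis=(0, 2, 3))
        # dx = full correlation of grad with the flipped kernel
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
        w_flip = self.weight[:, :, ::-1, ::-1]
        dx = np.einsum("nohwij,ocij->nchw", gwin, w_flip, optimize=True)
        return dx

    def parameters(self):
        return [self.weight, self.bias] if self.has_bias else [self.weight]

    def gradients(self):
        return [self.d_weight, self.d_bias] if self.has_bias else [self.d_weight]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class UpsampleNearest2x(Layer):
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _bilin_up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, -1)
    xm = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    xp = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.25 * xm + 0.75 * x
    odd = 0.75 * x + 0.25 * xp
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = even
    out[..., 1::2] = odd
    return np.moveaxis(out, -1, axis)


def _bilin_up_axis_T(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, axis)


class UpsampleBilinear2x(Layer):
    """Separable x2 bilinear upsampling (half-pixel centres, edges clamped).

    Each output sample mixes its nearest source pixel (weight 0.75) with
    the next-nearest (0.25); mirror-symmetric, so it commutes with axis
    flips.  Backward is the exact transpose.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        return _bilin_up_axis(_bilin_up_axis(x, 2), 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return _bilin_up_axis_T(_bilin_up_axis_T(grad, 3), 2)


class AvgPool2x(Layer):
    """2x2 average pooling; backward spreads each gradient over its block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.repeat(2, axis=2).repeat(2, axis=3) / 4.0


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
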