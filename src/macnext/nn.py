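"""Minimal NumPy neural-network core: layers with explicit forward/backward.

All tensors are NCHW ``float32`` (``float64`` inputs are honoured, which the
oracle tests use). Convolutions are evaluated by im2col plus a batched GEMM
over channel groups, so a grouped convolution with many small groups still
runs as a single ``np.matmul`` call.

Padding follows the "same/ceil" convention: a stride-``s`` convolution emits
``ceil(in / s)`` pixels per side, padding asymmetrically (extra pixel on the
bottom/right) when the required total padding is odd. This is what maps
224 -> 112 -> 56 in the stem and 56 -> 28 -> 14 -> 7 in the downsampling
stages.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "GELU",
    "ReLU",
    "Linear",
    "GlobalAvgPool",
    "softmax",
    "gelu",
    "same_pad",
    "conv_out_side",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    # d/dx [x * Phi(x)] = Phi(x) + x * phi(x)
    phi = _INV_SQRT2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * phi


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def conv_out_side(side: int, stride: int) -> int:
    """Output side length under the same/ceil padding convention."""
    return -(-side // stride)


def same_pad(side: int, k: int, stride: int) -> tuple[int, int]:
    """(before, after) padding for one spatial axis."""
    out = conv_out_side(side, stride)
    total = max((out - 1) * stride + k - side, 0)
    before = total // 2
    return before, total - before


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return int(self.data.size)


class Layer:
    """Base class; subclasses implement forward/backward and list parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state (e.g. BN running statistics)."""
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> columns (N, C*k*k, L) with L = Ho*Wo, plus geometry."""
    n, c, h, w = x.shape
    pt, pb = same_pad(h, k, stride)
    pl, pr = same_pad(w, k, stride)
    if pt or pb or pl or pr:
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    else:
        xp = x
    ho, wo = conv_out_side(h, stride), conv_out_side(w, stride)
    # (N, C, Ho, Wo, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    geom = (x.shape, xp.shape, (pt, pl), ho, wo)
    return np.ascontiguousarray(cols), geom


def _col2im(dcols: np.ndarray, k: int, stride: int, geom: tuple) -> np.ndarray:
    (n, c, h, w), xp_shape, (pt, pl), ho, wo = geom
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride] += d6[
                :, :, ki, kj
            ]
    return dxp[:, :, pt : pt + h, pl : pl + w]


class Conv2d(Layer):
    """2-D convolution with channel groups, same/ceil padding, optional bias.

    ``weight`` has shape (C_out, C_in // groups, k, k); with ``groups == 1``
    this is a dense convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        groups: int = 1,
        bias: bool = False,
        name: str = "conv",
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"{name}: groups={groups} must divide in_channels={in_channels} "
                f"and out_channels={out_channels}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.groups = groups
        self.name = name
        cg = in_channels // groups
        fan_in = cg * kernel_size * kernel_size
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, cg, kernel_size, kernel_size))
        self.weight = Parameter(f"{name}.weight", w.astype(np.float32))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, np.float32)) if bias else None
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        n = x.shape[0]
        g, k = self.groups, self.k
        cg = self.in_channels // g
        og = self.out_channels // g
        cols, geom = _im2col(x, k, self.stride)  # (N, C*k*k, L)
        ho, wo = geom[3], geom[4]
        colsg = cols.reshape(n, g, cg * k * k, ho * wo)
        wm = self.weight.data.astype(x.dtype).reshape(g, og, cg * k * k)
        out = np.matmul(wm, colsg)  # (N, g, og, L)
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out = out + self.bias.data.astype(x.dtype)[None, :, None, None]
        if training:
            self._cache = (colsg, geom)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        colsg, geom = self._cache
        n = grad.shape[0]
        g, k = self.groups, self.k
        cg = self.in_channels // g
        og = self.out_channels // g
        ho, wo = geom[3], geom[4]
        gg = grad.reshape(n, g, og, ho * wo)
        # dW: sum over batch of grad @ cols^T
        dw = np.einsum("ngol,ngcl->goc", gg, colsg, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3)).astype(np.float32)
        wm = self.weight.data.astype(grad.dtype).reshape(g, og, cg * k * k)
        dcols = np.matmul(wm.transpose(0, 2, 1), gg)  # (N, g, cg*k*k, L)
        dcols = dcols.reshape(n, self.in_channels * k * k, ho * wo)
        return _col2im(dcols, k, self.stride, geom)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, np.float32))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.running_mean": self.running_mean, f"{self.name}.running_var": self.running_var}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {x.shape[1]}")
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data.astype(x.dtype)[None, :, None, None] * xhat
        out = out + self.beta.data.astype(x.dtype)[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma.astype(np.float32)
        self.beta.grad += dbeta.astype(np.float32)
        g = self.gamma.data.astype(grad.dtype)
        dxhat = grad * g[None, :, None, None]
        dx = (
            dxhat
            - dbeta[None, :, None, None] * g[None, :, None, None] / m
            - xhat * (dgamma[None, :, None, None] * g[None, :, None, None] / m)
        ) * inv_std[None, :, None, None]
        return dx


class GELU(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._cache = x
        return gelu(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * _gelu_grad(self._cache)


class ReLU(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._cache = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._cache


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    """Fully connected layer with bias; fan-based uniform initialization."""

    def __init__(self, in_features: int, out_features: int, name: str = "fc", rng: np.random.Generator | None = None):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / (in_features + out_features))
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.weight = Parameter(f"{name}.weight", w.astype(np.float32))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features, np.float32))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(f"{self.name}: expected {self.in_features} features, got {x.shape[1]}")
        if training:
            self._cache = x
        return x @ self.weight.data.astype(x.dtype).T + self.bias.data.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += (grad.T @ x).astype(np.float32)
        self.bias.grad += grad.sum(axis=0).astype(np.float32)
        return grad @ self.weight.data.astype(grad.dtype)
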