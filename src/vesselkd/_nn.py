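"""Minimal CNN building blocks on numpy arrays.

Layers operate on (N, C, H, W) arrays and implement explicit forward/backward
passes; gradients accumulate into :class:`Param` objects and are consumed by
:class:`Adam`.  Everything is deterministic given the initialisation RNG, and
no layer keeps running statistics, so inference equals the training-mode
forward pass.  Correctness of every backward pass is pinned by a central
difference gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "InstanceNorm",
    "ReLU",
    "Sequential",
    "UpsampleNearest2x",
    "conv_block",
    "Adam",
]


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = True


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _windows(xp: np.ndarray, k: int, stride: int, dilation: int) -> np.ndarray:
    """View of all k×k receptive fields: (N, C, Ho, Wo, k, k)."""
    k_eff = dilation * (k - 1) + 1
    w = sliding_window_view(xp, (k_eff, k_eff), axis=(2, 3))
    return w[:, :, ::stride, ::stride, ::dilation, ::dilation]


class Conv2d(Module):
    """2-D convolution with 'same' padding (odd kernels), stride and dilation.

    Weight layout (out, in, k, k); He-normal init from the supplied RNG.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if k % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.w = Param((rng.standard_normal((out_ch, in_ch, k, k)) * std).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self.k, self.stride, self.dilation = k, stride, dilation
        self.pad = dilation * (k - 1) // 2
        self._xp: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _windows(xp, self.k, self.stride, self.dilation)
        y = np.tensordot(win, self.w.value, axes=[(1, 4, 5), (1, 2, 3)])
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self.b.value[None, :, None, None]
        self._xp, self._in_shape = xp, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (n, c, h, w) = self._xp, self._in_shape
        win = _windows(xp, self.k, self.stride, self.dilation)
        self.w.grad += np.tensordot(dy, win, axes=[(0, 2, 3), (0, 2, 3)])
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        ho, wo = dy.shape[2], dy.shape[3]
        s, d = self.stride, self.dilation
        for i in range(self.k):
            for j in range(self.k):
                t = np.tensordot(dy, self.w.value[:, :, i, j], axes=(1, 0))
                dxp[:, :, i * d : i * d + s * ho : s, j * d : j * d + s * wo : s] += (
                    t.transpose(0, 3, 1, 2)
                )
        p = self.pad
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over space with affine params.

    No running statistics are kept, so the layer behaves identically at
    training and inference time (this keeps whole-run determinism trivial).
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gain = Param(np.ones(channels, dtype=dtype))
        self.bias = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gain, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gain.value[None, :, None, None] * xhat + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gain.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        g = dy * self.gain.value[None, :, None, None]
        m1 = g.mean(axis=(2, 3), keepdims=True)
        m2 = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (g - m1 - xhat * m2)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UpsampleNearest2x(Module):
    """Nearest-neighbour ×2 spatial upsampling (parameter-free)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def conv_block(
    in_ch: int,
    out_ch: int,
    *,
    k: int = 3,
    stride: int = 1,
    dilation: int = 1,
    norm: bool = True,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> Sequential:
    """Conv → InstanceNorm → ReLU (the norm can be dropped for heads)."""
    layers: list[Module] = [Conv2d(in_ch, out_ch, k, stride, dilation, rng=rng, dtype=dtype)]
    if norm:
        layers.append(InstanceNorm(out_ch, dtype=dtype))
    layers.append(ReLU())
    return Sequential(*layers)


class Adam(Module):
    """Adam with bias correction; frozen params are skipped entirely."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
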