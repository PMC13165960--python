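"""Minimal seeded forward-pass building blocks (linear, conv, norm, softmax).

These primitives back the color-prior modules. They are inference-only:
parameters are drawn once from a seeded fan-in uniform distribution (the
standard Kaiming-uniform scheme) and applied deterministically, which is all
the architectural contracts here require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "silu",
    "sigmoid",
    "softmax",
]


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Affine map ``y = x W^T + b`` with seeded fan-in uniform init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = _fan_in_uniform(rng, (out_features, in_features), in_features)
        self.bias = _fan_in_uniform(rng, (out_features,), in_features) if bias else np.zeros(out_features)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected last dimension {self.in_features}, got {x.shape[-1]}"
            )
        return x @ self.weight.T + self.bias


class Conv2d:
    """2-D convolution over a ``(C, H, W)`` array, stride/pad per axis-symmetric ints.

    Implemented with a strided sliding-window view plus one tensordot; fast
    enough for the forward-only stacks used here.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _fan_in_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in
        )
        self.bias = _fan_in_uniform(rng, (out_channels,), fan_in)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected ({self.in_channels}, H, W) input, got shape {x.shape}"
            )
        p, k, s = self.padding, self.kernel_size, self.stride
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (C, Ho, Wo, k, k)
        out = np.tensordot(win, self.weight, axes=([0, 3, 4], [1, 2, 3]))
        return np.moveaxis(out, -1, 0) + self.bias[:, None, None]


class BatchNorm2d:
    """Inference-mode batch norm: fixed running stats (0 mean, unit var) with
    learnable-shaped scale/shift, initialized to the identity transform."""

    def __init__(self, num_features: int):
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = 1e-5

    def __call__(self, x: np.ndarray) -> np.ndarray:
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        shift = self.beta - self.running_mean * scale
        return x * scale[:, None, None] + shift[:, None, None]
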