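"""Scalar/array nonlinearities and pooling primitives.

The swish family gates its input by a logistic sigmoid, ``x * sigmoid(beta*x)``.
swish6 additionally clips the output at 6 for inputs at or above 6, in the
spirit of ReLU6's hard cap: the cap bounds activations so that a single large
pre-activation cannot blow up downstream statistics.  The clip is piecewise by
default (output jumps to exactly 6 at the threshold); a continuous
``min(swish(x), 6)`` form is available via ``mode="min"``.

Pooling here is the non-overlapping stride-2 case only: each output pixel
summarises one 2x2 window (max or mean).  Odd spatial dimensions are rejected
rather than padded, since no padding convention is defined for these
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationParams",
    "swish",
    "swish_grad",
    "swish6",
    "swish6_grad",
    "softmax",
    "max_pool_2x2",
    "avg_pool_2x2",
    "global_avg_pool",
    "CLASS_COUNT",
]

#: number of disease categories in the classification head
CLASS_COUNT = 7


@dataclass
class ActivationParams:
    """Configuration of the swish gate.

    Parameters
    ----------
    beta : float
        Slope of the sigmoid gate (dimensionless).  ``beta -> inf`` recovers
        ReLU, ``beta = 0`` gives ``x/2``.  Must be positive here.
    trainable : bool
        Whether ``beta`` is a learnable parameter.  When False (default),
        ``beta`` is a constant across calls.
    """

    beta: float = 1.0
    trainable: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be positive and finite, got {self.beta}")


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # evaluate on the non-overflowing branch of exp for each sign
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def swish(x: np.ndarray, params: ActivationParams | None = None) -> np.ndarray:
    """Elementwise ``x * sigmoid(beta * x)``."""
    params = params or ActivationParams()
    x = _check_finite(x, "swish input")
    return x * _sigmoid(params.beta * x)


def swish_grad(x: np.ndarray, params: ActivationParams | None = None) -> np.ndarray:
    """Derivative of :func:`swish`: ``s + beta*x*s*(1-s)`` with ``s = sigmoid(beta*x)``."""
    params = params or ActivationParams()
    x = _check_finite(x, "swish input")
    s = _sigmoid(params.beta * x)
    return s + params.beta * x * s * (1.0 - s)


def swish6(
    x: np.ndarray,
    params: ActivationParams | None = None,
    mode: str = "clip",
) -> np.ndarray:
    """swish with its output fixed at 6 once the input reaches 6.

    ``mode="clip"`` (default) is the literal piecewise definition: swish(x)
    for x < 6, exactly 6 for x >= 6.  Because swish(6) = 6*sigmoid(6*beta) < 6,
    this form has a jump discontinuity at x = 6 (of height ``6 - 6*sigmoid(6
    beta)``, about 0.0148 for beta = 1).  ``mode="min"`` is the continuous
    alternative ``min(swish(x), 6)``.  The input x = 6 itself is assigned to
    the cap branch, which makes the function total.
    """
    params = params or ActivationParams()
    x = _check_finite(x, "swish6 input")
    y = x * _sigmoid(params.beta * x)
    if mode == "clip":
        return np.where(x >= 6.0, 6.0, y)
    if mode == "min":
        return np.minimum(y, 6.0)
    raise ValueError(f"unknown swish6 mode {mode!r}")


def swish6_grad(
    x: np.ndarray,
    params: ActivationParams | None = None,
    mode: str = "clip",
) -> np.ndarray:
    """Derivative of :func:`swish6`; zero on the capped branch."""
    params = params or ActivationParams()
    g = swish_grad(x, params)
    if mode == "clip":
        return np.where(np.asarray(x, dtype=float) >= 6.0, 0.0, g)
    if mode == "min":
        y = swish(x, params)
        return np.where(y >= 6.0, 0.0, g)
    raise ValueError(f"unknown swish6 mode {mode!r}")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Probability vector ``exp(z_i) / sum_j exp(z_j)`` along ``axis``.

    Computed with the max-shift trick: subtracting ``max(z)`` from every logit
    leaves the ratio unchanged but keeps the exponentials in range.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax input must be non-empty")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input contains non-finite values")
    shifted = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def _pool_2x2(grid: np.ndarray, reducer) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {grid.shape}")
    h, w = grid.shape
    if h % 2 or w % 2:
        raise ValueError(
            f"pooling requires even spatial dimensions, got {h}x{w} "
            "(no padding convention is defined)"
        )
    blocks = grid.reshape(h // 2, 2, w // 2, 2)
    return reducer(blocks, axis=(1, 3))


def max_pool_2x2(grid: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling with stride 2; halves each dimension."""
    return _pool_2x2(grid, np.max)


def avg_pool_2x2(grid: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 average pooling with stride 2; halves each dimension."""
    return _pool_2x2(grid, np.mean)


def global_avg_pool(features: np.ndarray) -> np.ndarray:
    """Collapse a C x H x W feature stack to its per-channel spatial means."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError(f"expected a rank-3 CxHxW array, got shape {features.shape}")
    if features.shape[1] == 0 or features.shape[2] == 0:
        raise ValueError("global average pooling needs a non-empty spatial extent")
    return features.mean(axis=(1, 2))
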