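"""Minimal NumPy neural-network layers with explicit backward passes.

Convolutions are evaluated by lowering each input window to a column
(im2col) and calling a single BLAS matmul; depthwise convolutions use a
strided-window einsum instead, which avoids materialising the full column
matrix per channel.  Every layer caches what its backward pass needs during
``forward(training=True)`` and releases it on the next call.

All arrays are float32 NCHW.  Determinism: given the same seed and the same
BLAS backend, forward, backward and the optimizer are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .activations import ActivationParams, swish6, swish6_grad

DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient and optimizer slot."""

    __slots__ = ("value", "grad", "name", "weight_decay")

    def __init__(self, value: np.ndarray, name: str = "", weight_decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name
        # BN scale/shift and biases are conventionally excluded from L2 decay
        self.weight_decay = weight_decay


class Layer:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def _windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Strided view (N, C, OH, OW, k, k) over a padded NCHW array."""
    n, c, h, w = xp.shape
    oh = (h - kernel) // stride + 1
    ow = (w - kernel) // stride + 1
    sn, sc, sh, sw = xp.strides
    return as_strided(
        xp,
        shape=(n, c, oh, ow, kernel, kernel),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


class Conv2d(Layer):
    """2-D convolution (cross-correlation), dense or depthwise.

    ``groups`` must be 1 (dense) or ``in_channels`` (depthwise); intermediate
    group counts are not needed by this architecture.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 (dense) or in_channels (depthwise)")
        if groups > 1 and out_channels != in_channels:
            raise ValueError("depthwise conv requires out_channels == in_channels")
        self.cin, self.cout = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.depthwise = groups == in_channels and groups > 1
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * (1 if self.depthwise else in_channels)
        std = np.sqrt(2.0 / fan_in)
        wshape = (
            (out_channels, kernel, kernel)
            if self.depthwise
            else (out_channels, in_channels, kernel, kernel)
        )
        self.weight = Parameter(rng.normal(0.0, std, wshape), name=f"{name}.weight")
        self.bias = (
            Parameter(np.zeros(out_channels), name=f"{name}.bias", weight_decay=False)
            if bias
            else None
        )
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == 0:
            return x
        p = self.padding
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(
                f"expected (N,{self.cin},H,W) input, got shape {tuple(x.shape)}"
            )
        x = np.ascontiguousarray(x, dtype=DTYPE)
        xp = self._pad(x)
        win = _windows(xp, self.kernel, self.stride)
        n, _, oh, ow, _, _ = win.shape
        if self.depthwise:
            out = np.einsum("nchwuv,cuv->nchw", win, self.weight.value, optimize=True)
            cols = None
        else:
            # (N*OH*OW, C*k*k) @ (C*k*k, cout)
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * oh * ow, -1
            )
            wmat = self.weight.value.reshape(self.cout, -1)
            out = (cols @ wmat.T).reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
            out = np.ascontiguousarray(out)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        if self.training:
            self._cache = (xp.shape, win if self.depthwise else None, cols, (n, oh, ow))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp_shape, win, cols, (n, oh, ow) = self._cache
        self._cache = None
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        k, s = self.kernel, self.stride
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        if self.depthwise:
            self.weight.grad += np.einsum(
                "nchwuv,nchw->cuv", win, dout, optimize=True
            )
            w = self.weight.value
            for u in range(k):
                for v in range(k):
                    dxp[:, :, u : u + s * oh : s, v : v + s * ow : s] += (
                        dout * w[None, :, u, v, None, None]
                    )
        else:
            dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
            self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
            dcols = (dmat @ self.weight.value.reshape(self.cout, -1)).reshape(
                n, oh, ow, self.cin, k, k
            )
            dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # N,C,k,k,OH,OW
            for u in range(k):
                for v in range(k):
                    dxp[:, :, u : u + s * oh : s, v : v + s * ow : s] += dcols[
                        :, :, u, v
                    ]
        if self.padding:
            p = self.padding
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale and shift.

    Training mode normalizes by batch statistics and maintains exponential
    running estimates; eval mode uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma",
                               weight_decay=False)
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta",
                              weight_decay=False)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat
        out += self.beta.value[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv, x.shape)
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        # standard batch-norm backward through the batch statistics
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_eff
        ) * inv[None, :, None, None]
        return dx.astype(DTYPE)


class Swish6(Layer):
    """Elementwise swish6 activation layer (fixed, non-trainable beta)."""

    def __init__(self, beta: float = 1.0, mode: str = "clip"):
        self.params = ActivationParams(beta=beta)
        self.mode = mode
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        return swish6(x, self.params, mode=self.mode).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = swish6_grad(self._x, self.params, mode=self.mode).astype(DTYPE)
        self._x = None
        return dout * g


class GlobalAvgPool2d(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("global average pooling needs a non-empty spatial extent")
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_features, in_features)), name=f"{name}.weight"
        )
        self.bias = (
            Parameter(np.zeros(out_features), name=f"{name}.bias", weight_decay=False)
            if bias
            else None
        )
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if self.training:
            self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        self.weight.grad += dout.T @ self._x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.training = flag
            if hasattr(layer, "set_training"):
                layer.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Residual(Layer):
    """``out = body(x) + shortcut(x)``; identity shortcut when none given."""

    def __init__(self, body: Sequential, shortcut: Layer | None = None):
        self.body = body
        self.shortcut = shortcut

    def parameters(self) -> list[Parameter]:
        params = self.body.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.body.set_training(flag)
        if self.shortcut is not None:
            self.shortcut.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.body.forward(x)
        skip = x if self.shortcut is None else self.shortcut.forward(x)
        if main.shape != skip.shape:
            raise ValueError(
                f"additive skip requires matching shapes, got {main.shape} "
                f"vs {skip.shape}"
            )
        return main + skip

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.body.backward(dout)
        if self.shortcut is None:
            return dx + dout
        return dx + self.shortcut.backward(dout)
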