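"""Declarative layer specifications and builders for the ED-Net classifier.

The network is a stack of seven blocks: a strided 7x7 stem (ED_Conv), two
bottleneck residual blocks (ED_Resnet), three channel-doubling multi-kernel
blocks (ED_Xception) and a global-pool + linear head (ED_Linear):

    ED_Conv(3->64, stride 2)
    ED_Resnet(64)         # 1x1 down to 32, depthwise, 1x1 back up, +skip
    ED_Xception(64->128)  # 3x3, 5x5, 7x7 same-channel convs, then 1x1 doubling
    ED_Xception(128->256)
    ED_Resnet(256)
    ED_Xception(256->512)
    ED_Linear(512->num_classes)

Every convolution is immediately followed by batch normalization (so conv
biases are disabled), and rows marked with swish6 get the clipped-swish
nonlinearity.  Only the stem downsamples; all other blocks preserve the
spatial extent, so a 224x224 input stays at 112x112 until the global pool.

Two structural readings are exposed as flags: ``separable_xception`` replaces
each dense k x k ED_Xception convolution with a depthwise k x k plus a
pointwise 1x1 (the Xception idiom), and ``xception_projection_skip`` adds a
1x1-projected additive shortcut across each ED_Xception block.  The defaults
are frozen by the complexity-module interpretation sweep.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import layers as L
from .activations import softmax

VALID_KINDS = {
    "conv", "depthwise_conv", "norm", "activation", "pool", "global_pool", "linear",
}


@dataclass(frozen=True)
class LayerSpec:
    """One primitive layer of the network, in Table-row granularity.

    ``has_swish6`` marks convolution rows whose structure-table row carries
    the swish6 activation (the activation itself also appears as a separate
    ``activation`` spec so counting and instantiation stay 1:1).
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    has_swish6: bool = False

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "depthwise_conv" and self.in_channels != self.out_channels:
            raise ValueError("depthwise_conv requires in_channels == out_channels")
        if self.kind in ("conv", "depthwise_conv") and self.kernel not in (1, 3, 5, 7):
            raise ValueError(f"kernel must be one of 1/3/5/7, got {self.kernel}")
        if self.kind == "pool" and self.kernel < 2:
            raise ValueError("pool layers need an explicit kernel (e.g. 2)")


@dataclass(frozen=True)
class BlockSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    skip: str = "none"  # none | additive | concat
    skip_projection: tuple[LayerSpec, ...] = ()

    @property
    def in_channels(self) -> int:
        for s in self.layers:
            if s.in_channels:
                return s.in_channels
        raise ValueError(f"block {self.name} has no channelled layer")

    @property
    def out_channels(self) -> int:
        for s in reversed(self.layers):
            if s.out_channels:
                return s.out_channels
        raise ValueError(f"block {self.name} has no channelled layer")


def _conv_bn(cin, cout, k, stride=1, swish=False) -> list[LayerSpec]:
    pad = (k - 1) // 2
    specs = [
        LayerSpec("conv", cin, cout, k, stride, pad, has_swish6=swish),
        LayerSpec("norm", cout, cout),
    ]
    if swish:
        specs.append(LayerSpec("activation", cout, cout))
    return specs


def _sep_conv_bn(cin, cout, k, swish=False) -> list[LayerSpec]:
    """Depthwise k x k + pointwise 1x1, each followed by BN (Xception idiom)."""
    specs = [
        LayerSpec("depthwise_conv", cin, cin, k, 1, (k - 1) // 2),
        LayerSpec("norm", cin, cin),
        LayerSpec("conv", cin, cout, 1, 1, 0, has_swish6=swish),
        LayerSpec("norm", cout, cout),
    ]
    if swish:
        specs.append(LayerSpec("activation", cout, cout))
    return specs


def build_ed_conv(out_channels: int = 64) -> BlockSpec:
    """Stem: 7x7 stride-2 convolution 3 -> 64 with BN and swish6."""
    return BlockSpec("ED_Conv", tuple(_conv_bn(3, out_channels, 7, stride=2,
                                               swish=True)))


def build_ed_resnet_block(
    cin: int, dw_kernel: int = 3, skip: str = "additive"
) -> BlockSpec:
    """Bottleneck residual block: 1x1 halving, depthwise, 1x1 restoring.

    The shortcut is additive by default (the only form under which the
    structure table's 64-in/64-out channel arithmetic balances); ``skip=
    "concat"`` instead concatenates input and output channels and reconciles
    with an extra 1x1 convolution back to ``cin``.
    """
    if cin % 2:
        raise ValueError(f"ED_Resnet input channels must be even, got {cin}")
    if skip not in ("additive", "concat"):
        raise ValueError(f"unknown skip mode {skip!r}")
    mid = cin // 2
    specs = (
        _conv_bn(cin, mid, 1)
        + [
            LayerSpec("depthwise_conv", mid, mid, dw_kernel, 1, (dw_kernel - 1) // 2),
            LayerSpec("norm", mid, mid),
        ]
        + _conv_bn(mid, cin, 1, swish=True)
    )
    proj = ()
    if skip == "concat":
        proj = tuple(_conv_bn(2 * cin, cin, 1))
    return BlockSpec(f"ED_Resnet({cin})", tuple(specs), skip=skip,
                     skip_projection=proj)


def build_ed_xception_block(
    cin: int, separable: bool = True, projection_skip: bool = False
) -> BlockSpec:
    """Multi-kernel block: 3x3, 5x5, 7x7 same-channel convolutions in
    sequence, then a channel-doubling 1x1 with swish6."""
    make = _sep_conv_bn if separable else _conv_bn
    specs: list[LayerSpec] = []
    for k in (3, 5, 7):
        specs += make(cin, cin, k)
    specs += _conv_bn(cin, 2 * cin, 1, swish=True)
    skip = "none"
    proj: tuple[LayerSpec, ...] = ()
    if projection_skip:
        skip = "additive"
        proj = tuple(_conv_bn(cin, 2 * cin, 1))
    return BlockSpec(f"ED_Xception({cin}->{2 * cin})", tuple(specs), skip=skip,
                     skip_projection=proj)


def build_ed_linear(cin: int = 512, num_classes: int = 7) -> BlockSpec:
    return BlockSpec(
        "ED_Linear",
        (
            LayerSpec("global_pool", cin, cin),
            LayerSpec("linear", cin, num_classes),
        ),
    )


def _scaled_width(base: int, multiplier: float) -> int:
    # keep widths even so the resnet bottleneck halving stays integral
    return max(2, int(round(base * multiplier / 2)) * 2)


@dataclass
class EDNetConfig:
    """Full declarative description of the network.

    ``width_multiplier`` scales every channel width (rounded to even), which
    is how the desk-scale training tests shrink the model without changing
    its structure.  ``separable_xception``/``xception_projection_skip``/
    ``resnet_dw_kernel`` select between structural readings; the defaults are
    the configuration frozen by the complexity interpretation sweep.
    """

    num_classes: int = 7
    input_size: int = 224
    separable_xception: bool = True
    xception_projection_skip: bool = False
    resnet_dw_kernel: int = 3
    resnet_skip: str = "additive"
    width_multiplier: float = 1.0
    swish6_mode: str = "clip"
    bn_momentum: float = 0.1
    weight_init_seed: int = 0

    def blocks(self) -> list[BlockSpec]:
        # only the stem width is free; each ED_Xception doubles it, so the
        # remaining widths follow by the chain constraint
        w0 = _scaled_width(64, self.width_multiplier)
        w = [w0, 2 * w0, 4 * w0, 8 * w0]
        return [
            build_ed_conv(w[0]),
            build_ed_resnet_block(w[0], self.resnet_dw_kernel, self.resnet_skip),
            build_ed_xception_block(w[0], self.separable_xception,
                                    self.xception_projection_skip),
            build_ed_xception_block(w[1], self.separable_xception,
                                    self.xception_projection_skip),
            build_ed_resnet_block(w[2], self.resnet_dw_kernel, self.resnet_skip),
            build_ed_xception_block(w[2], self.separable_xception,
                                    self.xception_projection_skip),
            build_ed_linear(w[3], self.num_classes),
        ]

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "EDNetConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


class ConfigError(ValueError):
    pass


def validate_chain(blocks: list[BlockSpec]) -> None:
    """Check that each block's output width feeds the next block's input."""
    for i in range(len(blocks) - 1):
        a, b = blocks[i], blocks[i + 1]
        if a.out_channels != b.in_channels:
            raise ConfigError(
                f"channel chain mismatch between {a.name} (out={a.out_channels}) "
                f"and {b.name} (in={b.in_channels})"
            )


def _instantiate(specs, rng, swish6_mode, bn_momentum=0.1) -> L.Sequential:
    built: list[L.Layer] = []
    for s in specs:
        if s.kind == "conv":
            built.append(
                L.Conv2d(s.in_channels, s.out_channels, s.kernel, s.stride,
                         s.padding, bias=False, rng=rng)
            )
        elif s.kind == "depthwise_conv":
            built.append(
                L.Conv2d(s.in_channels, s.out_channels, s.kernel, s.stride,
                         s.padding, groups=s.in_channels, bias=False, rng=rng)
            )
        elif s.kind == "norm":
            built.append(L.BatchNorm2d(s.out_channels, momentum=bn_momentum))
        elif s.kind == "activation":
            built.append(L.Swish6(mode=swish6_mode))
        elif s.kind == "global_pool":
            built.append(L.GlobalAvgPool2d())
        elif s.kind == "linear":
            built.append(L.Linear(s.in_channels, s.out_channels, bias=True, rng=rng))
    return L.Sequential(*built)


class _Concat(L.Layer):
    """Channel concatenation of body output with the block input."""

    def __init__(self, body: L.Sequential):
        self.body = body
        self._split = None

    def parameters(self):
        return self.body.parameters()

    def set_training(self, flag):
        self.body.set_training(flag)

    def forward(self, x):
        main = self.body.forward(x)
        self._split = main.shape[1]
        return np.concatenate([main, x], axis=1)

    def backward(self, dout):
        c = self._split
        return self.body.backward(dout[:, :c]) + dout[:, c:]


class Network:
    """Executable network: blocks instantiated with learnable weights.

    Weight initialization is Kaiming fan-in scaling drawn from a generator
    seeded with ``weight_init_seed``, so two networks built from the same
    config are bitwise identical.
    """

    def __init__(self, config: EDNetConfig, blocks: list[BlockSpec] | None = None):
        self.config = config
        self.block_specs = blocks if blocks is not None else config.blocks()
        validate_chain(self.block_specs)
        rng = np.random.default_rng(config.weight_init_seed)
        modules: list[L.Layer] = []
        for spec in self.block_specs:
            body = _instantiate(spec.layers, rng, config.swish6_mode, config.bn_momentum)
            if spec.skip == "additive":
                shortcut = (
                    _instantiate(spec.skip_projection, rng, config.swish6_mode,
                                 config.bn_momentum)
                    if spec.skip_projection
                    else None
                )
                modules.append(L.Residual(body, shortcut))
            elif spec.skip == "concat":
                modules.append(L.Sequential(
                    _Concat(body),
                    *_instantiate(spec.skip_projection, rng, config.swish6_mode,
                                  config.bn_momentum).layers,
                ))
            else:
                modules.append(body)
        self.model = L.Sequential(*modules)
        self.model.set_training(False)

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[L.Parameter]:
        return self.model.parameters()

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        i = 0
        for layer in self._all_layers():
            if isinstance(layer, L.BatchNorm2d):
                state[f"bn_{i}_mean"] = layer.running_mean
                state[f"bn_{i}_var"] = layer.running_var
                i += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value = np.ascontiguousarray(state[f"param_{i}"], dtype=L.DTYPE)
        i = 0
        for layer in self._all_layers():
            if isinstance(layer, L.BatchNorm2d):
                layer.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=L.DTYPE)
                layer.running_var = np.asarray(state[f"bn_{i}_var"], dtype=L.DTYPE)
                i += 1

    def _all_layers(self):
        def walk(layer):
            if isinstance(layer, L.Sequential):
                for sub in layer.layers:
                    yield from walk(sub)
            elif isinstance(layer, L.Residual):
                yield from walk(layer.body)
                if layer.shortcut is not None:
                    yield from walk(layer.shortcut)
            elif isinstance(layer, _Concat):
                yield from walk(layer.body)
            else:
                yield layer

        yield from walk(self.model)

    # -- execution --------------------------------------------------------
    def set_training(self, flag: bool) -> None:
        self.model.set_training(flag)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=L.DTYPE)
        n = self.config.input_size
        if batch.ndim != 4 or batch.shape[1] != 3 or batch.shape[2:] != (n, n):
            raise ValueError(
                f"expected batch of shape (N,3,{n},{n}), got {tuple(batch.shape)}"
            )
        logits = self.model.forward(batch)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits in forward pass")
        return logits

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.model.backward(dlogits)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Row-wise class probabilities (each row sums to 1)."""
        return softmax(self.forward(batch), axis=1)


def assemble_ednet(
    config: EDNetConfig | None = None, blocks: list[BlockSpec] | None = None
) -> Network:
    """Build the executable network from a config (default: frozen flags)."""
    return Network(config or EDNetConfig(), blocks=blocks)


def summarize(config: EDNetConfig | None = None) -> str:
    """Table-style row listing of the assembled architecture."""
    config = config or EDNetConfig()
    lines = [
        f"{'Block':<22} {'Layer':<22} {'In':>5} {'Out':>5} {'Kernel':>7} "
        f"{'Stride/Pad':>10}"
    ]
    for block in config.blocks():
        first = True
        for s in block.layers:
            if s.kind in ("norm", "activation"):
                continue
            name = {
                "conv": "Conv/LBN",
                "depthwise_conv": "Dep-Conv/LBN",
                "global_pool": "Global_pool",
                "linear": "Linear",
            }[s.kind]
            if s.has_swish6:
                name += "/swish6"
            kern = f"{s.kernel}x{s.kernel}" if s.kernel else ""
            sp = f"{s.stride}/{s.padding}" if s.kernel else ""
            lines.append(
                f"{block.name if first else '':<22} {name:<22} "
                f"{s.in_channels:>5} {s.out_channels:>5} {kern:>7} {sp:>10}"
            )
            first = False
    return "\n".join(lines)
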