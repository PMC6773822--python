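"""Encoder-decoder translation network (U-Net) for MR -> 3-channel CT.

The encoder halves the spatial resolution at each of ``depth`` stages while
doubling the filter count; the decoder mirrors it with transpose
convolutions, concatenating the resolution-matched encoder feature map
(skip connection) before each decoder convolution.  Every convolution is
followed by batch normalization and Leaky ReLU except the final projection,
which is linear so the outputs are unbounded regression values in
normalized channel space.

Two ready-made profiles are provided: ``FULL_PROFILE`` (5 levels, 64 base
filters, the full-scale configuration) and ``DESK_PROFILE`` (3 levels, 8
base filters), a small configuration that trains in minutes on a CPU and is
used throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .hu_windows import NormalizationSpec
from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Layer, LeakyReLU, Param, Sequential


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of downsampling stages; ``base_filters`` the
    filter count at full resolution (doubles per stage).  Inputs must have
    height and width divisible by ``2**depth``; use :func:`pad_to_grid`
    otherwise.
    """

    depth: int = 5
    base_filters: int = 64
    input_channels: int = 1
    output_channels: int = 3
    leaky_slope: float = 0.2
    conv_kernel: int = 3
    up_kernel: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.output_channels != 3:
            raise ValueError("the translation network emits exactly 3 tissue channels")

    @property
    def grid_multiple(self) -> int:
        return 2**self.depth

    def filters_at(self, level: int) -> int:
        return self.base_filters * 2**level


FULL_PROFILE = NetworkConfig(depth=5, base_filters=64)
DESK_PROFILE = NetworkConfig(depth=3, base_filters=8)


def _conv_block(cfg: NetworkConfig, cin: int, cout: int, stride: int = 1) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, kernel=cfg.conv_kernel, stride=stride),
        BatchNorm2d(cout),
        LeakyReLU(cfg.leaky_slope),
    )


def _up_block(cfg: NetworkConfig, cin: int, cout: int) -> Sequential:
    return Sequential(
        ConvTranspose2d(cin, cout, kernel=cfg.up_kernel),
        BatchNorm2d(cout),
        LeakyReLU(cfg.leaky_slope),
    )


class UNet:
    """The translation network; see module docstring for the layout."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        cfg = config
        self.in_block = _conv_block(cfg, cfg.input_channels, cfg.filters_at(0))
        self.down = [
            _conv_block(cfg, cfg.filters_at(i), cfg.filters_at(i + 1), stride=2)
            for i in range(cfg.depth)
        ]
        self.enc = [
            _conv_block(cfg, cfg.filters_at(i + 1), cfg.filters_at(i + 1))
            for i in range(cfg.depth)
        ]
        self.up = [
            _up_block(cfg, cfg.filters_at(i + 1), cfg.filters_at(i))
            for i in range(cfg.depth)
        ]
        self.dec = [
            _conv_block(cfg, 2 * cfg.filters_at(i), cfg.filters_at(i))
            for i in range(cfg.depth)
        ]
        # final projection: linear, no batch norm or activation (HU regression)
        self.out_conv = Conv2d(cfg.filters_at(0), cfg.output_channels, kernel=cfg.conv_kernel)
        self._skip_cache: list[np.ndarray] | None = None

    # -- structure walks ---------------------------------------------------

    def blocks(self) -> list[tuple[str, Layer]]:
        """(name, layer) pairs in deterministic forward order."""
        named: list[tuple[str, Layer]] = [("in", self.in_block)]
        for i in range(self.config.depth):
            named.append((f"down{i}", self.down[i]))
            named.append((f"enc{i}", self.enc[i]))
        for i in reversed(range(self.config.depth)):
            named.append((f"up{i}", self.up[i]))
            named.append((f"dec{i}", self.dec[i]))
        named.append(("out", self.out_conv))
        return named

    def params(self) -> list[Param]:
        return [p for _, block in self.blocks() for p in block.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _leaf_layers(self) -> list[Layer]:
        leaves: list[Layer] = []
        for _, block in self.blocks():
            if isinstance(block, Sequential):
                leaves.extend(block.layers)
            else:
                leaves.append(block)
        return leaves

    # -- forward / backward ------------------------------------------------

    def check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        m = self.config.grid_multiple
        if h % m or w % m:
            ph, pw = (-h) % m, (-w) % m
            raise ValueError(
                f"input {h}x{w} is not divisible by 2^depth = {m}; "
                f"pad to {h + ph}x{w + pw} (see pad_to_grid)"
            )

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """(N, 1, H, W) -> (N, 3, H, W); H, W divisible by 2**depth."""
        self.check_input(x)
        depth = self.config.depth
        h = self.in_block.forward(x, training)
        skips = [h]
        for i in range(depth):
            h = self.down[i].forward(h, training)
            h = self.enc[i].forward(h, training)
            if i < depth - 1:
                skips.append(h)
        for i in reversed(range(depth)):
            h = self.up[i].forward(h, training)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h, training)
        if training:
            self._skip_cache = skips
        return self.out_conv.forward(h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        depth = self.config.depth
        fat = self.config.filters_at
        d = self.out_conv.backward(dy)
        dskips: list[np.ndarray | None] = [None] * depth
        for i in range(depth):  # reverse of the decoder loop
            d = self.dec[i].backward(d)
            dskips[i], d = d[:, : fat(i)], d[:, fat(i) :]
            d = self.up[i].backward(d)
        for i in reversed(range(depth)):  # reverse of the encoder loop
            if i < depth - 1:
                d = d + dskips[i + 1]
            d = self.enc[i].backward(d)
            d = self.down[i].backward(d)
        d = d + dskips[0]
        return self.in_block.backward(d)


def build_network(config: NetworkConfig = DESK_PROFILE) -> UNet:
    """Construct an (uninitialized) translation network for ``config``."""
    return UNet(config)


def initialize(net: UNet, seed: int) -> UNet:
    """Seeded weight initialization: conv weights ~ N(0, 0.01^2), biases 0,
    batch-norm scale 1 / shift 0, running statistics reset."""
    rng = np.random.default_rng(seed)
    for layer in net._leaf_layers():
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            layer.w.value = rng.normal(0.0, 0.01, size=layer.w.value.shape).astype(
                layer.w.value.dtype
            )
            layer.b.value[...] = 0
        elif isinstance(layer, BatchNorm2d):
            layer.gamma.value[...] = 1
            layer.beta.value[...] = 0
            layer.running_mean[...] = 0
            layer.running_var[...] = 1
    return net


# -- padding plumbing ------------------------------------------------------


@dataclass(frozen=True)
class CropRecord:
    """Margins added by :func:`pad_to_grid`; apply :meth:`crop` to undo."""

    top: int
    bottom: int
    left: int
    right: int

    def crop(self, arr: np.ndarray) -> np.ndarray:
        h, w = arr.shape[-2:]
        return arr[..., self.top : h - self.bottom, self.left : w - self.right]


def pad_to_grid(arr: np.ndarray, depth: int) -> tuple[np.ndarray, CropRecord]:
    """Zero-pad the trailing two axes to the next multiple of ``2**depth``,
    splitting the margin as symmetrically as possible."""
    m = 2**depth
    h, w = arr.shape[-2:]
    ph, pw = (-h) % m, (-w) % m
    top, left = ph // 2, pw // 2
    bottom, right = ph - top, pw - left
    widths = [(0, 0)] * (arr.ndim - 2) + [(top, bottom), (left, right)]
    return np.pad(arr, widths), CropRecord(top, bottom, left, right)


# -- summaries -------------------------------------------------------------


@dataclass
class NetworkSummary:
    encoder_filters: tuple[int, ...]
    level_shapes: list[tuple[int, int, int]]  # (channels, H, W) per encoder level
    n_parameters: int
    blocks: list[str] = field(default_factory=list)


def summarize(net: UNet, input_hw: tuple[int, int]) -> NetworkSummary:
    """Per-level feature shapes and parameter count for a given input size."""
    cfg = net.config
    h, w = input_hw
    net.check_input(np.empty((1, 1, h, w), dtype=np.float32))
    shapes = [(cfg.filters_at(0), h, w)]
    for i in range(cfg.depth):
        h, w = h // 2, w // 2
        shapes.append((cfg.filters_at(i + 1), h, w))
    block_names = [name for name, _ in net.blocks()]
    return NetworkSummary(
        encoder_filters=tuple(cfg.filters_at(i) for i in range(cfg.depth + 1)),
        level_shapes=shapes,
        n_parameters=net.n_parameters(),
        blocks=block_names,
    )


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, net: UNet, norm_spec: NormalizationSpec) -> None:
    """Serialize weights + architecture + normalization spec into one .npz,
    so a checkpoint is self-describing."""
    arrays: dict[str, np.ndarray] = {}
    for bname, block in net.blocks():
        layers = block.layers if isinstance(block, Sequential) else [block]
        for li, layer in enumerate(layers):
            prefix = f"{bname}.{li}"
            if isinstance(layer, (Conv2d, ConvTranspose2d)):
                arrays[f"{prefix}.w"] = layer.w.value
                arrays[f"{prefix}.b"] = layer.b.value
            elif isinstance(layer, BatchNorm2d):
                arrays[f"{prefix}.gamma"] = layer.gamma.value
                arrays[f"{prefix}.beta"] = layer.beta.value
                arrays[f"{prefix}.running_mean"] = layer.running_mean
                arrays[f"{prefix}.running_var"] = layer.running_var
    meta = {"config": asdict(net.config), "normalization": asdict(norm_spec)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[UNet, NormalizationSpec]:
    """Rebuild the network and normalization spec from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        net = UNet(NetworkConfig(**meta["config"]))
        spec = NormalizationSpec(**meta["normalization"])
        for bname, block in net.blocks():
            layers = block.layers if isinstance(block, Sequential) else [block]
            for li, layer in enumerate(layers):
                prefix = f"{bname}.{li}"
                if isinstance(layer, (Conv2d, ConvTranspose2d)):
                    layer.w.value = data[f"{prefix}.w"]
                    layer.b.value = data[f"{prefix}.b"]
                elif isinstance(layer, BatchNorm2d):
                    layer.gamma.value = data[f"{prefix}.gamma"]
                    layer.beta.value = data[f"{prefix}.beta"]
                    layer.running_mean = data[f"{prefix}.running_mean"]
                    layer.running_var = data[f"{prefix}.running_var"]
    return net, spec
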