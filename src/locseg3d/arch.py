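"""3D dilated residual U-Net: declarative spec and builder.

The network has three encoder blocks, a dilated bottleneck, three
decoder blocks with skip connections, and a 1x1x1 head. Each encoder/
decoder block is two 3x3x3 convolutions (each followed by batch norm
and ReLU) with a residual link realised as concatenation of the block
input with the second convolution's output, projected back to the block
width by a 1x1x1 convolution. The bottleneck is a chain of four 3x3x3
convolutions with dilation rates 1, 2, 4, 8 whose outputs are summed,
giving a receptive field of 2*(1+2+4+8)+1 = 31 voxels at bottleneck
resolution. Channel widths double per level (base, 2b, 4b; bottleneck
8b). Pooling halves all three axes, or only the in-plane axes when
`keep_z` is set (for thick-slice short-axis stacks).

A single-class head applies a sigmoid; a multi-class head applies a
per-voxel softmax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .nn import (
    BatchNorm3d,
    Conv3d,
    Module,
    Tensor,
    concatenate,
    max_pool3d,
    upsample_nearest3d,
)

__all__ = [
    "NetworkSpec",
    "DRUNet3D",
    "build_network",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    in_channels: int = 1
    num_classes: int = 1
    base_filters: int = 8
    levels: int = 3
    bottleneck_dilations: tuple[int, ...] = (1, 2, 4, 8)
    keep_z: bool = False

    def __post_init__(self):
        self.bottleneck_dilations = tuple(int(d) for d in self.bottleneck_dilations)
        if self.levels != 3:
            raise ValueError("the architecture is defined with exactly 3 levels")
        d = self.bottleneck_dilations
        if d[0] != 1 or d[-1] != 8 or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(
                "bottleneck dilations must be strictly increasing from 1 to 8"
            )
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.in_channels < 1 or self.num_classes < 1:
            raise ValueError("in_channels and num_classes must be >= 1")

    @property
    def pool_factor(self) -> tuple[int, int, int]:
        return (1, 2, 2) if self.keep_z else (2, 2, 2)

    @property
    def pool_divisor(self) -> tuple[int, int, int]:
        f = self.pool_factor
        return tuple(x**self.levels for x in f)


class ConvBlock(Module):
    """Two 3x3x3 conv+BN+ReLU layers with a concat-residual projection."""

    def __init__(self, in_channels: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(in_channels, width, 3, rng=rng)
        self.bn1 = BatchNorm3d(width)
        self.conv2 = Conv3d(width, width, 3, rng=rng)
        self.bn2 = BatchNorm3d(width)
        self.proj = Conv3d(in_channels + width, width, 1, rng=rng)
        self.bn3 = BatchNorm3d(width)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = concatenate([x, h], axis=1)  # residual link: input || conv2 output
        return self.bn3(self.proj(h)).relu()


class Bottleneck(Module):
    """Chain of dilated convolutions whose outputs are summed."""

    def __init__(
        self,
        in_channels: int,
        width: int,
        dilations: tuple[int, ...],
        rng: np.random.Generator,
        with_norm: bool = True,
        bias: bool = True,
    ):
        super().__init__()
        convs = []
        c = in_channels
        for d in dilations:
            convs.append(Conv3d(c, width, 3, dilation=d, bias=bias, rng=rng))
            c = width
        self.convs = convs
        self.bn = BatchNorm3d(width) if with_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        total = None
        h = x
        for conv in self.convs:
            h = conv(h)
            total = h if total is None else total + h
        if self.bn is not None:
            total = self.bn(total).relu()
        return total


class ForwardResult(NamedTuple):
    probs: Tensor     # sigmoid/softmax output, shape (N, K, Z, Y, X)
    logits: Tensor    # pre-activation head output
    features: Tensor  # final decoder feature maps (input to the head)


class DRUNet3D(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        b = spec.base_filters
        widths = [b, 2 * b, 4 * b]
        self.encoders = []
        c = spec.in_channels
        for w in widths:
            self.encoders.append(ConvBlock(c, w, rng))
            c = w
        self.bottleneck = Bottleneck(c, 8 * b, spec.bottleneck_dilations, rng)
        self.decoders = []
        c = 8 * b
        for w in reversed(widths):
            self.decoders.append(ConvBlock(c + w, w, rng))
            c = w
        self.head = Conv3d(widths[0], spec.num_classes, 1, rng=rng)

    def _check_divisible(self, shape: tuple[int, ...]) -> None:
        for axis, (n, d) in enumerate(zip(shape, self.spec.pool_divisor)):
            if n % d:
                raise ValueError(
                    f"input axis {'zyx'[axis]} has size {n}, not divisible by "
                    f"the cumulative pooling factor {d}"
                )

    def forward(self, x: Tensor) -> ForwardResult:
        """Run the network on a batch (N, C, Z, Y, X)."""
        if x.ndim != 5:
            raise ValueError("expected a 5D batch (N, C, Z, Y, X)")
        self._check_divisible(x.shape[2:])
        f = self.spec.pool_factor
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = max_pool3d(h, f)
        h = self.bottleneck(h)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = upsample_nearest3d(h, f)
            h = concatenate([h, skip], axis=1)
            h = dec(h)
        features = h
        logits = self.head(features)
        if self.spec.num_classes == 1:
            probs = logits.sigmoid()
        else:
            probs = logits.softmax(axis=1)
        return ForwardResult(probs, logits, features)

    __call__ = forward


def build_network(spec: NetworkSpec, seed: int | None = None) -> DRUNet3D:
    """Instantiate the network; construction is deterministic under `seed`."""
    return DRUNet3D(spec, np.random.default_rng(0 if seed is None else seed))


def count_parameters(model: Module) -> int:
    """Exact number of trainable scalars (kernels, biases, BN affine pairs)."""
    return model.num_parameters()


def save_checkpoint(model: DRUNet3D, path: str | Path) -> Path:
    """Save weights plus the embedded spec (npz with a JSON header array)."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    spec_json = json.dumps(asdict(model.spec))
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> DRUNet3D:
    with np.load(path) as z:
        raw = json.loads(bytes(z["__spec__"]).decode())
        raw["bottleneck_dilations"] = tuple(raw["bottleneck_dilations"])
        spec = NetworkSpec(**raw)
        model = build_network(spec)
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model.load_state_arrays(arrays)
    return model
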