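"""Edge-output fully-convolutional segmentation network.

A truncated residual backbone extracts multi-scale features; at three tap
points (ends of the stride-4/8/16 stages for the ResNet50 layout) an
"edge output" branch reduces the feature map to a fixed channel width
(default 128) with a 1×1 convolution and upsamples it to the input
resolution with a transposed convolution initialized to bilinear
interpolation. The three upsampled maps are concatenated and fused by two
convolutions down to a single channel; a sigmoid yields the per-pixel
tumor probability.

Two backbones share the tap structure: ``resnet50`` — the standard
bottleneck layout with its last three residual blocks, global pooling and
fully-connected head removed (13 blocks remain; taps at blocks 3, 7, 13);
``reduced`` — a shallow basic-block backbone sized for CPU training,
taps at the end of each of its three stages.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import (
    Adam,
    BasicBlock,
    BottleneckBlock,
    Conv2d,
    ConvTranspose2d,
    MaxPool2d,
    ReLU,
    sigmoid,
)
from .preprocess import NormalizedSlice

__all__ = [
    "NetworkConfig",
    "ProbabilityMap",
    "EdgeOutputNet",
    "build_network",
    "forward",
    "binarize",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``tap_points`` are 1-based residual-block indices; the last tap is the
    truncation point (no trunk exists beyond it). ``reduced_channels`` /
    ``reduced_blocks`` shape the shallow backbone only.
    """

    backbone: str = "resnet50"
    tap_points: tuple[int, ...] = (3, 7, 13)
    reduction_channels: int = 128
    input_size: int = 96
    pretrained: bool = False
    head_channels: tuple[int, int] = (64, 1)
    deep_supervision: bool = False
    seed: int = 0
    reduced_channels: tuple[int, int, int] = (8, 16, 32)
    reduced_blocks: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.backbone not in ("resnet50", "reduced"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        taps = self.tap_points
        if len(taps) != 3 or any(b <= a for a, b in zip(taps, taps[1:])):
            raise ValueError("tap_points must be 3 strictly increasing indices")
        if self.reduction_channels < 1:
            raise ValueError("reduction_channels must be >= 1")
        if self.head_channels[-1] != 1:
            raise ValueError("final head convolution must output 1 channel")

    @staticmethod
    def reduced_default(input_size: int = 64, reduction_channels: int = 8,
                        head_channels: tuple[int, int] = (16, 1),
                        seed: int = 0, **kw) -> "NetworkConfig":
        """Desk-scale configuration used throughout the tests."""
        return NetworkConfig(
            backbone="reduced",
            tap_points=(1, 2, 3),
            reduction_channels=reduction_channels,
            input_size=input_size,
            head_channels=head_channels,
            seed=seed,
            **kw,
        )


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel tumor probabilities, same spatial shape as the input."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _resnet50_blocks(rng):
    """Bottleneck blocks of conv2_x..conv4_x (conv5_x removed): 13 blocks."""
    specs = []
    c_in = 64
    for n_blocks, c_mid, c_out, first_stride in (
        (3, 64, 256, 1),
        (4, 128, 512, 2),
        (6, 256, 1024, 2),
    ):
        for i in range(n_blocks):
            stride = first_stride if i == 0 else 1
            specs.append(BottleneckBlock(c_in, c_mid, c_out, stride=stride, rng=rng))
            c_in = c_out
    return specs


class _Backbone:
    def __init__(self, config: NetworkConfig, rng):
        self.tap_points = config.tap_points
        if config.backbone == "resnet50":
            in_ch = 3 if config.pretrained else 1
            self.stem = [Conv2d(in_ch, 64, 7, stride=2, pad=3, rng=rng), ReLU(),
                         MaxPool2d(3, 2, 1)]
            self.stem_stride = 4
            self.blocks = _resnet50_blocks(rng)
        else:
            chans = config.reduced_channels
            self.stem = [Conv2d(1, chans[0], 3, rng=rng), ReLU()]
            self.stem_stride = 1
            self.blocks = []
            c_in = chans[0]
            for stage, (c_out, n_blocks) in enumerate(
                zip(chans, config.reduced_blocks)
            ):
                for i in range(n_blocks):
                    stride = 2 if i == 0 else 1
                    self.blocks.append(BasicBlock(c_in, c_out, stride=stride, rng=rng))
                    c_in = c_out
        n = len(self.blocks)
        if max(self.tap_points) > n:
            raise ValueError(
                f"tap index {max(self.tap_points)} beyond truncation point "
                f"({n} residual blocks)"
            )
        # drop trunk blocks past the last tap: they receive no gradient
        self.blocks = self.blocks[: max(self.tap_points)]

    def tap_stride(self, tap: int) -> int:
        s = self.stem_stride
        for b in self.blocks[:tap]:
            s *= b.stride
        return s

    def tap_channels(self, tap: int) -> int:
        return self.blocks[tap - 1].c_out

    def forward(self, x):
        for layer in self.stem:
            x = layer.forward(x)
        feats = {}
        for i, block in enumerate(self.blocks, start=1):
            x = block.forward(x)
            if i in self.tap_points:
                feats[i] = x
        return feats

    def backward(self, d_taps: dict[int, np.ndarray]):
        grad = None
        for i in range(len(self.blocks), 0, -1):
            if i in d_taps:
                grad = d_taps[i] if grad is None else grad + d_taps[i]
            grad = self.blocks[i - 1].backward(grad)
        for layer in reversed(self.stem):
            grad = layer.backward(grad)
        return grad

    def layer_items(self):
        items = []
        for i, layer in enumerate(self.stem):
            if layer.params:
                items.append((f"stem{i}", layer))
        for i, block in enumerate(self.blocks, start=1):
            for name, sub in block.sublayers:
                items.append((f"block{i}.{name}", sub))
        return items


class _EdgeBranch:
    """1×1 channel reduction followed by learned upsampling to input size."""

    def __init__(self, c_in, c_red, factor, rng):
        self.factor = factor
        self.reduce = Conv2d(c_in, c_red, 1, pad=0, rng=rng)
        self.up = (
            ConvTranspose2d(c_red, c_red, k=2 * factor, stride=factor,
                            pad=factor // 2, bilinear_init=True)
            if factor > 1
            else None
        )
        self.c_red = c_red

    def forward(self, x):
        y = self.reduce.forward(x)
        return self.up.forward(y) if self.up is not None else y

    def backward(self, dout):
        if self.up is not None:
            dout = self.up.backward(dout)
        return self.reduce.backward(dout)

    def layer_items(self):
        items = [("reduce", self.reduce)]
        if self.up is not None:
            items.append(("up", self.up))
        return items


class EdgeOutputNet:
    """The full network; also serves as its own parameter container."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = _Backbone(config, rng)
        self.branches = []
        for tap in config.tap_points:
            factor = self.backbone.tap_stride(tap)
            if config.input_size % factor:
                raise ValueError(
                    f"input_size {config.input_size} not divisible by tap "
                    f"stride {factor}"
                )
            self.branches.append(
                _EdgeBranch(self.backbone.tap_channels(tap),
                            config.reduction_channels, factor, rng)
            )
        fused_ch = 3 * config.reduction_channels
        self.fuse1 = Conv2d(fused_ch, config.head_channels[0], 3, rng=rng)
        self.fuse_relu = ReLU()
        self.fuse2 = Conv2d(config.head_channels[0], 1, 1, pad=0, rng=rng)
        # start near "all background": tumor pixels are the rare class, and
        # a negative prior logit keeps early Dice/CE gradients from swamping
        # the network with false positives
        self.fuse2.params["b"][:] = -2.0
        self.side_heads = (
            [Conv2d(config.reduction_channels, 1, 1, pad=0, rng=rng)
             for _ in config.tap_points]
            if config.deep_supervision
            else []
        )

    # -- structure ---------------------------------------------------------

    def layer_items(self):
        items = self.backbone.layer_items()
        for i, branch in enumerate(self.branches):
            for name, layer in branch.layer_items():
                items.append((f"branch{i}.{name}", layer))
        items.append(("fuse1", self.fuse1))
        items.append(("fuse2", self.fuse2))
        for i, head in enumerate(self.side_heads):
            items.append((f"side{i}", head))
        return items

    def param_slots(self):
        return [
            (layer, name)
            for _, layer in self.layer_items()
            for name in sorted(layer.params)
        ]

    def describe(self) -> dict:
        """Structural audit: branch count, per-branch reduction width and
        upsampling factor, and the two-convolution head widths."""
        return {
            "n_edge_branches": len(self.branches),
            "branch_reduction_channels": [b.c_red for b in self.branches],
            "branch_upsample_factors": [b.factor for b in self.branches],
            "n_backbone_blocks": len(self.backbone.blocks),
            "head_conv_channels": [
                self.fuse1.params["W"].shape[0],
                self.fuse2.params["W"].shape[0],
            ],
        }

    # -- computation -------------------------------------------------------

    @property
    def dtype(self):
        """Compute dtype follows the parameters (float32 by default)."""
        return self.fuse1.params["W"].dtype

    def forward_logits(self, x: np.ndarray):
        """(N,C,H,W) batch -> fused logits (N,1,H,W) and side logits."""
        x = np.asarray(x).astype(self.dtype, copy=False)
        feats = self.backbone.forward(x)
        branch_outs = [
            br.forward(feats[tap])
            for br, tap in zip(self.branches, self.config.tap_points)
        ]
        self._branch_channels = [b.shape[1] for b in branch_outs]
        fused = np.concatenate(branch_outs, axis=1)
        y = self.fuse1.forward(fused)
        y = self.fuse_relu.forward(y)
        logits = self.fuse2.forward(y)
        sides = [head.forward(b) for head, b in zip(self.side_heads, branch_outs)]
        return logits, sides

    def backward_logits(self, d_logits, d_sides=None):
        d_logits = np.asarray(d_logits).astype(self.dtype, copy=False)
        if d_sides is not None:
            d_sides = [np.asarray(d).astype(self.dtype, copy=False)
                       for d in d_sides]
        dy = self.fuse_relu.backward(self.fuse2.backward(d_logits))
        dfused = self.fuse1.backward(dy)
        splits = np.cumsum(self._branch_channels)[:-1]
        d_branches = list(np.split(dfused, splits, axis=1))
        if d_sides:
            for i, (head, ds) in enumerate(zip(self.side_heads, d_sides)):
                d_branches[i] = d_branches[i] + head.backward(ds)
        d_taps = {}
        for br, tap, db in zip(self.branches, self.config.tap_points, d_branches):
            d_taps[tap] = br.backward(db)
        return self.backbone.backward(d_taps)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single 2D image -> 2D probability array."""
        image = np.asarray(image, dtype=float)
        self._check_size(image.shape)
        x = image[None, None]
        if self.config.backbone == "resnet50" and self.config.pretrained:
            x = np.repeat(x, 3, axis=1)  # replicate gray to RGB for stock weights
        logits, _ = self.forward_logits(x)
        return sigmoid(logits[0, 0])

    def _check_size(self, shape):
        s = self.config.input_size
        if shape != (s, s):
            raise ValueError(f"expected input of size {s}x{s}, got {shape}")


def build_network(config: NetworkConfig) -> EdgeOutputNet:
    """Construct the network with seeded initial parameters."""
    return EdgeOutputNet(config)


def forward(params: EdgeOutputNet, image) -> ProbabilityMap:
    """Run one normalized slice through the network."""
    if isinstance(image, NormalizedSlice):
        image = image.image
    return ProbabilityMap(values=params.predict(image))


def binarize(pmap, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary mask (1 where p >= t)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    values = pmap.values if isinstance(pmap, ProbabilityMap) else np.asarray(pmap)
    return (values >= threshold).astype(np.uint8)


# -- serialization ---------------------------------------------------------

def save_network(net: EdgeOutputNet, path) -> None:
    """Single-file checkpoint: all arrays plus the embedded config."""
    arrays = {
        f"{lname}/{pname}": layer.params[pname]
        for lname, layer in net.layer_items()
        for pname in sorted(layer.params)
    }
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(net.config)).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_network(path) -> EdgeOutputNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("tap_points", "head_channels", "reduced_channels",
                    "reduced_blocks"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = EdgeOutputNet(NetworkConfig(**cfg_dict))
        for lname, layer in net.layer_items():
            for pname in sorted(layer.params):
                layer.params[pname] = data[f"{lname}/{pname}"].copy()
    return net
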