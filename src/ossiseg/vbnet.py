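"""VB-Net: a V-Net encoder-decoder whose stages are bottleneck residual units.

The network has one input block, four down blocks, four up blocks, one
output block and a softmax head. A down block is a strided convolution
(kernel k, stride s) followed by bottleneck units; an up block is a
transposed convolution that doubles resolution, a skip connection from the
matching encoder level (concatenation, or addition when channel widths
match), and bottleneck units. A bottleneck unit is 1x1x1 reduce ->
k x k x k spatial conv -> 1x1x1 expand with a residual addition; the
reduction factor shrinks parameter count while keeping depth, which is the
point of using bottlenecks on a V-Net backbone. Instance normalization and
ReLU are used throughout (small-batch 3D segmentation default).

With stride 2 the encoder halves each spatial dimension four times, so
input patches must be divisible by 16 per axis.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn


class ConfigurationError(ValueError):
    """NetConfig violates an architecture invariant."""


class ShapeError(ValueError):
    """Input spatial shape incompatible with the encoder's downsampling."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``desk`` preset (channels 8/16/32/64) keeps CPU training tractable;
    ``full`` preset (16/32/64/128) mirrors the scale intended for GPU use.
    """

    n_classes: int = 2
    input_channels: int = 1
    input_block_channels: int = 8
    down_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    up_channels: tuple[int, int, int, int] = (32, 16, 8, 8)
    bottlenecks_down: tuple[int, int, int, int] = (1, 1, 1, 1)
    bottlenecks_up: tuple[int, int, int, int] = (1, 1, 1, 1)
    kernel_size: int = 3
    down_stride: int = 2
    reduction: int = 4
    skip_mode: str = "concat"  # concat | add

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.down_channels) != 4 or len(self.up_channels) != 4:
            raise ConfigurationError("topology is fixed at 4 down and 4 up blocks")
        if len(self.bottlenecks_down) != 4 or len(self.bottlenecks_up) != 4:
            raise ConfigurationError("need one bottleneck count per block (4 + 4)")
        widths = (
            (self.input_block_channels,) + tuple(self.down_channels) + tuple(self.up_channels)
        )
        if any(c < 1 for c in widths):
            raise ConfigurationError(f"every channel width must be >= 1, got {widths}")
        for c in tuple(self.down_channels) + tuple(self.up_channels):
            if c % self.reduction:
                raise ConfigurationError(
                    f"reduction {self.reduction} must divide channel width {c}"
                )
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ConfigurationError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.down_stride != 2:
            raise ConfigurationError("down_stride 2 is required (2x per level, 16x total)")
        if self.skip_mode not in ("concat", "add"):
            raise ConfigurationError(f"skip_mode must be concat|add, got {self.skip_mode}")
        if self.skip_mode == "add":
            skips = (self.down_channels[2], self.down_channels[1],
                     self.down_channels[0], self.input_block_channels)
            for u, s in zip(self.up_channels, skips):
                if u != s:
                    raise ConfigurationError(
                        "skip_mode='add' requires up_channels to match encoder widths "
                        f"({self.up_channels} vs {skips})"
                    )


DESK_CONFIG = NetConfig()
FULL_CONFIG = NetConfig(
    input_block_channels=16,
    down_channels=(16, 32, 64, 128),
    up_channels=(64, 32, 16, 16),
    bottlenecks_down=(1, 2, 2, 2),
    bottlenecks_up=(2, 2, 1, 1),
)

DOWN_FACTOR = 16  # stride 2 applied at each of the 4 encoder levels


class Bottleneck(nn.Layer):
    """1x1 reduce -> k^3 spatial -> 1x1 expand, residual add, ReLU."""

    def __init__(self, c, reduction, k, rng):
        cr = max(1, c // reduction)
        self.body = nn.Sequential(
            nn.Conv3d(c, cr, 1, rng=rng), nn.InstanceNorm(cr), nn.ReLU(),
            nn.Conv3d(cr, cr, k, rng=rng), nn.InstanceNorm(cr), nn.ReLU(),
            nn.Conv3d(cr, c, 1, rng=rng), nn.InstanceNorm(c),
        )
        self.relu = nn.ReLU()

    def params(self):
        return self.body.params()

    def forward(self, x, train=True):
        return self.relu.forward(x + self.body.forward(x, train=train), train=train)

    def backward(self, gy):
        g = self.relu.backward(gy)
        return g + self.body.backward(g)


class DownBlock(nn.Layer):
    """Strided convolution then bottlenecks (conv first, per the block layout)."""

    def __init__(self, cin, cout, n_bottlenecks, cfg: NetConfig, rng):
        k, s = cfg.kernel_size, cfg.down_stride
        layers = [nn.Conv3d(cin, cout, k, stride=s, rng=rng), nn.InstanceNorm(cout), nn.ReLU()]
        layers += [Bottleneck(cout, cfg.reduction, k, rng) for _ in range(n_bottlenecks)]
        self.seq = nn.Sequential(*layers)

    def params(self):
        return self.seq.params()

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, gy):
        return self.seq.backward(gy)


class UpBlock(nn.Layer):
    """Transposed conv (2x), skip connection, then bottlenecks."""

    def __init__(self, cin, skip_c, cout, n_bottlenecks, cfg: NetConfig, rng):
        self.mode = cfg.skip_mode
        self.skip_c = skip_c
        self.up = nn.ConvTranspose2x(cin, cout, rng=rng)
        if self.mode == "concat":
            self.merge = nn.Sequential(
                nn.Conv3d(cout + skip_c, cout, 1, rng=rng),
                nn.InstanceNorm(cout),
                nn.ReLU(),
            )
        self.tail = nn.Sequential(
            *[Bottleneck(cout, cfg.reduction, cfg.kernel_size, rng) for _ in range(n_bottlenecks)]
        )

    def params(self):
        ps = self.up.params() + self.tail.params()
        if self.mode == "concat":
            ps += self.merge.params()
        return ps

    def forward(self, x, skip, train=True):
        u = self.up.forward(x, train=train)
        if self.mode == "concat":
            z = np.concatenate([u, skip], axis=1)
            z = self.merge.forward(z, train=train)
        else:
            z = u + skip
        return self.tail.forward(z, train=train)

    def backward(self, gy):
        g = self.tail.backward(gy)
        if self.mode == "concat":
            g = self.merge.backward(g)
            cu = self.up.cout
            gu, gskip = g[:, :cu], g[:, cu:]
        else:
            gu, gskip = g, g
        return self.up.backward(np.ascontiguousarray(gu)), gskip


class VBNet:
    """The cascaded-stage segmentation network (one stage)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = cfg.kernel_size
        cin, c0 = cfg.input_channels, cfg.input_block_channels
        dc, uc = cfg.down_channels, cfg.up_channels
        self.input_block = nn.Sequential(
            nn.Conv3d(cin, c0, k, rng=rng), nn.InstanceNorm(c0), nn.ReLU()
        )
        enc_in = (c0,) + tuple(dc[:3])
        self.down = [
            DownBlock(enc_in[i], dc[i], cfg.bottlenecks_down[i], cfg, rng)
            for i in range(4)
        ]
        skips = (dc[2], dc[1], dc[0], c0)
        up_in = (dc[3],) + tuple(uc[:3])
        self.up = [
            UpBlock(up_in[i], skips[i], uc[i], cfg.bottlenecks_up[i], cfg, rng)
            for i in range(4)
        ]
        self.output_block = nn.Conv3d(uc[3], cfg.n_classes, 1, rng=rng)

    # -- introspection -------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.cfg.n_classes

    def params(self) -> list[nn.Param]:
        ps = self.input_block.params()
        for b in self.down:
            ps += b.params()
        for b in self.up:
            ps += b.params()
        ps += self.output_block.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def n_layers(self) -> int:
        def count(layer):
            if isinstance(layer, nn.Sequential):
                return sum(count(l) for l in layer.layers)
            if isinstance(layer, Bottleneck):
                return count(layer.body)
            return 1 if isinstance(layer, (nn.Conv3d, nn.ConvTranspose2x)) else 0

        n = count(self.input_block) + count(self.output_block) + 0
        for b in self.down:
            n += count(b.seq)
        for b in self.up:
            n += count(nn.Sequential(b.up, b.tail)) + (
                count(b.merge) if b.mode == "concat" else 0
            )
        return n

    # -- forward / backward --------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ShapeError(f"expected (N, C, D, H, W) input, got shape {x.shape}")
        bad = [d for d in x.shape[2:] if d % DOWN_FACTOR]
        if bad:
            raise ShapeError(
                f"every spatial dimension must be a multiple of {DOWN_FACTOR}; "
                f"got {x.shape[2:]}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_shape(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        f0 = self.input_block.forward(x, train=train)
        f1 = self.down[0].forward(f0, train=train)
        f2 = self.down[1].forward(f1, train=train)
        f3 = self.down[2].forward(f2, train=train)
        z = self.down[3].forward(f3, train=train)
        z = self.up[0].forward(z, f3, train=train)
        z = self.up[1].forward(z, f2, train=train)
        z = self.up[2].forward(z, f1, train=train)
        z = self.up[3].forward(z, f0, train=train)
        return self.output_block.forward(z, train=train)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.output_block.backward(glogits)
        gskips = []
        for blk in reversed(self.up):
            g, gs = blk.backward(g)
            gskips.append(gs)
        g0, g1, g2, g3 = gskips  # grads for f0, f1, f2, f3
        g = self.down[3].backward(g)
        g = self.down[2].backward(g + g3)
        g = self.down[1].backward(g + g2)
        g = self.down[0].backward(g + g1)
        self.input_block.backward(g + g0)

    def predict(self, x: np.ndarray, geometry=None) -> np.ndarray:
        """Per-voxel class probabilities, (N, n_classes, D, H, W); eval mode.

        ``geometry`` is accepted (and ignored) so that geometry-aware stand-in
        predictors can share this interface in the cascade.
        """
        logits = self.forward_logits(np.asarray(x, dtype=np.float32), train=False)
        return nn.softmax(logits, axis=1)

    # -- checkpointing --------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "VBNet":
        with np.load(path) as z:
            cfg_dict = json.loads(bytes(z["config_json"]).decode())
            for key in ("down_channels", "up_channels", "bottlenecks_down", "bottlenecks_up"):
                cfg_dict[key] = tuple(cfg_dict[key])
            net = cls(NetConfig(**cfg_dict))
            for i, p in enumerate(net.params()):
                val = z[f"p{i}"]
                if val.shape != p.value.shape:  # pragma: no cover
                    raise ConfigurationError(f"checkpoint parameter {i} shape mismatch")
                p.value = val.astype(np.float32)
        return net


def build_network(cfg: NetConfig, seed: int = 0) -> VBNet:
    """Construct a VB-Net from its configuration with seeded initialization."""
    return VBNet(cfg, seed=seed)


def forward(net: VBNet, patch: np.ndarray) -> np.ndarray:
    """Run one evaluation-mode forward pass -> per-class probability block.

    Accepts a bare (D, H, W) patch, (C, D, H, W) or a full (N, C, D, H, W)
    batch; the output matches the input's spatial shape with a leading class
    axis (batch axis preserved if given).
    """
    patch = np.asarray(patch, dtype=np.float32)
    squeeze = 0
    if patch.ndim == 3:
        patch = patch[None, None]
        squeeze = 2
    elif patch.ndim == 4:
        patch = patch[None]
        squeeze = 1
    probs = net.predict(patch)
    return probs[0] if squeeze else probs
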