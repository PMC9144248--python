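"""Segmentation networks: a single-image UNet and the dual-stream MI-UNet.

The UNet is the conventional bidimensional encoder-decoder: each level is
(conv3x3 -> BN -> ReLU) x 2, max pooling between encoder levels, 2x2
stride-2 transposed convolutions on the way up, skip connections by
channel concatenation between equal levels, and a final 1x1 convolution
to class scores followed by a per-pixel softmax.

The MI-UNet processes a co-located image pair (cine-SSFP-like and
LGE-like) with two independent encoders and two independent decoders.
At the join level the two streams' feature maps are summed elementwise
and pass through a single shared block — by default only the deepest
level (the bottom of the "U") is shared, giving the two streams a common
deep embedding. The two outputs are never fused; each decoder receives
skip connections only from its own (or the shared) encoder levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigurationError, DimensionError
from .nn import Conv2d, ConvTranspose2d, DoubleConv, Module, Tensor, concat

__all__ = [
    "ModelConfig",
    "UNet",
    "MIUNet",
    "build_unet",
    "build_mi_unet",
    "count_parameters",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description shared by UNet and MI-UNet.

    depth counts levels including the bottleneck; channel width doubles
    per level starting from base_channels. join_level is the level at
    which the MI-UNet streams are additively joined (1-based; levels at
    and below it are shared); None means the deepest level only.
    """

    depth: int = 5
    base_channels: int = 64
    in_channels: int = 1
    n_classes: int = 4
    batch_norm: bool = True
    join_level: int | None = None
    init_sigma: float | str = "he"  # "he" for He scaling, or a fixed std

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        j = self.resolved_join_level
        if not 1 <= j <= self.depth:
            raise ConfigurationError(
                f"join_level {j} outside [1, {self.depth}]"
            )

    @property
    def resolved_join_level(self) -> int:
        return self.depth if self.join_level is None else self.join_level

    @property
    def stride_factor(self) -> int:
        return 2 ** (self.depth - 1)

    def channels(self, level: int) -> int:
        """Output channels of encoder level (1-based)."""
        return self.base_channels * 2 ** (level - 1)


def _check_input_size(config: ModelConfig, h: int, w: int):
    f = config.stride_factor
    if h % f or w % f:
        raise ConfigurationError(
            f"input spatial size {h}x{w} not divisible by 2^(depth-1) = {f}"
        )


class _Decoder(Module):
    """Upsampling path: transpose conv, concat skip, double conv per level."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.ups = []
        self.blocks = []
        for level in range(config.depth - 1, 0, -1):
            cin = config.channels(level + 1)
            cout = config.channels(level)
            self.ups.append(
                ConvTranspose2d(cin, cout, rng, config.init_sigma)
            )
            self.blocks.append(
                DoubleConv(2 * cout, cout, rng, config.batch_norm, config.init_sigma)
            )
        self.head = Conv2d(
            config.base_channels, config.n_classes, 1, 0, rng, config.init_sigma
        )

    def __call__(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        x = bottom
        for up, block, skip in zip(self.ups, self.blocks, reversed(skips)):
            x = up(x)
            x = block(concat([skip, x], axis=1))
        return self.head(x).softmax(axis=1)


class UNet(Module):
    """Single-image encoder-decoder segmentation network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = [
            DoubleConv(
                config.in_channels if lvl == 1 else config.channels(lvl - 1),
                config.channels(lvl),
                rng,
                config.batch_norm,
                config.init_sigma,
            )
            for lvl in range(1, config.depth)
        ]
        self.bottleneck = DoubleConv(
            config.channels(config.depth - 1),
            config.channels(config.depth),
            rng,
            config.batch_norm,
            config.init_sigma,
        )
        self.decoder = _Decoder(config, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise DimensionError(f"expected NCHW input, got shape {x.shape}")
        _check_input_size(self.config, x.shape[2], x.shape[3])
        skips = []
        for block in self.encoder:
            x = block(x)
            skips.append(x)
            x = x.maxpool2x2()
        x = self.bottleneck(x)
        return self.decoder(x, skips)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode forward on (N, H, W) or (N, 1, H, W) arrays."""
        was_training = self.training
        self.eval()
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = self(Tensor(x)).data
        if was_training:
            self.train()
        return out


class MIUNet(Module):
    """Dual-stream network with an additively joined shared deep embedding."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        j = config.resolved_join_level

        def make_levels(lo, hi):
            return [
                DoubleConv(
                    config.in_channels if lvl == 1 else config.channels(lvl - 1),
                    config.channels(lvl),
                    rng,
                    config.batch_norm,
                    config.init_sigma,
                )
                for lvl in range(lo, hi)
            ]

        # private encoder levels 1..j-1 per stream, shared levels j..depth-1,
        # shared bottleneck (level `depth`); the additive join happens at the
        # entry to level j
        self.encoder_cine = make_levels(1, j)
        self.encoder_lge = make_levels(1, j)
        self.shared_encoder = make_levels(j, config.depth) if j < config.depth else []
        self.shared_bottleneck = DoubleConv(
            config.channels(config.depth - 1),
            config.channels(config.depth),
            rng,
            config.batch_norm,
            config.init_sigma,
        )
        self.decoder_cine = _Decoder(config, rng)
        self.decoder_lge = _Decoder(config, rng)

    def __call__(self, x_cine: Tensor, x_lge: Tensor) -> tuple[Tensor, Tensor]:
        cfg = self.config
        for x in (x_cine, x_lge):
            if x.ndim != 4 or x.shape[1] != cfg.in_channels:
                raise DimensionError(f"expected NCHW inputs, got {x.shape}")
        if x_cine.shape != x_lge.shape:
            raise DimensionError("paired inputs must share a shape")
        _check_input_size(cfg, x_cine.shape[2], x_cine.shape[3])
        j = cfg.resolved_join_level

        skips_cine: list[Tensor] = []
        skips_lge: list[Tensor] = []
        a, b = x_cine, x_lge
        for block in self.encoder_cine:
            a = block(a)
            skips_cine.append(a)
            a = a.maxpool2x2()
        for block in self.encoder_lge:
            b = block(b)
            skips_lge.append(b)
            b = b.maxpool2x2()

        x = a + b  # additive join of the two streams
        for block in self.shared_encoder:
            x = block(x)
            skips_cine.append(x)
            skips_lge.append(x)
            x = x.maxpool2x2()
        x = self.shared_bottleneck(x)

        return (
            self.decoder_cine(x, skips_cine),
            self.decoder_lge(x, skips_lge),
        )

    def predict_proba(self, cine: np.ndarray, lge: np.ndarray):
        was_training = self.training
        self.eval()
        xc = np.asarray(cine, dtype=np.float32)
        xl = np.asarray(lge, dtype=np.float32)
        if xc.ndim == 3:
            xc, xl = xc[:, None], xl[:, None]
        pc, pl = self(Tensor(xc), Tensor(xl))
        if was_training:
            self.train()
        return pc.data, pl.data


def build_unet(config: ModelConfig, seed: int = 0) -> UNet:
    return UNet(config, seed)


def build_mi_unet(config: ModelConfig, seed: int = 0) -> MIUNet:
    return MIUNet(config, seed)


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))
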