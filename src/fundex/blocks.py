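"""Residual contraction and expansion blocks.

The codec's encoders are stacks of *contraction* blocks (halve the spatial
side, grow the channel count) and its decoders are stacks of *expansion*
blocks (double the spatial side, shrink the channel count, with transposed
convolutions on the main path).  Both are residual: a projection shortcut
matches the shape change and the two paths are summed before the final
leaky-rectifier activation.  A *group* chains two blocks, quartering or
quadrupling the spatial side.

Layer choices not pinned by the endpoint dimensions: 3×3 kernels with a
stride-2 convolution for contraction, a 4×4 stride-2 transposed convolution
for expansion, and 1×1 (or 2×2 transposed) projection shortcuts.  Parameter
counts are pure functions of the channel configuration and are frozen by the
test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Conv2d, ConvTranspose2d, Module, Tensor

__all__ = [
    "BlockConfig", "ContractionBlock", "ExpansionBlock",
    "ContractionGroup", "ExpansionGroup", "LEAKY_SLOPE",
]

LEAKY_SLOPE = 0.01  # leaky-rectifier negative slope used throughout the codec


@dataclasses.dataclass(frozen=True)
class BlockConfig:
    in_channels: int
    out_channels: int
    leaky_slope: float = LEAKY_SLOPE

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")


class ContractionBlock(Module):
    """C×S×S → C'×(S/2)×(S/2); requires S even."""

    def __init__(self, cfg: BlockConfig, *, rng: np.random.Generator):
        self.cfg = cfg
        self.conv1 = Conv2d(cfg.in_channels, cfg.out_channels, 3, stride=2,
                            padding=1, rng=rng)
        self.conv2 = Conv2d(cfg.out_channels, cfg.out_channels, 3, stride=1,
                            padding=1, rng=rng)
        self.proj = Conv2d(cfg.in_channels, cfg.out_channels, 1, stride=2,
                           padding=0, rng=rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        s = x.shape[-1]
        if s % 2 != 0:
            raise ValueError(f"contraction needs an even spatial side, got {s}")
        h = self.conv1(x).leaky_relu(self.cfg.leaky_slope)
        h = self.conv2(h)
        return (h + self.proj(x)).leaky_relu(self.cfg.leaky_slope)


class ExpansionBlock(Module):
    """C×S×S → C'×2S×2S via transposed convolution on the main path."""

    def __init__(self, cfg: BlockConfig, *, rng: np.random.Generator):
        self.cfg = cfg
        self.deconv = ConvTranspose2d(cfg.in_channels, cfg.out_channels, 4,
                                      stride=2, padding=1, rng=rng)
        self.conv = Conv2d(cfg.out_channels, cfg.out_channels, 3, stride=1,
                           padding=1, rng=rng)
        self.proj = ConvTranspose2d(cfg.in_channels, cfg.out_channels, 2,
                                    stride=2, padding=0, rng=rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h = self.deconv(x).leaky_relu(self.cfg.leaky_slope)
        h = self.conv(h)
        return (h + self.proj(x)).leaky_relu(self.cfg.leaky_slope)


class ContractionGroup(Module):
    """Two chained contraction blocks: S → S/4, in_ch → mid_ch → out_ch."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, *,
                 rng: np.random.Generator):
        self.b1 = ContractionBlock(BlockConfig(in_ch, mid_ch), rng=rng)
        self.b2 = ContractionBlock(BlockConfig(mid_ch, out_ch), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.b2(self.b1(x))


class ExpansionGroup(Module):
    """Two chained expansion blocks: S → 4S, in_ch → mid_ch → out_ch."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, *,
                 rng: np.random.Generator):
        self.b1 = ExpansionBlock(BlockConfig(in_ch, mid_ch), rng=rng)
        self.b2 = ExpansionBlock(BlockConfig(mid_ch, out_ch), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.b2(self.b1(x))
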