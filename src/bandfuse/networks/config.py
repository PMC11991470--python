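"""Architecture configuration records."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["NetworkConfig", "CresSpec", "CattSpec", "BACKBONE_ARCHS", "ALL_ARCHS"]

BACKBONE_ARCHS = ("resnet50", "densenet201", "mobilenetv2")
ALL_ARCHS = BACKBONE_ARCHS + ("cres", "catt", "tinycnn")


@dataclass
class NetworkConfig:
    """What to build: architecture, input channels/size, class count.

    The three classic backbones are RGB networks and require exactly three
    input channels; the custom multichannel networks accept any number of
    bands.
    """

    arch_id: str
    in_channels: int
    n_classes: int
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.arch_id not in ALL_ARCHS:
            raise ValueError(f"unknown arch_id {self.arch_id!r}; choose from {ALL_ARCHS}")
        if self.arch_id in BACKBONE_ARCHS and self.in_channels != 3:
            raise ValueError(
                f"{self.arch_id} is a 3-channel backbone; got in_channels={self.in_channels}"
            )
        if self.in_channels < 1 or self.n_classes < 1:
            raise ValueError("in_channels and n_classes must be >= 1")
        self.input_size = tuple(self.input_size)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "arch_id": self.arch_id, "in_channels": self.in_channels,
            "n_classes": self.n_classes, "input_size": list(self.input_size)}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(arch_id=d["arch_id"], in_channels=d["in_channels"],
                   n_classes=d["n_classes"],
                   input_size=tuple(d.get("input_size", (64, 64))))


@dataclass
class CresSpec:
    """The inception-in-residual hybrid CNN.

    A stem convolution with 64 filters feeds three macroblocks; channels
    double per macroblock (128, 256, 512) while 2×2 max pooling after each
    halves height and width, leaving a 512-channel 4×4 map for a 64×64
    input.  Each macroblock embeds a four-branch inception transform in a
    residual connection whose 1×1 convolution aligns shapes.
    """

    stem_filters: int = 64
    filters_per_block: tuple[int, ...] = (128, 256, 512)
    fc_widths: tuple[int, int] = (1024, 256)

    def __post_init__(self) -> None:
        for prev, cur in zip((self.stem_filters,) + tuple(self.filters_per_block),
                             self.filters_per_block):
            if cur != 2 * prev:
                raise ValueError(
                    f"channel count must double per macroblock, got {prev} -> {cur}")
        if any(f % 4 for f in self.filters_per_block):
            raise ValueError("macroblock filters must split across 4 branches")

    @property
    def n_macroblocks(self) -> int:
        return len(self.filters_per_block)


@dataclass
class CattSpec:
    """The 3-D CNN + Transformer-encoder attention network.

    Three Conv3D(3×3×3) → BatchNorm3D → Tanh blocks with 1×2×2 pooling
    (spatial only, spectral depth preserved) end in adaptive average
    pooling to a fixed 1×8×8 map whose 64 spatial positions become the
    encoder's tokens.
    """

    conv_channels: tuple[int, int, int] = (32, 64, 128)
    pooled_hw: tuple[int, int] = (8, 8)
    n_encoder_layers: int = 6
    d_model: int = 256
    n_heads: int = 8
    ffn_width: int = 512

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def n_tokens(self) -> int:
        return self.pooled_hw[0] * self.pooled_hw[1]
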