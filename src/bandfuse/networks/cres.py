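"""Cres: an inception-in-residual hybrid CNN for multichannel input.

The multichannel image passes through a 64-filter stem convolution and
2×2 max pooling, then three macroblocks.  Each macroblock embeds a
four-branch inception transform (1×1; 1×1→3×3; 1×1→5×5; 3×3 max-pool→1×1,
each branch carrying one-fourth of the block's filters) inside a residual
connection whose 1×1 convolution projects the block input to the output
width.  Channels double per macroblock while a trailing 2×2 max pool
halves the spatial size, so a 64×64 input leaves the last macroblock as a
512×4×4 map that a three-layer fully-connected head turns into logits.

Every convolution except the residual 1×1 is followed by batch
normalization; activations are ReLU throughout, including after the
residual addition.
"""

from __future__ import annotations

import numpy as np

from ..nn import (BatchNorm, Conv2d, Flatten, Linear, MaxPool2d, Module,
                  ReLU, Sequential, concat, maxpool2d_3x3s1)
from .config import CresSpec, NetworkConfig

__all__ = ["Cres", "build_cres"]


def _conv_bn_relu(in_ch, out_ch, k, rng, padding=0):
    return Sequential(Conv2d(in_ch, out_ch, k, rng, padding=padding),
                      BatchNorm(out_ch), ReLU())


class _InceptionBlock(Module):
    """Four parallel branches, each emitting filters/4 channels."""

    def __init__(self, in_ch: int, filters: int, rng):
        super().__init__()
        q = filters // 4
        self.branch1 = _conv_bn_relu(in_ch, q, 1, rng)
        self.branch2 = Sequential(_conv_bn_relu(in_ch, q, 1, rng),
                                  _conv_bn_relu(q, q, 3, rng, padding=1))
        self.branch3 = Sequential(_conv_bn_relu(in_ch, q, 1, rng),
                                  _conv_bn_relu(q, q, 5, rng, padding=2))
        self.branch4 = _conv_bn_relu(in_ch, q, 1, rng)  # applied after 3×3 pool

    def forward(self, x):
        pooled = maxpool2d_3x3s1(x)
        return concat([self.branch1(x), self.branch2(x), self.branch3(x),
                       self.branch4(pooled)], axis=1)


class _Macroblock(Module):
    """Inception transform + 1×1-convolution residual, ReLU after the add."""

    def __init__(self, in_ch: int, filters: int, rng):
        super().__init__()
        self.inception = _InceptionBlock(in_ch, filters, rng)
        self.residual = Conv2d(in_ch, filters, 1, rng)  # no BatchNorm here

    def forward(self, x):
        return (self.inception(x) + self.residual(x)).relu()


class Cres(Module):
    def __init__(self, spec: CresSpec, cfg: NetworkConfig, rng):
        super().__init__()
        h, w = cfg.input_size
        self.divisor = 2 ** (1 + spec.n_macroblocks)
        if h % self.divisor or w % self.divisor:
            raise ValueError(
                f"input size {h}x{w} must be divisible by {self.divisor} "
                f"(stem pool + {spec.n_macroblocks} macroblock pools)")
        self.spec, self.cfg = spec, cfg
        self.stem = Sequential(
            Conv2d(cfg.in_channels, spec.stem_filters, 3, rng, padding=1),
            BatchNorm(spec.stem_filters), ReLU(), MaxPool2d(2))
        blocks: list[Module] = []
        in_ch = spec.stem_filters
        for f in spec.filters_per_block:
            blocks.append(_Macroblock(in_ch, f, rng))
            blocks.append(MaxPool2d(2))
            in_ch = f
        self.blocks = blocks
        flat = in_ch * (h // self.divisor) * (w // self.divisor)
        w1, w2 = spec.fc_widths
        self.head = Sequential(Flatten(),
                               Linear(flat, w1, rng), ReLU(),
                               Linear(w1, w2, rng), ReLU(),
                               Linear(w2, cfg.n_classes, rng, gain="glorot"))

    def forward_features(self, x):
        """The pre-flatten feature map (512×4×4 for a 64×64 input)."""
        x = self.stem(x)
        for block in self.blocks:
            x = block(x)
        return x

    def forward(self, x):
        return self.head(self.forward_features(x))


def build_cres(spec: CresSpec | None, cfg: NetworkConfig,
               rng: np.random.Generator | int = 0) -> Cres:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return Cres(spec or CresSpec(), cfg, rng)
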