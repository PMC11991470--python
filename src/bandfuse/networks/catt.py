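"""Catt: 3-D convolutional backbone + Transformer encoder.

Bands occupy the depth axis of the 3-D convolutions (a singleton feature
axis is prepended), so a C-band H×W pattern enters as a (1, C, H, W)
volume.  Three Conv3D(3×3×3) → BatchNorm3D → Tanh blocks extract joint
spatio-spectral features; the first two are followed by 1×2×2 max pooling
that halves height and width while preserving the spectral depth, and the
third by adaptive average pooling to a fixed 1×8×8 map regardless of the
input's spatial size.

The 64 spatial positions of the pooled map become tokens (channels are
the feature vector), linearly projected to ``d_model``, summed with
sinusoidal positional encodings, and passed through six Transformer
encoder layers — multi-head self-attention softmax(QKᵀ/√d_k)V plus a
position-wise FFN max(0, XW₁+b₁)W₂+b₂ with residual connections and layer
normalization.  Mean-pooling over encoder outputs feeds the linear
classification head.
"""

from __future__ import annotations

import numpy as np

from ..nn import (BatchNorm, Conv3d, Linear, Module, Tanh, Tensor,
                  TransformerEncoderLayer, adaptive_avg_pool_hw, maxpool_hw,
                  sinusoidal_positional_encoding)
from .config import CattSpec, NetworkConfig

__all__ = ["Catt", "build_catt"]


class _ConvBlock3d(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, 3, rng, padding=1)
        self.bn = BatchNorm(out_ch)
        self.act = Tanh()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Catt(Module):
    def __init__(self, spec: CattSpec, cfg: NetworkConfig, rng):
        super().__init__()
        h, w = cfg.input_size
        oh, ow = spec.pooled_hw
        if h < oh or w < ow:
            raise ValueError(f"input {h}x{w} smaller than the {oh}x{ow} pooled map")
        self.spec, self.cfg = spec, cfg
        c1, c2, c3 = spec.conv_channels
        self.block1 = _ConvBlock3d(1, c1, rng)
        self.block2 = _ConvBlock3d(c1, c2, rng)
        self.block3 = _ConvBlock3d(c2, c3, rng)
        self.proj = Linear(c3, spec.d_model, rng, gain="glorot")
        self.pe = sinusoidal_positional_encoding(spec.n_tokens, spec.d_model)
        self.encoders = [TransformerEncoderLayer(spec.d_model, spec.n_heads,
                                                 spec.ffn_width, rng)
                         for _ in range(spec.n_encoder_layers)]
        self.head = Linear(spec.d_model, cfg.n_classes, rng, gain="glorot")

    def forward_pooled(self, x):
        """The 1×8×8-per-channel pooled map, shape (N, C3, 8, 8)."""
        if x.ndim == 4:                      # (N, bands, H, W) -> add feature axis
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h, w = x.shape[-2:]
        oh, ow = self.spec.pooled_hw
        if h < oh or w < ow:
            raise ValueError(f"input {h}x{w} smaller than the {oh}x{ow} pooled map")
        x = maxpool_hw(self.block1(x), 2)    # 1×2×2: spectral depth untouched
        x = maxpool_hw(self.block2(x), 2)
        x = self.block3(x)
        x = x.mean(axis=2)                   # collapse spectral depth to 1
        return adaptive_avg_pool_hw(x, self.spec.pooled_hw)

    def forward(self, x):
        pooled = self.forward_pooled(x)
        n, c = pooled.shape[:2]
        tokens = pooled.reshape(n, c, self.spec.n_tokens).swapaxes(1, 2)
        z = self.proj(tokens) + Tensor(self.pe[None])
        for enc in self.encoders:
            z = enc(z)
        return self.head(z.mean(axis=1))


def build_catt(spec: CattSpec | None, cfg: NetworkConfig,
               rng: np.random.Generator | int = 0) -> Catt:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return Catt(spec or CattSpec(), cfg, rng)
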