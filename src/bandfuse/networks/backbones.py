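"""Classic 3-channel RGB backbones: ResNet50, DenseNet201, MobileNetV2.

These follow the published architectures (bottleneck residual stages
3-4-6-3 for ResNet50; dense blocks 6-12-48-32 with growth rate 32 and
half-compression transitions for DenseNet201; inverted residual blocks
with expansion 6 and ReLU6 for MobileNetV2), built on the package's own
NumPy engine with He initialization.  The classification head is a fresh
linear layer sized to the task's class count, all layers trainable.
Global average pooling makes every backbone input-size agnostic down to
small rasters.  External checkpoints can be loaded through
``load_state_dict`` when trained weights are available.
"""

from __future__ import annotations

import numpy as np

from ..nn import (BatchNorm, Conv2d, DepthwiseConv2d, GlobalAvgPool2d,
                  Linear, Module, ReLU, Sequential, adaptive_avg_pool_hw,
                  concat, maxpool2d)
from .config import NetworkConfig

__all__ = ["ResNet50", "DenseNet201", "MobileNetV2", "build_backbone"]


def _conv_bn(in_ch, out_ch, k, rng, stride=1, padding=0):
    return Sequential(Conv2d(in_ch, out_ch, k, rng, stride=stride,
                             padding=padding, bias=False),
                      BatchNorm(out_ch))


# ---------------------------------------------------------------------------
# ResNet50
# ---------------------------------------------------------------------------

class _Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch, width, rng, stride=1):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = _conv_bn(in_ch, width, 1, rng)
        self.conv2 = _conv_bn(width, width, 3, rng, stride=stride, padding=1)
        self.conv3 = _conv_bn(width, out_ch, 1, rng)
        self.down = (_conv_bn(in_ch, out_ch, 1, rng, stride=stride)
                     if stride != 1 or in_ch != out_ch else None)

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        out = self.conv1(x).relu()
        out = self.conv2(out).relu()
        return (self.conv3(out) + identity).relu()


class ResNet50(Module):
    stage_widths = (64, 128, 256, 512)
    stage_depths = (3, 4, 6, 3)

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.stem = _conv_bn(3, 64, 7, rng, stride=2, padding=3)
        blocks: list[Module] = []
        in_ch = 64
        for s, (width, depth) in enumerate(zip(self.stage_widths, self.stage_depths)):
            for b in range(depth):
                stride = 2 if (b == 0 and s > 0) else 1
                blocks.append(_Bottleneck(in_ch, width, rng, stride=stride))
                in_ch = width * _Bottleneck.expansion
        self.blocks = blocks
        self.pool = GlobalAvgPool2d()
        self.head = Linear(in_ch, cfg.n_classes, rng, gain="glorot")

    def forward(self, x):
        x = maxpool2d(self.stem(x).relu(), 3, stride=2, padding=1)
        for block in self.blocks:
            x = block(x)
        return self.head(self.pool(x))


# ---------------------------------------------------------------------------
# DenseNet201
# ---------------------------------------------------------------------------

class _DenseLayer(Module):
    def __init__(self, in_ch, growth, rng):
        super().__init__()
        self.bn1 = BatchNorm(in_ch)
        self.conv1 = Conv2d(in_ch, 4 * growth, 1, rng, bias=False)
        self.bn2 = BatchNorm(4 * growth)
        self.conv2 = Conv2d(4 * growth, growth, 3, rng, padding=1, bias=False)

    def forward(self, x):
        out = self.conv1(self.bn1(x).relu())
        out = self.conv2(self.bn2(out).relu())
        return concat([x, out], axis=1)


class _Transition(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.bn = BatchNorm(in_ch)
        self.conv = Conv2d(in_ch, out_ch, 1, rng, bias=False)

    def forward(self, x):
        x = self.conv(self.bn(x).relu())
        h, w = x.shape[-2:]
        return adaptive_avg_pool_hw(x, (h // 2, w // 2))  # exact 2×2 mean pool


class DenseNet201(Module):
    growth = 32
    block_depths = (6, 12, 48, 32)

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.stem = _conv_bn(3, 64, 7, rng, stride=2, padding=3)
        layers: list[Module] = []
        ch = 64
        for i, depth in enumerate(self.block_depths):
            for _ in range(depth):
                layers.append(_DenseLayer(ch, self.growth, rng))
                ch += self.growth
            if i < len(self.block_depths) - 1:
                layers.append(_Transition(ch, ch // 2, rng))
                ch //= 2
        self.layers = layers
        self.bn_final = BatchNorm(ch)
        self.pool = GlobalAvgPool2d()
        self.head = Linear(ch, cfg.n_classes, rng, gain="glorot")

    def forward(self, x):
        x = maxpool2d(self.stem(x).relu(), 3, stride=2, padding=1)
        for layer in self.layers:
            x = layer(x)
        return self.head(self.pool(self.bn_final(x).relu()))


# ---------------------------------------------------------------------------
# MobileNetV2
# ---------------------------------------------------------------------------

class _InvertedResidual(Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, expand=6):
        super().__init__()
        hidden = in_ch * expand
        self.expand = _conv_bn(in_ch, hidden, 1, rng) if expand != 1 else None
        self.dw = DepthwiseConv2d(hidden, 3, rng, stride=stride, padding=1,
                                  bias=False)
        self.dw_bn = BatchNorm(hidden)
        self.project = _conv_bn(hidden, out_ch, 1, rng)
        self.use_skip = stride == 1 and in_ch == out_ch

    def forward(self, x):
        h = self.expand(x).relu6() if self.expand is not None else x
        h = self.dw_bn(self.dw(h)).relu6()
        h = self.project(h)
        return x + h if self.use_skip else h


class MobileNetV2(Module):
    # (expansion, out_channels, repeats, first stride)
    settings = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1))

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.stem = _conv_bn(3, 32, 3, rng, stride=2, padding=1)
        blocks: list[Module] = []
        in_ch = 32
        for t, c, n, s in self.settings:
            for b in range(n):
                blocks.append(_InvertedResidual(in_ch, c, rng,
                                                stride=s if b == 0 else 1,
                                                expand=t))
                in_ch = c
        self.blocks = blocks
        self.final = _conv_bn(in_ch, 1280, 1, rng)
        self.pool = GlobalAvgPool2d()
        self.head = Linear(1280, cfg.n_classes, rng, gain="glorot")

    def forward(self, x):
        x = self.stem(x).relu6()
        for block in self.blocks:
            x = block(x)
        return self.head(self.pool(self.final(x).relu6()))


_BACKBONES = {"resnet50": ResNet50, "densenet201": DenseNet201,
              "mobilenetv2": MobileNetV2}


def build_backbone(cfg: NetworkConfig, rng: np.random.Generator | int = 0,
                   weights: dict | None = None) -> Module:
    """Build a 3-channel backbone with a task-sized classification head.

    ``weights`` (a state dict from a previous checkpoint) is loaded when
    given; otherwise all layers start from He/Glorot random draws.  Every
    layer is trainable — nothing is frozen.
    """
    if cfg.arch_id not in _BACKBONES:
        raise ValueError(f"{cfg.arch_id!r} is not a 3-channel backbone")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    net = _BACKBONES[cfg.arch_id](cfg, rng)
    if weights is not None:
        net.load_state_dict(weights)
    return net
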