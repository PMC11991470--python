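"""A deliberately small CNN for desk-scale experiments.

Two convolution/pool stages, global average pooling and a linear head:
well under 50k parameters, input-size agnostic, trains in seconds on a
CPU.  It plays the role a fine-tuned ImageNet backbone plays at full
scale, so end-to-end ensemble behavior can be exercised quickly.
"""

from __future__ import annotations

import numpy as np

from ..nn import (BatchNorm, Conv2d, GlobalAvgPool2d, Linear, MaxPool2d,
                  Module, ReLU, Sequential)
from .config import NetworkConfig

__all__ = ["TinyCNN", "build_tinycnn"]


class TinyCNN(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        # batch norm keeps low-contrast bands trainable in few epochs
        self.features = Sequential(
            Conv2d(cfg.in_channels, 8, 3, rng, padding=1), BatchNorm(8),
            ReLU(), MaxPool2d(2),
            Conv2d(8, 16, 3, rng, padding=1), BatchNorm(16),
            ReLU(), MaxPool2d(2),
        )
        self.pool = GlobalAvgPool2d()
        self.head = Linear(16, cfg.n_classes, rng, gain="glorot")

    def forward(self, x):
        return self.head(self.pool(self.features(x)))


def build_tinycnn(cfg: NetworkConfig, rng: np.random.Generator | int = 0) -> TinyCNN:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return TinyCNN(cfg, rng)
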