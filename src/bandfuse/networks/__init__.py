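"""Network factory: classic RGB backbones and custom multichannel nets."""

from __future__ import annotations

import numpy as np

from ..nn import Module
from .backbones import DenseNet201, MobileNetV2, ResNet50, build_backbone
from .catt import Catt, build_catt
from .config import ALL_ARCHS, BACKBONE_ARCHS, CattSpec, CresSpec, NetworkConfig
from .cres import Cres, build_cres
from .tiny import TinyCNN, build_tinycnn

__all__ = ["NetworkConfig", "CresSpec", "CattSpec", "ALL_ARCHS",
           "BACKBONE_ARCHS", "ResNet50", "DenseNet201", "MobileNetV2",
           "Cres", "Catt", "TinyCNN", "build_backbone", "build_cres",
           "build_catt", "build_tinycnn", "build_network"]


def build_network(cfg: NetworkConfig, rng: np.random.Generator | int = 0,
                  spec=None) -> Module:
    """Build any supported architecture from its config.

    ``spec`` optionally carries a :class:`CresSpec` or :class:`CattSpec`
    for the custom networks; backbones ignore it.
    """
    if cfg.arch_id in BACKBONE_ARCHS:
        return build_backbone(cfg, rng)
    if cfg.arch_id == "cres":
        return build_cres(spec, cfg, rng)
    if cfg.arch_id == "catt":
        return build_catt(spec, cfg, rng)
    return build_tinycnn(cfg, rng)
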