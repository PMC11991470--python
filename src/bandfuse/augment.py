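"""Offline data augmentation.

Each normalized training pattern is expanded into four: the original,
its top–bottom reflection, its left–right reflection, and an
anisotropically scaled copy.  Scaling draws two independent factors from
U(1, 2) — one per axis — magnifies the image bilinearly and center-crops
back to the original height × width, so batch shapes never change.  All
bands of a pattern are transformed identically (channel-coherent).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import LabeledDataset, MultibandImage

__all__ = ["augment_pattern", "augment_dataset"]


def _scale_crop(pixels: np.ndarray, fy: float, fx: float) -> np.ndarray:
    h, w = pixels.shape[:2]
    zoomed = ndimage.zoom(pixels, (fy, fx, 1), order=1)
    i0 = (zoomed.shape[0] - h) // 2
    j0 = (zoomed.shape[1] - w) // 2
    return zoomed[i0:i0 + h, j0:j0 + w]


def augment_pattern(img: MultibandImage, rng: np.random.Generator,
                    scale_range: tuple[float, float] = (1.0, 2.0)
                    ) -> list[MultibandImage]:
    """Return ``[original, top–bottom flip, left–right flip, scaled]``."""
    fy, fx = rng.uniform(*scale_range, size=2)
    variants = [
        img.pixels,
        img.pixels[::-1, :, :],
        img.pixels[:, ::-1, :],
        _scale_crop(img.pixels, fy, fx),
    ]
    return [MultibandImage(pixels=np.ascontiguousarray(p),
                           band_ids=list(img.band_ids),
                           pattern_id=f"{img.pattern_id}#aug{i}")
            for i, p in enumerate(variants)]


def augment_dataset(ds: LabeledDataset, rng: np.random.Generator,
                    scale_range: tuple[float, float] = (1.0, 2.0)
                    ) -> LabeledDataset:
    """Materialize the ×4 offline augmentation; labels are replicated."""
    images, labels = [], []
    for img, label in zip(ds.images, ds.labels):
        for variant in augment_pattern(img, rng, scale_range):
            images.append(variant)
            labels.append(label)
    return LabeledDataset(images=images, labels=np.asarray(labels),
                          class_names=list(ds.class_names))
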