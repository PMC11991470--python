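"""Core containers for multiband raster patterns.

A *pattern* is one labeled sample: ``n_bands`` co-registered single-band
2-D rasters sharing a height and width (e.g. the 13 spectral bands of a
Sentinel-2 tile, or the 16 illumination angles of a foraminifera
microscopy stack).  Bands are stored on the trailing axis, so ``pixels``
has shape ``(height, width, n_bands)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultibandImage", "LabeledDataset"]


@dataclass
class MultibandImage:
    """One multiband pattern.

    Parameters
    ----------
    pixels
        Array of shape ``(height, width, n_bands)``.  Raw (pre-normalization)
        values are non-negative reals; normalized values are ``uint8``.
    band_ids
        Ordered band labels, e.g. ``["B02", ..., "B12"]`` or
        ``["illum_00", ..., "illum_15"]``.
    pattern_id
        Opaque identifier carried through scoring so that multiple views of
        the same pattern can be re-grouped.
    """

    pixels: np.ndarray
    band_ids: list[str]
    pattern_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pattern {self.pattern_id!r}: pixels must be (H, W, n_bands), "
                f"got shape {self.pixels.shape}"
            )
        if self.n_bands < 1:
            raise ValueError(f"pattern {self.pattern_id!r}: needs at least one band")
        if len(self.band_ids) != self.n_bands:
            raise ValueError(
                f"pattern {self.pattern_id!r}: {len(self.band_ids)} band_ids for "
                f"{self.n_bands} bands"
            )
        if not np.issubdtype(self.pixels.dtype, np.unsignedinteger):
            if np.any(np.asarray(self.pixels) < 0):
                raise ValueError(
                    f"pattern {self.pattern_id!r}: negative pixel values are not allowed"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Return one 2-D band plane (a view, not a copy)."""
        return self.pixels[:, :, index]


@dataclass
class LabeledDataset:
    """A list of patterns with integer class labels.

    Invariants checked on construction: all patterns share band count and
    band order, and every label indexes into ``class_names``.
    """

    images: list[MultibandImage]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if not self.class_names:
            n = int(self.labels.max()) + 1 if len(self.labels) else 0
            self.class_names = [f"class_{i}" for i in range(n)]
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            bad = int(self.labels[(self.labels < 0) | (self.labels >= len(self.class_names))][0])
            raise ValueError(f"label {bad} outside [0, {len(self.class_names)})")
        if self.images:
            ref = self.images[0].band_ids
            for img in self.images[1:]:
                if img.band_ids != ref:
                    raise ValueError(
                        f"pattern {img.pattern_id!r}: band_ids {img.band_ids} "
                        f"differ from {ref}"
                    )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_bands(self) -> int:
        if not self.images:
            raise ValueError("empty dataset has no band count")
        return self.images[0].n_bands

    @property
    def band_ids(self) -> list[str]:
        if not self.images:
            raise ValueError("empty dataset has no band_ids")
        return self.images[0].band_ids

    def subset(self, indices) -> "LabeledDataset":
        """A new dataset holding the selected patterns (pixels shared)."""
        indices = np.asarray(indices)
        return LabeledDataset(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
        )
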