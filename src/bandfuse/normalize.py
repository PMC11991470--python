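"""Per-band normalization of raw multiband values to 8-bit.

Two procedures are supported, both mapping raw non-negative band values
onto ``uint8``:

``per_band_max_tenth``
    Let ``rec[b]`` be the maximum raw value of band *b* across the
    *training* patterns.  A value ``v`` is rescaled by
    ``v / ((rec[b] / 10) / 255)`` and cast to ``uint8``, so anything at or
    above one tenth of the training maximum saturates at 255.  This is an
    outlier-robust stretch for sensors whose occasional extreme readings
    would otherwise crush the dynamic range.

``fixed_scale``
    All bands share a known physical ceiling (e.g. 2.8 for reflectance
    data); ``v`` maps to ``v / (ceiling / 255)`` cast to ``uint8``.

Statistics are always extracted from the training fold only; test
patterns never update ``rec``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import LabeledDataset, MultibandImage

__all__ = ["BandNormalizer", "fit_band_stats", "normalize_image", "normalize_dataset", "cast_uint8"]


def cast_uint8(values: np.ndarray) -> np.ndarray:
    """Saturating 8-bit cast, rounding half away from zero.

    Mirrors MATLAB ``uint8()`` semantics: values are rounded with ties
    going away from zero, then clipped to [0, 255].  Centralized here so
    every normalization path shares one rounding rule.
    """
    v = np.asarray(values, dtype=np.float64)
    rounded = np.floor(np.abs(v) + 0.5) * np.sign(v)
    return np.clip(rounded, 0, 255).astype(np.uint8)


@dataclass
class BandNormalizer:
    """Fitted normalization parameters for one dataset.

    ``mode`` selects the procedure; ``rec`` holds per-band training maxima
    (``per_band_max_tenth``) and ``ceiling`` the shared physical maximum
    (``fixed_scale``).
    """

    mode: str
    rec: np.ndarray | None = None
    ceiling: float | None = None
    band_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("per_band_max_tenth", "fixed_scale"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "per_band_max_tenth":
            if self.rec is None:
                raise ValueError("per_band_max_tenth requires rec")
            self.rec = np.asarray(self.rec, dtype=np.float64)
            if np.any(self.rec <= 0):
                raise ValueError("every rec entry must be > 0")
        else:
            if self.ceiling is None or self.ceiling <= 0:
                raise ValueError("fixed_scale requires ceiling > 0")

    @property
    def n_bands(self) -> int | None:
        return None if self.rec is None else int(self.rec.shape[0])

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload: dict = {"mode": self.mode, "band_ids": self.band_ids}
        if self.mode == "per_band_max_tenth":
            payload["rec"] = [float(r) for r in self.rec]
        else:
            payload["ceiling"] = float(self.ceiling)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BandNormalizer":
        payload = json.loads(Path(path).read_text())
        return cls(
            mode=payload["mode"],
            rec=payload.get("rec"),
            ceiling=payload.get("ceiling"),
            band_ids=payload.get("band_ids", []),
        )


def fit_band_stats(train: LabeledDataset) -> BandNormalizer:
    """Extract per-band maxima from the training patterns.

    Returns a ``per_band_max_tenth`` normalizer whose ``rec[b]`` is the
    maximum raw value of band *b* over every pixel of every training
    pattern.  A band whose maximum is 0 is degenerate (it would normalize
    to a constant) and raises.
    """
    if len(train) == 0:
        raise ValueError("cannot fit normalization statistics on an empty dataset")
    rec = np.full(train.n_bands, -np.inf)
    for img in train.images:
        band_max = np.asarray(img.pixels, dtype=np.float64).max(axis=(0, 1))
        rec = np.maximum(rec, band_max)
    if np.any(rec <= 0):
        bad = [train.band_ids[i] for i in np.nonzero(rec <= 0)[0]]
        raise ValueError(f"degenerate band(s) with max 0: {bad}")
    return BandNormalizer(mode="per_band_max_tenth", rec=rec, band_ids=list(train.band_ids))


def normalize_image(img: MultibandImage, norm: BandNormalizer) -> MultibandImage:
    """Apply a fitted normalizer to one raw pattern, returning uint8 pixels.

    Internal arithmetic is double precision; the single 8-bit cast happens
    at the end through :func:`cast_uint8`.
    """
    pixels = np.asarray(img.pixels, dtype=np.float64)
    if np.any(pixels < 0):
        raise ValueError(f"pattern {img.pattern_id!r}: negative values cannot be normalized")
    if norm.mode == "per_band_max_tenth":
        if norm.n_bands != img.n_bands:
            raise ValueError(
                f"pattern {img.pattern_id!r}: {img.n_bands} bands but normalizer "
                f"was fitted on {norm.n_bands}"
            )
        divisor = (norm.rec / 10.0) / 255.0  # one-tenth of training max maps to 255
        scaled = pixels / divisor[None, None, :]
    else:
        scaled = pixels / (norm.ceiling / 255.0)
    return MultibandImage(
        pixels=cast_uint8(scaled),
        band_ids=list(img.band_ids),
        pattern_id=img.pattern_id,
    )


def normalize_dataset(ds: LabeledDataset, norm: BandNormalizer) -> LabeledDataset:
    """Normalize every pattern of a dataset with the same fitted parameters."""
    return LabeledDataset(
        images=[normalize_image(img, norm) for img in ds.images],
        labels=ds.labels.copy(),
        class_names=list(ds.class_names),
    )
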