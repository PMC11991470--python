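"""Dataset directory I/O.

Layout::

    dataset/
      manifest.csv      # columns: pattern_id, file, label
      bands.json        # {"band_ids": [...], "class_names": [...],
                        #  "rgb_band_ids": optional [...]}
      <pattern files>   # one per pattern: NPZ (key "pixels", H×W×C)
                        # or multi-page TIFF (page order = band order)

The RGB designation is data, not code: a manifest's ``rgb_band_ids``
names which bands play the red/green/blue roles for the recipe samplers
that privilege them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import LabeledDataset, MultibandImage

__all__ = ["read_dataset", "write_dataset", "rgb_indices"]


def write_dataset(
    ds: LabeledDataset,
    path: str | Path,
    fmt: str = "npz",
    rgb_band_ids: list[str] | None = None,
) -> Path:
    """Write a dataset directory (manifest + sidecar + one file per pattern)."""
    if fmt not in ("npz", "tiff"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, label in zip(ds.images, ds.labels):
        ext = "npz" if fmt == "npz" else "tif"
        fname = f"{img.pattern_id}.{ext}"
        if fmt == "npz":
            np.savez(path / fname, pixels=img.pixels)
        else:
            # pages in band order; tifffile maps the leading axis to pages
            tifffile.imwrite(path / fname, np.moveaxis(img.pixels, -1, 0))
        rows.append({"pattern_id": img.pattern_id, "file": fname,
                     "label": ds.class_names[int(label)]})
    pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)
    sidecar = {"band_ids": ds.band_ids, "class_names": list(ds.class_names)}
    if rgb_band_ids is not None:
        sidecar["rgb_band_ids"] = list(rgb_band_ids)
    (path / "bands.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_dataset(path: str | Path) -> LabeledDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Errors name the offending pattern: missing file, label outside the
    class list, or a band count inconsistent with ``bands.json``.
    """
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv", dtype=str)
    for col in ("pattern_id", "file", "label"):
        if col not in manifest.columns:
            raise ValueError(f"manifest.csv missing column {col!r}")
    sidecar = json.loads((path / "bands.json").read_text())
    band_ids = list(sidecar["band_ids"])
    class_names = list(sidecar["class_names"])
    class_to_idx = {c: i for i, c in enumerate(class_names)}

    images, labels = [], []
    for row in manifest.itertuples(index=False):
        fpath = path / row.file
        if not fpath.exists():
            raise FileNotFoundError(f"pattern {row.pattern_id!r}: file {row.file} missing")
        if row.label not in class_to_idx:
            raise ValueError(
                f"pattern {row.pattern_id!r}: label {row.label!r} not in class list "
                f"{class_names}"
            )
        if fpath.suffix == ".npz":
            with np.load(fpath) as z:
                pixels = z["pixels"]
        else:
            pixels = np.moveaxis(tifffile.imread(fpath), 0, -1)
        if pixels.shape[-1] != len(band_ids):
            raise ValueError(
                f"pattern {row.pattern_id!r}: {pixels.shape[-1]} bands, "
                f"expected {len(band_ids)}"
            )
        images.append(MultibandImage(pixels=pixels, band_ids=band_ids,
                                     pattern_id=str(row.pattern_id)))
        labels.append(class_to_idx[row.label])
    return LabeledDataset(images=images, labels=np.asarray(labels),
                          class_names=class_names)


def rgb_indices(path_or_ds, band_ids: list[str] | None = None) -> list[int]:
    """Resolve a dataset directory's declared RGB bands to band positions."""
    sidecar = json.loads((Path(path_or_ds) / "bands.json").read_text())
    band_ids = band_ids or list(sidecar["band_ids"])
    rgb = sidecar.get("rgb_band_ids")
    if rgb is None:
        raise ValueError("dataset declares no rgb_band_ids")
    return [band_ids.index(b) for b in rgb]
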