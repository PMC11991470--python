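"""Channel recipes: how one ensemble member views a multiband pattern.

Every member of an ensemble is trained on its own re-encoding of the
source bands.  A :class:`ChannelRecipe` is the ordered list of source
band positions that defines that re-encoding.  Five strategies:

``grayset``
    Replicate a single band into all three color planes — band *i* gives
    the triplet ``(i, i, i)``.  One member uses *all* C such triplets as
    views of each pattern; their scores are averaged at evaluation.
``random``
    Three bands drawn independently and uniformly with replacement.
``random_one_rgb``
    As ``random``, but one slot (itself at a uniformly random position)
    is guaranteed to come from the declared red/green/blue bands, since
    those tend to carry more discriminative power.  Degenerate draws such
    as an all-red triplet are deliberately allowed.
``bagged``
    K bands drawn with replacement — a bagging view of channel space for
    networks that accept multichannel input.
``bagged_first_rgb``
    As ``bagged``, but the first channel comes from the RGB bands.

All draws are with replacement and unconstrained; diversity across
members, not per-member optimality, is the design goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import MultibandImage

__all__ = [
    "ChannelRecipe",
    "make_grayset_recipes",
    "sample_random_triplet",
    "sample_random_one_rgb",
    "sample_bagged_multichannel",
    "apply_recipe",
    "save_recipes",
    "load_recipes",
]

STRATEGIES = ("grayset", "random", "random_one_rgb", "bagged", "bagged_first_rgb")


@dataclass(frozen=True)
class ChannelRecipe:
    strategy: str
    indices: tuple[int, ...]
    seed: int | None = None
    member_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if any(i < 0 for i in self.indices):
            raise ValueError(f"negative band index in {self.indices}")
        if self.strategy == "grayset" and len(set(self.indices)) != 1:
            raise ValueError("grayset recipes replicate one band across all slots")

    def __len__(self) -> int:
        return len(self.indices)

    def to_dict(self) -> dict:
        d = {"strategy": self.strategy, "indices": list(self.indices), "seed": self.seed}
        if self.member_id is not None:
            d["member_id"] = self.member_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelRecipe":
        return cls(strategy=d["strategy"], indices=tuple(d["indices"]),
                   seed=d.get("seed"), member_id=d.get("member_id"))


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _seed_of(rng) -> int | None:
    return int(rng) if isinstance(rng, (int, np.integer)) else None


def make_grayset_recipes(n_bands: int) -> list[ChannelRecipe]:
    """The C deterministic single-band triplets ``(i, i, i)``."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    return [ChannelRecipe("grayset", (i, i, i)) for i in range(n_bands)]


def sample_random_triplet(n_bands: int, rng) -> ChannelRecipe:
    """Three i.i.d. uniform draws over all bands, with replacement."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    seed = _seed_of(rng)
    gen = _as_rng(rng)
    idx = tuple(gen.integers(0, n_bands, size=3))
    return ChannelRecipe("random", idx, seed=seed)


def sample_random_one_rgb(n_bands: int, rgb_set, rng) -> ChannelRecipe:
    """Random triplet with one slot guaranteed from the RGB bands.

    The guaranteed slot's position is itself uniform over the three
    positions so no color plane is systematically favored; the other two
    slots are uniform over all bands.
    """
    rgb = sorted(int(i) for i in rgb_set)
    if len(rgb) != 3 or any(i < 0 or i >= n_bands for i in rgb):
        raise ValueError(f"rgb_set must be 3 in-range band positions, got {rgb_set}")
    seed = _seed_of(rng)
    gen = _as_rng(rng)
    idx = list(gen.integers(0, n_bands, size=3))
    slot = int(gen.integers(0, 3))
    idx[slot] = rgb[int(gen.integers(0, 3))]
    return ChannelRecipe("random_one_rgb", tuple(idx), seed=seed)


def sample_bagged_multichannel(
    n_bands: int, k: int, rng, first_rgb=None
) -> ChannelRecipe:
    """K i.i.d. uniform draws with replacement (bagging over channels).

    With ``first_rgb`` given, the leading channel is drawn uniformly from
    those three bands instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    strategy = "bagged"
    seed = _seed_of(rng)
    gen = _as_rng(rng)
    idx = list(gen.integers(0, n_bands, size=k))
    if first_rgb is not None:
        rgb = sorted(int(i) for i in first_rgb)
        if len(rgb) != 3 or any(i < 0 or i >= n_bands for i in rgb):
            raise ValueError(f"first_rgb must be 3 in-range band positions, got {first_rgb}")
        idx[0] = rgb[int(gen.integers(0, 3))]
        strategy = "bagged_first_rgb"
    return ChannelRecipe(strategy, tuple(idx), seed=seed)


def apply_recipe(img: MultibandImage, recipe: ChannelRecipe) -> MultibandImage:
    """Materialize a recipe: band j of the output copies source band
    ``indices[j]``.  Pixel values are copied verbatim, never mixed."""
    for i in recipe.indices:
        if i >= img.n_bands:
            raise IndexError(
                f"recipe index {i} out of range for {img.n_bands}-band pattern "
                f"{img.pattern_id!r}"
            )
    sel = list(recipe.indices)
    return MultibandImage(
        pixels=img.pixels[:, :, sel].copy(),
        band_ids=[img.band_ids[i] for i in sel],
        pattern_id=img.pattern_id,
    )


def save_recipes(recipes: list[ChannelRecipe], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in recipes], indent=2))


def load_recipes(path: str | Path) -> list[ChannelRecipe]:
    return [ChannelRecipe.from_dict(d) for d in json.loads(Path(path).read_text())]
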