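"""Per-member training and scoring.

A *member* couples one network with one channel recipe (or, for the
grayset strategy, the full set of single-band triplets, whose per-view
scores are averaged downstream).  Training presets follow the study
design:

* pretrained-backbone preset — SGD (momentum 0.9), learning rate 0.001,
  batch size 30, 20 epochs (10 for very large datasets), cross-entropy;
* custom-network preset — Adam, initial learning rate 1e-3, step
  scheduler with step size 5 and decay 0.5.

Augmentation, when enabled, is materialized offline (×4) before
training.  Every stochastic step — augmentation factors, shuffling,
weight initialization — flows from the config seed, so a run is
bit-reproducible on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .augment import augment_dataset
from .fusion import ScoreMatrix
from .image import LabeledDataset
from .nn import BatchNorm, Module, cross_entropy
from .nn.optim import SGD, Adam, StepLR
from .nn.tensor import Tensor
from .recipes import ChannelRecipe, apply_recipe

__all__ = ["TrainConfig", "train_member", "score_dataset",
           "PRESETS", "preset"]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 30
    epochs: int = 20
    scheduler: dict | None = None          # {"step_size": int, "gamma": float}
    momentum: float = 0.9
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


PRESETS: dict[str, TrainConfig] = {
    # fine-tuning preset for the classic backbones
    "pretrained": TrainConfig(optimizer="sgd", learning_rate=1e-3,
                              batch_size=30, epochs=20),
    # very large datasets: shorter schedule, no augmentation
    "pretrained_large": TrainConfig(optimizer="sgd", learning_rate=1e-3,
                                    batch_size=30, epochs=10, augment=False),
    # scratch-trained custom networks
    "custom": TrainConfig(optimizer="adam", learning_rate=1e-3, batch_size=30,
                          epochs=20,
                          scheduler={"step_size": 5, "gamma": 0.5}),
    # desk-scale runs with the tiny CNN: the custom-network recipe shape
    # (Adam + step schedule) at a short schedule
    "tiny": TrainConfig(optimizer="adam", learning_rate=1e-2, batch_size=30,
                        epochs=10, scheduler={"step_size": 5, "gamma": 0.5}),
}


def preset(name: str, **overrides) -> TrainConfig:
    """A fresh copy of a named preset, optionally with field overrides."""
    base = PRESETS[name]
    cfg = TrainConfig(**{**base.__dict__})
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"TrainConfig has no field {key!r}")
        setattr(cfg, key, value)
    return cfg


def _as_recipes(recipe) -> list[ChannelRecipe]:
    return list(recipe) if isinstance(recipe, (list, tuple)) else [recipe]


def _resize_batch(batch: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear per-image resize of an (N, C, H, W) batch."""
    n, c, h, w = batch.shape
    if (h, w) == tuple(size):
        return batch
    fy, fx = size[0] / h, size[1] / w
    return np.stack([ndimage.zoom(img, (1, fy, fx), order=1) for img in batch])


def _views(ds: LabeledDataset, recipes: list[ChannelRecipe],
           input_size: tuple[int, int] | None = None
           ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Materialize recipe views: (N·V, C, H, W) in [0,1], labels, ids."""
    xs, ys, ids = [], [], []
    for img, label in zip(ds.images, ds.labels):
        for recipe in recipes:
            view = apply_recipe(img, recipe)
            xs.append(np.moveaxis(view.pixels, -1, 0))
            ys.append(label)
            ids.append(img.pattern_id)
    batch = np.asarray(xs, dtype=np.float32) / 255.0
    if input_size is not None:
        batch = _resize_batch(batch, input_size)
    return batch, np.asarray(ys), ids


def train_member(net: Module, recipe, train: LabeledDataset,
                 cfg: TrainConfig) -> list[dict]:
    """Train one member in place; returns the per-epoch loss log.

    ``recipe`` is one :class:`ChannelRecipe` or a list of them (a grayset
    member's views).  The recipe is applied to every (augmented) pattern;
    optimization follows ``cfg``.
    """
    recipes = _as_recipes(recipe)
    present = np.unique(train.labels)
    if len(present) < train.n_classes:
        missing = sorted(set(range(train.n_classes)) - set(present.tolist()))
        raise ValueError(f"class(es) {missing} absent from the training fold")
    rng = np.random.default_rng(cfg.seed)
    if cfg.augment:
        train = augment_dataset(train, rng)
    x, y, _ = _views(train, recipes, getattr(net, "cfg", None)
                     and tuple(net.cfg.input_size) or None)

    params = net.parameters()
    if cfg.optimizer == "sgd":
        opt = SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    else:
        opt = Adam(params, lr=cfg.learning_rate)
    sched = (StepLR(opt, **cfg.scheduler) if cfg.scheduler else None)

    net.train()
    log: list[dict] = []
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            logits = net(Tensor(x[idx]))
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}; "
                    f"lr={opt.lr}, batch_size={cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if sched is not None:
            sched.step()
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    # class-mixed batches: between-batch mean spread must land in the means,
    # not vanish from the variances
    _recalibrate_batchnorm(net, x[rng.permutation(n)], cfg.batch_size)
    return log


def _recalibrate_batchnorm(net: Module, x: np.ndarray, batch_size: int) -> None:
    """Recompute batch-norm running statistics under the final weights.

    Short, high-learning-rate runs leave the exponential running
    estimates lagging the activations the trained weights actually
    produce; one cumulative-average pass over the training inputs aligns
    eval-mode behavior with train-mode behavior.
    """
    bns = [m for m in net.modules() if isinstance(m, BatchNorm)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.reset_running()
        bn.momentum = None
    net.train()
    for start in range(0, len(x), batch_size):
        batch = x[start:start + batch_size]
        if len(batch) < 2:
            continue
        net(Tensor(batch))
    for bn, m in zip(bns, saved):
        bn.momentum = m


def score_dataset(net: Module, recipe, data: LabeledDataset) -> ScoreMatrix:
    """Raw per-view scores (logits) in eval mode, no augmentation.

    A grayset member emits one row per band view, all tagged with the
    pattern's id so :func:`bandfuse.fusion.average_views` can combine
    them; other strategies emit exactly one row per pattern.
    """
    recipes = _as_recipes(recipe)
    for r in recipes:
        for i in r.indices:
            if i >= data.n_bands:
                raise IndexError(f"recipe index {i} out of range for "
                                 f"{data.n_bands}-band data")
    x, _, ids = _views(data, recipes, getattr(net, "cfg", None)
                       and tuple(net.cfg.input_size) or None)
    net.eval()
    chunks = []
    for start in range(0, len(x), 64):
        chunks.append(net(Tensor(x[start:start + 64])).data)
    return ScoreMatrix(scores=np.concatenate(chunks, axis=0),
                       pattern_ids=ids, normalized=False)
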