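"""End-to-end orchestration: normalize → recipes → train → score → fuse
→ evaluate, from one config.

An ensemble is declared as *member groups*: each group couples an
architecture with a recipe strategy, a member count, a training preset
and a fusion weight (e.g. ten random-triplet members on one backbone,
plus three bagged multichannel members on a custom net, the latter
weighted 3).  Per-member randomness — recipe draw, weight init, epoch
shuffling — is derived deterministically from the master seed and the
member's position, so members differ from each other but a rerun of the
same config reproduces every prediction bit-exactly.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion import EnsembleMember, EnsembleSpec, average_views, fuse
from .image import LabeledDataset
from .io import read_dataset
from .metrics import confusion, metrics
from .networks import NetworkConfig, build_network
from .normalize import BandNormalizer, fit_band_stats, normalize_dataset
from .protocol import run_protocol
from .recipes import (ChannelRecipe, make_grayset_recipes,
                      sample_bagged_multichannel, sample_random_one_rgb,
                      sample_random_triplet, save_recipes)
from .training import TrainConfig, preset, score_dataset, train_member

__all__ = ["MemberGroup", "RunConfig", "run", "format_ensemble_name",
           "parse_ensemble_name"]

_STRATEGY_NAMES = {"grayset": "GraySet", "random": "Random",
                   "random_one_rgb": "RandomOneRGB", "bagged": "Bagged",
                   "bagged_first_rgb": "BaggedFirstRGB"}
_ARCH_NAMES = {"resnet50": "Res", "densenet201": "DN", "mobilenetv2": "MV2",
               "cres": "Cres", "catt": "Catt", "tinycnn": "Tiny"}
_STRATEGY_BY_NAME = {v: k for k, v in _STRATEGY_NAMES.items()}
_ARCH_BY_NAME = {v: k for k, v in _ARCH_NAMES.items()}


def format_ensemble_name(strategy: str, n_members: int, arch: str) -> str:
    """E.g. ``("random", 10, "resnet50") -> "Random(10)_Res"``."""
    return f"{_STRATEGY_NAMES[strategy]}({n_members})_{_ARCH_NAMES[arch]}"


def parse_ensemble_name(name: str) -> tuple[str, int, str]:
    m = re.fullmatch(r"(\w+)\((\d+)\)_(\w+)", name)
    if not m or m.group(1) not in _STRATEGY_BY_NAME or m.group(3) not in _ARCH_BY_NAME:
        raise ValueError(f"cannot parse ensemble name {name!r}")
    return (_STRATEGY_BY_NAME[m.group(1)], int(m.group(2)),
            _ARCH_BY_NAME[m.group(3)])


@dataclass
class MemberGroup:
    """One (architecture, strategy) family of ensemble members."""

    arch: str
    strategy: str
    n_members: int = 1
    preset: str = "tiny"
    weight: float = 1.0
    bagged_k: int | None = None          # defaults to the dataset band count
    train_overrides: dict = field(default_factory=dict)

    @property
    def name_stub(self) -> str:
        return format_ensemble_name(self.strategy, self.n_members, self.arch)


@dataclass
class RunConfig:
    groups: list[MemberGroup]
    dataset: str | None = None           # directory path; or pass ds to run()
    protocol: dict = field(default_factory=lambda: {"kind": "kfold", "k": 4})
    normalization: dict = field(default_factory=lambda:
                                {"mode": "per_band_max_tenth"})
    rgb_indices: list[int] | None = None
    master_seed: int = 0
    out_dir: str | None = None
    resume: bool = True


def _draw_recipes(group: MemberGroup, n_bands: int, rgb: list[int] | None,
                  rng: np.random.Generator) -> list[ChannelRecipe] | ChannelRecipe:
    if group.strategy == "grayset":
        return make_grayset_recipes(n_bands)
    if group.strategy == "random":
        return sample_random_triplet(n_bands, rng)
    if group.strategy == "random_one_rgb":
        if rgb is None:
            raise ValueError("random_one_rgb requires rgb_indices in the config")
        return sample_random_one_rgb(n_bands, rgb, rng)
    k = group.bagged_k or n_bands
    if group.strategy == "bagged_first_rgb":
        if rgb is None:
            raise ValueError("bagged_first_rgb requires rgb_indices in the config")
        return sample_bagged_multichannel(n_bands, k, rng, first_rgb=rgb)
    return sample_bagged_multichannel(n_bands, k, rng)


def _in_channels(group: MemberGroup, recipe) -> int:
    return len(recipe[0]) if isinstance(recipe, list) else len(recipe)


def run(config: RunConfig, dataset: LabeledDataset | None = None) -> dict:
    """Execute the full pipeline; returns the report bundle.

    The bundle holds per-fold member and fused metrics plus their mean
    over folds.  With ``config.out_dir`` set, recipes, normalizer,
    member checkpoints, score CSVs, the report JSON and a run log are
    persisted; a rerun resumes from existing member checkpoints.
    """
    if dataset is None:
        if config.dataset is None:
            raise ValueError("either config.dataset or a dataset is required")
        dataset = read_dataset(config.dataset)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    fold_counter = {"i": 0}

    def fold_runner(train_ds: LabeledDataset, test_ds: LabeledDataset) -> dict:
        fold = fold_counter["i"]
        fold_counter["i"] += 1
        stage = "normalize"
        try:
            if config.normalization["mode"] == "per_band_max_tenth":
                norm = fit_band_stats(train_ds)
            else:
                norm = BandNormalizer(mode="fixed_scale",
                                      ceiling=config.normalization["ceiling"],
                                      band_ids=list(train_ds.band_ids))
            train_n = normalize_dataset(train_ds, norm)
            test_n = normalize_dataset(test_ds, norm)
            if out:
                norm.to_json(out / f"normalizer_fold{fold}.json")

            h, w = train_n.images[0].height, train_n.images[0].width
            member_reports: dict[str, dict] = {}
            matrices, members, recipes_drawn = [], [], []
            for g_idx, group in enumerate(config.groups):
                for m_idx in range(group.n_members):
                    member_key = f"{group.name_stub}#m{m_idx}"
                    member_id = f"{member_key}_f{fold}"
                    stage = f"member {member_id}"
                    rng = np.random.default_rng(
                        [config.master_seed, fold, g_idx, m_idx])
                    recipe = _draw_recipes(group, train_n.n_bands,
                                           config.rgb_indices, rng)
                    net_cfg = NetworkConfig(
                        arch_id=group.arch,
                        in_channels=_in_channels(group, recipe),
                        n_classes=train_n.n_classes, input_size=(h, w))
                    net = build_network(net_cfg, rng)
                    ckpt = out / f"ckpt_{member_id.replace('#', '_')}.npz" if out else None
                    if ckpt and ckpt.exists() and config.resume:
                        state = dict(np.load(ckpt))
                        net.load_state_dict(state)
                        log(f"fold {fold}: resumed {member_id}")
                    else:
                        tcfg = preset(group.preset, **group.train_overrides)
                        tcfg.seed = int(rng.integers(0, 2 ** 31))
                        tlog = train_member(net, recipe, train_n, tcfg)
                        log(f"fold {fold}: trained {member_id} "
                            f"final loss {tlog[-1]['loss']:.4f}")
                        if ckpt:
                            np.savez(ckpt, **net.state_dict())
                    scores = score_dataset(net, recipe, test_n)
                    if group.strategy == "grayset":
                        scores = average_views(scores)
                    if out:
                        scores.to_csv(out / f"scores_{member_id.replace('#', '_')}.csv")
                    cc = confusion(scores.predictions(), test_n.labels,
                                   test_n.n_classes)
                    member_reports[member_key] = metrics(cc)
                    matrices.append(scores)
                    members.append(EnsembleMember(member_id=member_id,
                                                  weight=group.weight))
                    if isinstance(recipe, list):
                        recipes_drawn.extend(recipe)
                    else:
                        recipes_drawn.append(recipe)
            stage = "fuse"
            preds, fused_matrix = fuse(EnsembleSpec(members=members), matrices)
            fused_report = metrics(confusion(preds, test_n.labels,
                                             test_n.n_classes))
            if out:
                save_recipes(recipes_drawn, out / f"recipes_fold{fold}.json")
                fused_matrix.to_csv(out / f"scores_fused_f{fold}.csv")
            return {"members": member_reports, "fused": fused_report,
                    "fused_predictions": [int(p) for p in preds]}
        except Exception as exc:
            raise RuntimeError(f"fold {fold}, stage '{stage}' failed: {exc}") from exc

    bundle = run_protocol(dataset, config.protocol, fold_runner,
                          seed=config.master_seed)
    if out:
        (out / "report.json").write_text(json.dumps(bundle, indent=2))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle
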