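"""Canned desk-scale experiments.

The central one is the ensemble-size sweep: train a pool of
random-triplet tiny-CNN members on the heterogeneous-band spectral
fixture and measure fused performance at increasing ensemble sizes —
the desk-scale analogue of growing a backbone ensemble on a real
multiband benchmark, where performance climbs steeply over the first
handful of members.
"""

from __future__ import annotations

import numpy as np

from .fusion import EnsembleMember, EnsembleSpec, fuse
from .image import LabeledDataset
from .metrics import confusion, metrics
from .networks import NetworkConfig, build_tinycnn
from .normalize import fit_band_stats, normalize_dataset
from .protocol import make_fixed_split
from .recipes import sample_random_triplet
from .synthetic import generate, spectral_fixture_spec
from .training import preset, score_dataset, train_member

__all__ = ["ensemble_size_sweep"]


def ensemble_size_sweep(dataset: LabeledDataset | None = None,
                        sizes: tuple[int, ...] = (1, 5, 10),
                        n_seeds: int = 5,
                        base_seed: int = 0,
                        preset_name: str = "tiny",
                        test_fraction: float = 0.25) -> dict:
    """Fused-vs-member performance across ensemble sizes.

    For each of ``n_seeds`` splits, trains ``max(sizes)`` members (one
    random channel triplet + one tiny CNN each) and evaluates nested
    ensembles of the requested sizes on the held-out quarter.  All
    randomness derives from ``base_seed``.

    Returns mean accuracy per size, the mean fused-minus-mean-member
    macro-F1 gap at the largest size, and the per-seed detail.
    """
    if dataset is None:
        fixture_seed = int(np.random.default_rng([base_seed, 101]).integers(2 ** 31))
        dataset = generate(spectral_fixture_spec(
            seed=fixture_seed, n_per_class=12, noise_sd=25.0,
            heterogeneous_bands=True))
    n_members = max(sizes)
    per_seed: list[dict] = []
    for s in range(n_seeds):
        split_seed = int(np.random.default_rng([base_seed, 7, s]).integers(2 ** 31))
        tr_idx, te_idx = make_fixed_split(dataset.labels, test_fraction,
                                          split_seed)[0]
        train_ds, test_ds = dataset.subset(tr_idx), dataset.subset(te_idx)
        norm = fit_band_stats(train_ds)
        train_n = normalize_dataset(train_ds, norm)
        test_n = normalize_dataset(test_ds, norm)
        mats, member_f1 = [], []
        for m in range(n_members):
            rng = np.random.default_rng([base_seed, s, m])
            recipe = sample_random_triplet(train_n.n_bands, rng)
            net = build_tinycnn(NetworkConfig("tinycnn", 3, train_n.n_classes,
                                              (train_n.images[0].height,
                                               train_n.images[0].width)), rng)
            cfg = preset(preset_name)
            cfg.seed = int(rng.integers(0, 2 ** 31))
            train_member(net, recipe, train_n, cfg)
            sm = score_dataset(net, recipe, test_n)
            mats.append(sm)
            member_f1.append(metrics(confusion(
                sm.predictions(), test_n.labels, test_n.n_classes))["macro_f1"])

        def fused_report(k: int) -> dict:
            spec = EnsembleSpec(members=[EnsembleMember(f"m{i}")
                                         for i in range(k)])
            preds, _ = fuse(spec, mats[:k])
            return metrics(confusion(preds, test_n.labels, test_n.n_classes))

        by_size = {k: fused_report(k) for k in sizes}
        per_seed.append({
            "member_macro_f1": member_f1,
            "mean_member_macro_f1": float(np.mean(member_f1)),
            "fused": {k: {"accuracy": by_size[k]["accuracy"],
                          "macro_f1": by_size[k]["macro_f1"]}
                      for k in sizes},
        })
    mean_acc = {k: float(np.mean([p["fused"][k]["accuracy"] for p in per_seed]))
                for k in sizes}
    top = max(sizes)
    f1_gap = float(np.mean([p["fused"][top]["macro_f1"]
                            - p["mean_member_macro_f1"] for p in per_seed]))
    return {"sizes": list(sizes), "mean_accuracy": mean_acc,
            "fused_minus_member_f1": f1_gap, "per_seed": per_seed,
            "fused_macro_f1": float(np.mean(
                [p["fused"][top]["macro_f1"] for p in per_seed])),
            "mean_member_macro_f1": float(np.mean(
                [p["mean_member_macro_f1"] for p in per_seed]))}
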