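"""Evaluation protocols: stratified k-fold cross-validation and a fixed
stratified train/test split.

Fold assignment is stratified and seeded; everything fitted from data —
normalization statistics, augmentation, network weights — is derived
within each training fold only.  Cross-validation reports the mean over
folds; a fixed split reports a single run.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .image import LabeledDataset

__all__ = ["make_folds", "make_fixed_split", "run_protocol", "aggregate_reports"]


def make_folds(labels: np.ndarray, k: int, seed: int
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, test_idx) pairs."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if counts.min() < k:
        bad = np.nonzero(counts < k)[0].tolist()
        raise ValueError(f"class(es) {bad} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def make_fixed_split(labels: np.ndarray, test_fraction: float, seed: int
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One stratified (train_idx, test_idx) pair, e.g. the 80/20 split."""
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=labels,
                              random_state=seed)
    return [(tr, te)]


def run_protocol(ds: LabeledDataset, protocol: dict,
                 fold_runner: Callable[[LabeledDataset, LabeledDataset], dict],
                 seed: int = 0) -> dict:
    """Run ``fold_runner(train, test)`` under the named protocol.

    ``protocol`` is ``{"kind": "kfold", "k": 4}`` or
    ``{"kind": "fixed_split", "test_fraction": 0.2}``.  Returns per-fold
    reports plus the aggregate (mean of numeric leaves over folds).
    """
    kind = protocol.get("kind")
    if kind == "kfold":
        folds = make_folds(ds.labels, int(protocol.get("k", 4)), seed)
    elif kind == "fixed_split":
        folds = make_fixed_split(ds.labels,
                                 float(protocol.get("test_fraction", 0.2)), seed)
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    reports = []
    for tr, te in folds:
        reports.append(fold_runner(ds.subset(tr), ds.subset(te)))
    return {"folds": reports, "aggregate": aggregate_reports(reports)}


def aggregate_reports(reports: list[dict]) -> dict:
    """Element-wise mean of numeric leaves across per-fold report dicts."""
    def merge(values):
        first = values[0]
        if isinstance(first, dict):
            return {k: merge([v[k] for v in values]) for k in first}
        if isinstance(first, (int, float, np.floating)):
            return float(np.mean(values))
        if isinstance(first, list) and first and isinstance(first[0], (int, float)):
            if len({len(v) for v in values}) == 1:
                return np.mean(np.asarray(values, dtype=np.float64), axis=0).tolist()
        return first
    return merge(reports)
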