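"""Score normalization, view averaging, and sum-rule fusion.

An ensemble's members each produce a :class:`ScoreMatrix` — one row of
per-class confidences per pattern view.  Fusion is the (weighted) sum
rule: members' probability rows are added and the argmax over classes is
the prediction.  Members are probability-normalized (row softmax) before
summation so scores are commensurate; integer weights let a
small-but-strong member family count for more, turning the sum rule into
a weighted sum rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScoreMatrix", "EnsembleMember", "EnsembleSpec", "softmax_rows",
           "average_views", "fuse"]


@dataclass
class ScoreMatrix:
    """patterns(×views) × classes confidence table.

    ``normalized`` distinguishes probability rows (each summing to 1)
    from raw logits.  ``pattern_ids`` tag rows so multiple views of one
    pattern can be re-grouped and averaged.
    """

    scores: np.ndarray
    pattern_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (rows × classes)")
        if len(self.pattern_ids) != self.scores.shape[0]:
            raise ValueError("one pattern_id per score row required")
        if self.normalized:
            if np.any(self.scores < -1e-9) or np.any(self.scores > 1 + 1e-9):
                raise ValueError("normalized scores must lie in [0, 1]")
            if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("normalized rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]

    def predictions(self) -> np.ndarray:
        return self.scores.argmax(axis=1)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores,
                          columns=[f"class_{j}" for j in range(self.n_classes)])
        df.insert(0, "pattern_id", self.pattern_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, normalized: bool = False) -> "ScoreMatrix":
        df = pd.read_csv(path, dtype={"pattern_id": str})
        return cls(scores=df.drop(columns="pattern_id").to_numpy(),
                   pattern_ids=df["pattern_id"].tolist(), normalized=normalized)


@dataclass
class EnsembleMember:
    member_id: str
    weight: float = 1.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"member {self.member_id!r}: weight must be > 0")


@dataclass
class EnsembleSpec:
    members: list[EnsembleMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")


def softmax_rows(s: ScoreMatrix) -> ScoreMatrix:
    """Row-wise softmax with max-subtraction for numerical stability."""
    if not np.all(np.isfinite(s.scores)):
        raise ValueError("scores contain non-finite values")
    z = s.scores - s.scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return ScoreMatrix(scores=e / e.sum(axis=1, keepdims=True),
                       pattern_ids=list(s.pattern_ids), normalized=True)


def average_views(s: ScoreMatrix) -> ScoreMatrix:
    """Average all rows sharing a pattern_id (the GraySet view-average).

    Output keeps one row per unique pattern in first-appearance order.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(s.pattern_ids):
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append(i)
    avg = np.stack([s.scores[groups[pid]].mean(axis=0) for pid in order])
    return ScoreMatrix(scores=avg, pattern_ids=order, normalized=s.normalized)


def fuse(spec: EnsembleSpec, matrices: list[ScoreMatrix]
         ) -> tuple[np.ndarray, ScoreMatrix]:
    """Weighted sum rule: fused = Σᵢ wᵢ·vᵢ, prediction = argmax.

    Members flagged ``normalize`` have raw rows softmaxed first.  All
    matrices must agree on pattern order and class count.
    """
    if len(spec.members) != len(matrices):
        raise ValueError(f"{len(spec.members)} members but {len(matrices)} matrices")
    ref = matrices[0]
    fused = np.zeros_like(ref.scores)
    for member, mat in zip(spec.members, matrices):
        if mat.scores.shape != ref.scores.shape:
            raise ValueError(
                f"member {member.member_id!r}: score shape {mat.scores.shape} "
                f"differs from {ref.scores.shape}")
        if mat.pattern_ids != ref.pattern_ids:
            raise ValueError(f"member {member.member_id!r}: pattern order differs")
        if member.normalize and not mat.normalized:
            mat = softmax_rows(mat)
        fused += member.weight * mat.scores
    fused_matrix = ScoreMatrix(scores=fused, pattern_ids=list(ref.pattern_ids),
                               normalized=False)
    return fused_matrix.predictions(), fused_matrix
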