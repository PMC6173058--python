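"""Essentiality scores from minimal lethal set collections.

The essentiality score of target i at analysis level n is

    ES_i = y_i1 + sum_{j=2..n} y_ij * (j-1)! / X^(j-1)

where y_ij is the number of minimal lethal sets of cardinality j that
contain i, and X is the number of knockout candidates in the model. The
weight has a counting interpretation: for a fixed target there are X^(j-1)
ordered level-j knockout combinations (with repetition) that involve it,
and each unordered minimal set containing the target accounts for (j-1)! of
them, so the score is the involved fraction of that population. Because the
population size depends only on X and n, scores are comparable across
models.

An essential target (y_i1 = 1) scores exactly 1 at every level: minimality
removes it from all larger sets, so every j >= 2 term vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Dict

from .sla import LethalSetCollection

__all__ = [
    "InvolvementCounts",
    "EScoreTable",
    "count_involvements",
    "compute_escore",
    "combination_count",
]


@dataclass
class InvolvementCounts:
    """y_ij for one target: minimal lethal sets of each cardinality j."""

    target_id: str
    y: Dict[int, int]


@dataclass
class EScoreTable:
    """Per-target essentiality scores with their normalization context."""

    scores: Dict[str, float]
    X: int
    level_n: int
    target_kind: str
    involvements: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def __getitem__(self, target_id: str) -> float:
        return self.scores[target_id]

    def to_tsv(self, path: str | Path) -> None:
        levels = list(range(1, self.level_n + 1))
        with open(path, "w") as fh:
            header = ["target_id", "escore"] + [f"y_{j}" for j in levels] + ["X", "n"]
            fh.write("\t".join(header) + "\n")
            for tid in sorted(self.scores):
                y = self.involvements.get(tid, {})
                row = [tid, f"{self.scores[tid]:.6f}"]
                row += [str(y.get(j, 0)) for j in levels]
                row += [str(self.X), str(self.level_n)]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EScoreTable":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        y_cols = [h for h in header if h.startswith("y_")]
        scores: Dict[str, float] = {}
        involvements: Dict[str, Dict[int, int]] = {}
        X = n = 0
        for line in lines[1:]:
            parts = dict(zip(header, line.split("\t")))
            tid = parts["target_id"]
            scores[tid] = float(parts["escore"])
            involvements[tid] = {
                int(c[2:]): int(parts[c]) for c in y_cols
            }
            X = int(parts["X"])
            n = int(parts["n"])
        return cls(
            scores=scores,
            X=X,
            level_n=n,
            target_kind="unknown",
            involvements=involvements,
        )


def count_involvements(
    collection: LethalSetCollection, target_id: str
) -> InvolvementCounts:
    """y_ij of one target (minimal lethal cardinality-j sets containing it)."""
    return InvolvementCounts(target_id=target_id, y=collection.involvement(target_id))


def combination_count(X: int, n: int) -> int:
    """Ordered level-n knockout combinations (with repetition) for one target.

    X^(n-1): the population size that motivates the (j-1)!/X^(j-1) score
    weights. The same for every target in a model, which is what makes the
    normalized scores cross-model comparable.
    """
    if X < 1:
        raise ValueError(f"X must be >= 1, got {X}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return X ** (n - 1)


def compute_escore(collection: LethalSetCollection) -> EScoreTable:
    """Score every candidate target of a lethal-set collection.

    Targets appearing in no minimal lethal set score 0; candidates are never
    dropped, so genes/reactions without any lethality involvement remain in
    the output. Scores above 1 for non-essential targets contradict the
    expected bound and trigger a warning (the raw value is reported
    unclamped).
    """
    X = collection.X
    if X < 1:
        raise ValueError("empty candidate set: cannot normalize scores")
    scores: Dict[str, float] = {}
    involvements: Dict[str, Dict[int, int]] = {}
    for tid in collection.candidate_ids:
        y = collection.involvement(tid)
        involvements[tid] = y
        score = float(y.get(1, 0))
        for j in range(2, collection.level_n + 1):
            score += y.get(j, 0) * factorial(j - 1) / X ** (j - 1)
        if score > 1.0 and y.get(1, 0) == 0:
            warnings.warn(
                f"score of non-essential target {tid!r} exceeds 1 "
                f"({score:.6g}); reporting the raw value",
                stacklevel=2,
            )
        scores[tid] = score
    return EScoreTable(
        scores=scores,
        X=X,
        level_n=collection.level_n,
        target_kind=collection.target_kind,
        involvements=involvements,
    )
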