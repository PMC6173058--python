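"""Cross-model score comparison and benchmarking helpers.

The motivating workflow: score a wild-type model and a knockout mutant
derived from it, carry the removed reaction's wild-type score over to the
mutant (it no longer exists there but should not distort the comparison),
and report which targets became more or less essential. A second workflow
benchmarks stoichiometry-based scores against topology centralities via a
2x2 zero/non-zero partition and Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import EScoreTable

__all__ = [
    "ComparisonReport",
    "compare_escores",
    "spearman_rank",
    "score_overlap_counts",
    "subsystem_mean_scores",
]

_EQ_TOL = 1e-9


@dataclass
class ComparisonReport:
    """Aligned per-target scores of two models with deltas and a summary."""

    table: pd.DataFrame  # index target id; score_a, score_b, delta, status
    summary: Dict[str, float]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6f")

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            "model comparison (b vs a)",
            f"  targets compared : {int(s['n_targets'])}",
            f"  up (b > a)       : {int(s['n_up'])}",
            f"  down (b < a)     : {int(s['n_down'])}",
            f"  unchanged        : {int(s['n_unchanged'])}",
            f"  only in a        : {int(s['n_only_a'])}",
            f"  only in b        : {int(s['n_only_b'])}",
            f"  mean score a     : {s['mean_a']:.6f}",
            f"  mean score b     : {s['mean_b']:.6f}",
        ]
        return "\n".join(lines) + "\n"


def compare_escores(
    table_a: EScoreTable,
    table_b: EScoreTable,
    carryover_ids: Iterable[str] = (),
) -> ComparisonReport:
    """Compare two score tables target by target (delta = b - a).

    Each carryover id must be scored in table_a; when it is absent from
    table_b (e.g. the reaction was removed to build model b) its score_b is
    set equal to score_a before deltas are computed, so the removal itself
    does not register as a change. Scores within 1e-9 count as unchanged.
    """
    carryover = list(carryover_ids)
    missing = [c for c in carryover if c not in table_a.scores]
    if missing:
        raise ValueError(f"carryover ids missing from table_a: {missing}")
    scores_b = dict(table_b.scores)
    for c in carryover:
        if c not in scores_b:
            scores_b[c] = table_a.scores[c]
    ids = sorted(set(table_a.scores) | set(scores_b))
    rows = []
    for tid in ids:
        a = table_a.scores.get(tid)
        b = scores_b.get(tid)
        if a is None:
            status, delta = "only_b", np.nan
        elif b is None:
            status, delta = "only_a", np.nan
        else:
            delta = b - a
            if abs(delta) <= _EQ_TOL:
                status = "unchanged"
            elif delta > 0:
                status = "up"
            else:
                status = "down"
        rows.append(
            {
                "target_id": tid,
                "score_a": np.nan if a is None else a,
                "score_b": np.nan if b is None else b,
                "delta": delta,
                "status": status,
            }
        )
    table = pd.DataFrame(rows).set_index("target_id")
    counts = table["status"].value_counts()
    summary = {
        "n_targets": float(len(table)),
        "n_up": float(counts.get("up", 0)),
        "n_down": float(counts.get("down", 0)),
        "n_unchanged": float(counts.get("unchanged", 0)),
        "n_only_a": float(counts.get("only_a", 0)),
        "n_only_b": float(counts.get("only_b", 0)),
        "mean_a": float(np.nanmean(table["score_a"].to_numpy(dtype=float)))
        if len(table)
        else np.nan,
        "mean_b": float(np.nanmean(table["score_b"].to_numpy(dtype=float)))
        if len(table)
        else np.nan,
    }
    return ComparisonReport(table=table, summary=summary)


def spearman_rank(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided t-approx p.

    Raises on constant input, where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def score_overlap_counts(
    escores: EScoreTable,
    centrality: pd.DataFrame,
    metric: str = "betweenness",
) -> Dict[str, object]:
    """2x2 zero/non-zero partition of targets by score vs centrality.

    Targets are the intersection of the score table and the centrality
    table's index. "Zero" means exactly 0.0: uninvolved targets are
    structurally zero in both pipelines, so no epsilon is applied.
    """
    shared = sorted(set(escores.scores) & set(centrality.index))
    if not shared:
        raise ValueError("no shared target ids between the two tables")
    cells: Dict[str, List[str]] = {
        "both_nonzero": [],
        "escore_only": [],
        "centrality_only": [],
        "both_zero": [],
    }
    for tid in shared:
        e_nonzero = escores.scores[tid] != 0.0
        c_nonzero = float(centrality.loc[tid, metric]) != 0.0
        if e_nonzero and c_nonzero:
            cells["both_nonzero"].append(tid)
        elif e_nonzero:
            cells["escore_only"].append(tid)
        elif c_nonzero:
            cells["centrality_only"].append(tid)
        else:
            cells["both_zero"].append(tid)
    out: Dict[str, object] = {f"n_{k}": len(v) for k, v in cells.items()}
    out["members"] = cells
    out["n_shared"] = len(shared)
    return out


def subsystem_mean_scores(
    escores: EScoreTable, subsystem_of: Dict[str, str]
) -> pd.DataFrame:
    """Mean score per subsystem for a user-supplied target->subsystem map."""
    rows = [
        {"target_id": tid, "subsystem": subsystem_of.get(tid, ""), "escore": sc}
        for tid, sc in escores.scores.items()
    ]
    df = pd.DataFrame(rows)
    grouped = (
        df[df["subsystem"] != ""]
        .groupby("subsystem")["escore"]
        .agg(["mean", "count"])
        .sort_values("mean", ascending=False)
    )
    return grouped.rename(columns={"mean": "mean_escore", "count": "n_targets"})
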