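"""Enumeration of essential targets and minimal synthetic-lethal sets.

Two routes produce the same answer:

* :func:`enumerate_minimal_lethal_sets` — the production path. It grows
  candidate knockout sets level by level, restricting each extension to
  targets that carry flux in a minimum-L1-norm optimal solution of the
  current knockout model (the Fast-SL pruning argument: a target outside
  that support cannot convert the current set into a lethal one, because
  the exhibited optimal flux distribution survives its deletion).
* :func:`brute_force_lethal_sets` — an exhaustive oracle that tests every
  combination up to level n, used to validate the pruned path on small
  models.

Both apply the same minimality ("true synthetic lethal") rule: a lethal set
is stored only if none of its proper subsets is lethal, i.e. supersets of
already-stored sets are discarded. Only minimal sets enter the scoring
stage, which is what keeps an essential target's score pinned at 1.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence

from .fba import FBASession
from .model import (
    AnalysisConfig,
    MetabolicModel,
    disabled_reactions,
    logical_transform,
)

__all__ = [
    "LethalSetCollection",
    "BudgetExceededError",
    "find_essential",
    "enumerate_minimal_lethal_sets",
    "brute_force_lethal_sets",
]

IdSet = FrozenSet[str]


class BudgetExceededError(RuntimeError):
    """Raised when an exhaustive search would exceed its combination budget."""


def _canon(sets: Sequence[IdSet]) -> List[IdSet]:
    return sorted(set(sets), key=lambda s: tuple(sorted(s)))


@dataclass
class LethalSetCollection:
    """Minimal lethal knockout sets grouped by cardinality.

    ``candidate_ids`` is the full knockout-candidate universe analyzed; its
    size is the normalization constant X of the scoring stage. The count of
    stored cardinality-j sets containing a target i is the involvement count
    y_ij.
    """

    level_n: int
    target_kind: str
    candidate_ids: List[str]
    sets_by_level: Dict[int, List[IdSet]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets_by_level = {
            int(j): _canon(v) for j, v in self.sets_by_level.items()
        }
        for j in range(1, self.level_n + 1):
            self.sets_by_level.setdefault(j, [])
        cand = set(self.candidate_ids)
        for j, sets in self.sets_by_level.items():
            if not 1 <= j <= self.level_n:
                raise ValueError(f"stored level {j} outside 1..{self.level_n}")
            for s in sets:
                if len(s) != j:
                    raise ValueError(f"set {sorted(s)} stored at wrong level {j}")
                if not s <= cand:
                    raise ValueError(
                        f"set {sorted(s)} contains non-candidate ids"
                    )
        stored = self.all_sets()
        for a in stored:
            for b in stored:
                if a < b:
                    raise ValueError(
                        f"minimality violated: {sorted(a)} is a subset of "
                        f"{sorted(b)}"
                    )

    @property
    def X(self) -> int:
        return len(self.candidate_ids)

    def all_sets(self) -> List[IdSet]:
        return [s for j in sorted(self.sets_by_level) for s in self.sets_by_level[j]]

    def involvement(self, target_id: str) -> Dict[int, int]:
        """y_ij for one target: stored cardinality-j sets containing it."""
        if target_id not in set(self.candidate_ids):
            raise KeyError(f"unknown target id: {target_id!r}")
        return {
            j: sum(1 for s in self.sets_by_level.get(j, ()) if target_id in s)
            for j in range(1, self.level_n + 1)
        }

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "level_n": self.level_n,
            "target_kind": self.target_kind,
            "candidate_ids": list(self.candidate_ids),
            "sets_by_level": {
                str(j): [sorted(s) for s in self.sets_by_level[j]]
                for j in sorted(self.sets_by_level)
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LethalSetCollection":
        return cls(
            level_n=int(doc["level_n"]),
            target_kind=doc["target_kind"],
            candidate_ids=list(doc["candidate_ids"]),
            sets_by_level={
                int(j): [frozenset(s) for s in sets]
                for j, sets in doc["sets_by_level"].items()
            },
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LethalSetCollection":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("level\tmembers\n")
            for j in sorted(self.sets_by_level):
                for s in self.sets_by_level[j]:
                    fh.write(f"{j}\t{','.join(sorted(s))}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LethalSetCollection):
            return NotImplemented
        return (
            self.level_n == other.level_n
            and self.target_kind == other.target_kind
            and list(self.candidate_ids) == list(other.candidate_ids)
            and {j: v for j, v in self.sets_by_level.items()}
            == {j: v for j, v in other.sets_by_level.items()}
        )


# ---------------------------------------------------------------------------
# knockout-target adapters
# ---------------------------------------------------------------------------

class _TargetSpace:
    """Maps candidate id-sets to blocked-reaction signatures.

    Gene-level analysis runs on the logically transformed model, and gene
    sets that disable the same reactions share one LP verdict through the
    session cache keyed by the blocked-reaction signature.
    """

    def __init__(self, model: MetabolicModel, config: AnalysisConfig):
        self.config = config
        self.kind = config.targets
        if self.kind == "genes":
            self.model = logical_transform(model)
        else:
            self.model = model
        self.session = FBASession(self.model, config)
        self.candidates = config.candidate_ids(model)
        if self.kind == "genes":
            self._genes_of_rxn = {
                r.id: (r.gpr.genes if r.gpr is not None else frozenset())
                for r in self.model.reactions
            }
            self._disabled_cache: Dict[IdSet, FrozenSet[int]] = {}
        self._rxn_id_at = {
            i: r.id for i, r in enumerate(self.model.reactions)
        }

    def blocked(self, ids: IdSet) -> FrozenSet[int]:
        if self.kind == "reactions":
            return self.session.rxn_indices(ids)
        cached = self._disabled_cache.get(ids)
        if cached is None:
            cached = self.session.rxn_indices(disabled_reactions(self.model, ids))
            self._disabled_cache[ids] = cached
        return cached

    def is_lethal(self, ids: IdSet) -> bool:
        return self.session.is_lethal_indices(self.blocked(ids))

    def extension_candidates(self, base: IdSet) -> List[str]:
        """Candidates that can still turn ``base`` into a lethal set.

        Reactions: members of the minimum-norm flux support of the knockout
        model. Genes: genes appearing in the GPR of any support reaction
        (a gene outside those rules cannot disable a support reaction, alone
        or in combination).
        """
        support = self.session.min_norm_support(self.blocked(base))
        support_ids = {self._rxn_id_at[i] for i in support}
        if self.kind == "reactions":
            pool = support_ids
        else:
            pool = set()
            for rid in support_ids:
                pool |= self._genes_of_rxn[rid]
        return sorted((pool & set(self.candidates)) - base)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def find_essential(
    model: MetabolicModel, config: Optional[AnalysisConfig] = None
) -> List[str]:
    """Candidate ids whose single knockout is lethal, lexicographically."""
    config = config or AnalysisConfig()
    space = _TargetSpace(model, config)
    _check_viable(space)
    return sorted(
        x
        for x in space.extension_candidates(frozenset())
        if space.is_lethal(frozenset([x]))
    )


def _check_viable(space: _TargetSpace) -> None:
    if space.session.is_lethal_indices(frozenset()):
        raise ValueError(
            "wild-type objective is already at or below the lethality "
            "threshold; essentiality analysis is undefined"
        )


def _contains_stored_subset(s: IdSet, stored: Dict[int, set]) -> bool:
    return any(t <= s for j in stored for t in stored[j] if t != s)


def _fingerprint(model: MetabolicModel, config: AnalysisConfig) -> str:
    doc = {
        "model": model.id,
        "reactions": [
            (r.id, sorted(r.stoichiometry.items()), r.lower_bound, r.upper_bound)
            for r in model.reactions
        ],
        "objective": model.objective_id,
        "targets": config.targets,
        "excluded": sorted(config.excluded_ids),
        "epsilon": config.lethality_epsilon,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def enumerate_minimal_lethal_sets(
    model: MetabolicModel,
    config: Optional[AnalysisConfig] = None,
    checkpoint_dir: Optional[str | Path] = None,
) -> LethalSetCollection:
    """All minimal lethal knockout sets of cardinality 1..level_n.

    Level 1 holds the essential singletons; level j >= 2 holds every
    cardinality-j candidate set that is lethal while no proper subset is.
    When ``checkpoint_dir`` is given the partial collection (plus search
    frontier) is flushed there after each completed level, and a matching
    checkpoint is resumed instead of recomputed.
    """
    config = config or AnalysisConfig()
    if config.level_n > 3:
        warnings.warn(
            f"level_n={config.level_n}: pruned enumeration beyond level 3 can "
            "be very expensive on genome-scale models",
            stacklevel=2,
        )
    space = _TargetSpace(model, config)
    _check_viable(space)

    stored: Dict[int, set] = {j: set() for j in range(1, config.level_n + 1)}
    frontier: List[IdSet] = [frozenset()]
    start_level = 1

    ckpt_path = None
    if checkpoint_dir is not None:
        ckpt_path = Path(checkpoint_dir) / "sla_checkpoint.json"
        resumed = _load_checkpoint(ckpt_path, _fingerprint(model, config), config)
        if resumed is not None:
            stored, frontier, start_level = resumed

    for j in range(start_level, config.level_n + 1):
        next_frontier: List[IdSet] = []
        seen: set = set()
        for base in frontier:
            for x in space.extension_candidates(base):
                s = base | {x}
                if s in seen:
                    continue
                seen.add(s)
                if _contains_stored_subset(s, stored):
                    continue
                if space.is_lethal(s):
                    stored[j].add(s)
                elif j < config.level_n:
                    next_frontier.append(s)
        frontier = sorted(next_frontier, key=lambda s: tuple(sorted(s)))
        if ckpt_path is not None:
            _save_checkpoint(
                ckpt_path, _fingerprint(model, config), stored, frontier, j
            )

    return LethalSetCollection(
        level_n=config.level_n,
        target_kind=config.targets,
        candidate_ids=space.candidates,
        sets_by_level={j: _canon(list(v)) for j, v in stored.items()},
    )


def _save_checkpoint(path, fingerprint, stored, frontier, completed_level):
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "fingerprint": fingerprint,
        "completed_level": completed_level,
        "stored": {str(j): [sorted(s) for s in _canon(list(v))] for j, v in stored.items()},
        "frontier": [sorted(s) for s in frontier],
    }
    path.write_text(json.dumps(doc) + "\n")


def _load_checkpoint(path, fingerprint, config):
    if not path.exists():
        return None
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError:
        return None
    if doc.get("fingerprint") != fingerprint:
        return None
    completed = int(doc["completed_level"])
    if completed >= config.level_n:
        completed = config.level_n  # fully done; loop below won't run
    stored = {j: set() for j in range(1, config.level_n + 1)}
    for j_str, sets in doc["stored"].items():
        j = int(j_str)
        if j <= config.level_n:
            stored[j] = {frozenset(s) for s in sets}
    frontier = [frozenset(s) for s in doc["frontier"]]
    return stored, frontier, completed + 1


def brute_force_lethal_sets(
    model: MetabolicModel,
    config: Optional[AnalysisConfig] = None,
) -> LethalSetCollection:
    """Exhaustively test every candidate combination up to level n.

    Ground truth for the pruned path on small models. Refuses to start when
    the total combination count exceeds ``config.brute_force_budget``.
    """
    config = config or AnalysisConfig()
    space = _TargetSpace(model, config)
    _check_viable(space)
    candidates = space.candidates
    X = len(candidates)
    total = sum(math.comb(X, j) for j in range(1, config.level_n + 1))
    if total > config.brute_force_budget:
        raise BudgetExceededError(
            f"exhaustive search over {X} candidates up to level "
            f"{config.level_n} requires {total} combinations "
            f"(budget {config.brute_force_budget})"
        )
    stored: Dict[int, set] = {j: set() for j in range(1, config.level_n + 1)}
    for j in range(1, config.level_n + 1):
        for combo in itertools.combinations(candidates, j):
            s = frozenset(combo)
            if _contains_stored_subset(s, stored):
                continue
            if space.is_lethal(s):
                stored[j].add(s)
    return LethalSetCollection(
        level_n=config.level_n,
        target_kind=config.targets,
        candidate_ids=candidates,
        sets_by_level={j: _canon(list(v)) for j, v in stored.items()},
    )
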