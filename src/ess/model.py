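"""Constraint-based model representation and knockout semantics.

The in-memory model is deliberately small: metabolites, reactions with a
stoichiometry map and flux bounds (mmol gDW^-1 h^-1 by convention), optional
GPR rules, a gene list, and the identifier of the objective reaction.
Reversibility is encoded purely in the bounds (lb < 0); reactions are never
split into forward/backward halves, so knocking out an identifier removes
both directions at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Literal, Optional, Set

from .gpr import GPRRule, evaluate_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "AnalysisConfig",
    "ModelValidationError",
    "apply_knockout",
    "logical_transform",
    "disabled_reactions",
]

TargetKind = Literal["reactions", "genes"]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GPRRule] = None
    name: str = ""
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def substrates(self) -> Set[str]:
        return {m for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> Set[str]:
        return {m for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicModel:
    """A validated constraint-based model.

    The gene list is derived from the union of GPR leaves at validation time;
    extra genes supplied by the source file are preserved so that genes with
    no GPR appearance remain reportable.
    """

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    objective_id: str
    genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id: {rid!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if any(not m for m in met_ids):
            raise ModelValidationError("empty metabolite id")
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        gpr_genes: Set[str] = set()
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(unknown)}"
                )
            # zero coefficients are dropped rather than stored
            zeros = [m for m, c in r.stoichiometry.items() if c == 0]
            for m in zeros:
                del r.stoichiometry[m]
            if r.gpr is not None:
                gpr_genes |= r.gpr.genes
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        undeclared = gpr_genes - set(self.genes)
        if undeclared:
            # genes referenced only in GPRs are adopted into the gene list
            self.genes = sorted(set(self.genes) | gpr_genes)
        self._rxn_index = {r.id: r for r in self.reactions}
        self._met_index = {m.id: m for m in self.metabolites}

    # -- copying --------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    gpr=r.gpr,
                    name=r.name,
                    subsystem=r.subsystem,
                )
                for r in self.reactions
            ],
            objective_id=self.objective_id,
            genes=list(self.genes),
        )

    def remove_reaction(self, rid: str) -> "MetabolicModel":
        """A copy with ``rid`` deleted outright (not merely blocked)."""
        if not self.has_reaction(rid):
            raise KeyError(f"unknown reaction id: {rid!r}")
        if rid == self.objective_id:
            raise ValueError("cannot remove the objective reaction")
        out = self.copy()
        out.reactions = [r for r in out.reactions if r.id != rid]
        out.validate()
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by the lethality and enumeration machinery.

    ``level_n`` is the maximal cardinality of knockout combinations examined
    (1 = single deletions only). ``excluded_ids`` removes pseudo reactions
    such as ATP maintenance from knockout candidacy; the objective reaction
    is always excluded automatically. ``lethality_epsilon`` of ``None``
    selects the adaptive default max(1e-6, 1e-3 x wild-type objective).
    """

    level_n: int = 3
    targets: TargetKind = "reactions"
    excluded_ids: FrozenSet[str] = frozenset()
    lethality_epsilon: Optional[float] = None
    solver_name: str = "highs"
    zero_flux_tol: float = 1e-6
    brute_force_budget: int = 500_000

    def __post_init__(self) -> None:
        if self.level_n < 1:
            raise ValueError(f"level_n must be >= 1, got {self.level_n}")
        if self.targets not in ("reactions", "genes"):
            raise ValueError(f"unknown target kind: {self.targets!r}")
        if self.lethality_epsilon is not None and self.lethality_epsilon < 0:
            raise ValueError("lethality_epsilon must be non-negative")
        object.__setattr__(self, "excluded_ids", frozenset(self.excluded_ids))

    def candidate_ids(self, model: MetabolicModel) -> List[str]:
        """The knockout-candidate universe (defines the normalization X).

        All reactions (or genes) minus exclusions minus the objective
        reaction, in lexicographic order. Blocked reactions remain
        candidates; they simply never appear in lethal sets.
        """
        if self.targets == "reactions":
            pool: Iterable[str] = (r.id for r in model.reactions)
        else:
            pool = model.genes
        drop = set(self.excluded_ids) | {model.objective_id}
        return sorted(set(pool) - drop)


def disabled_reactions(
    model: MetabolicModel, deleted_genes: Iterable[str]
) -> FrozenSet[str]:
    """Reaction ids whose GPR evaluates false under a gene deletion set."""
    deleted = set(deleted_genes)
    if not deleted:
        return frozenset()
    out = set()
    for r in model.reactions:
        if r.gpr is not None and not deleted.isdisjoint(r.gpr.genes):
            if not evaluate_gpr(r.gpr, deleted):
                out.add(r.id)
    return frozenset(out)


def apply_knockout(
    model: MetabolicModel,
    target_ids: Iterable[str],
    targets: TargetKind = "reactions",
) -> MetabolicModel:
    """A copy of ``model`` with the knockout applied; the input is untouched.

    Reaction targets have both flux bounds set to zero. Gene targets zero the
    bounds of every reaction whose GPR evaluates false under the deletion.
    """
    target_set = set(target_ids)
    if targets == "reactions":
        unknown = target_set - set(model.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
        blocked = target_set
    elif targets == "genes":
        unknown = target_set - set(model.genes)
        if unknown:
            raise KeyError(f"unknown gene ids: {sorted(unknown)}")
        blocked = set(disabled_reactions(model, target_set))
    else:
        raise ValueError(f"unknown target kind: {targets!r}")
    out = model.copy()
    for r in out.reactions:
        if r.id in blocked:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def logical_transform(model: MetabolicModel) -> MetabolicModel:
    """Canonicalize every GPR to its minimal disjunctive normal form.

    Each disjunct of the result is a minimal gene set sufficient to keep the
    reaction active, which makes enzyme redundancy explicit and turns
    gene-set lethality checks into set comparisons. Gene-deletion outcomes
    are unchanged for every possible deletion set (monotone-logic identity).
    """
    out = model.copy()
    for r in out.reactions:
        if r.gpr is not None:
            r.gpr = r.gpr.transformed()
    return out
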