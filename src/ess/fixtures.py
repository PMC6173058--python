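"""Programmatic toy and synthetic models with known lethal structure.

Every generated model is a small mass-balanced pathway: an uptake reaction
feeds a chain of segments ending in the objective. Serial segments make
their single reaction essential; k-way parallel branch bundles make the
bundle a minimal lethal set of cardinality k; pair groups sharing a common
member are realized as a skip reaction over a series of the other members.
All fluxes use unit stoichiometry with uptake bound 10 so LP answers stay
hand-checkable.

The generator verifies its own output: by default the realized minimal
lethal structure is recomputed with the exhaustive oracle and compared to
the requested specification, so a fixture that silently deviates from its
declared structure cannot exist.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .gpr import parse_gpr
from .model import AnalysisConfig, MetabolicModel, Metabolite, Reaction

__all__ = [
    "LethalStructureSpec",
    "GenerationError",
    "fig1a_model",
    "fig1b_model",
    "synth_model",
    "synth_config",
    "PSEUDO_UPTAKE_ID",
]

#: id of the pseudo uptake reaction every synthetic model carries; exclude it
#: from knockout candidacy the same way maintenance pseudo-reactions are.
PSEUDO_UPTAKE_ID = "SRC"


class GenerationError(ValueError):
    """Raised when a lethal-structure specification cannot be realized."""


@dataclass
class LethalStructureSpec:
    """Requested minimal lethal structure of a synthetic model.

    ``n_targets`` is the number of knockout candidates (X); ids not used by
    essentials or groups are filled with blocked decoy reactions.
    """

    n_targets: int
    essential_ids: List[str] = field(default_factory=list)
    sl_groups: List[Set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sl_groups = [set(g) for g in self.sl_groups]
        ess = set(self.essential_ids)
        if len(ess) != len(self.essential_ids):
            raise GenerationError("duplicate essential ids")
        for g in self.sl_groups:
            if len(g) < 2:
                raise GenerationError(f"group {sorted(g)} has fewer than 2 members")
            if g & ess:
                raise GenerationError(
                    f"group {sorted(g)} contains essential ids {sorted(g & ess)}; "
                    "such a group could never be minimal"
                )
        for a in self.sl_groups:
            for b in self.sl_groups:
                if a is not b and a <= b:
                    raise GenerationError(
                        f"group {sorted(a)} is a subset of group {sorted(b)}"
                    )
        named = ess | {x for g in self.sl_groups for x in g}
        if len(named) + 0 > self.n_targets:
            raise GenerationError(
                f"{len(named)} named targets exceed n_targets={self.n_targets}"
            )

    @property
    def member_ids(self) -> Set[str]:
        return set(self.essential_ids) | {x for g in self.sl_groups for x in g}

    @property
    def min_check_level(self) -> int:
        return max([len(g) for g in self.sl_groups], default=1)


def _model(
    mid: str,
    mets: Sequence[str],
    rxns: Sequence[Tuple[str, Dict[str, float], float, float, Optional[str]]],
    objective: str,
) -> MetabolicModel:
    return MetabolicModel(
        id=mid,
        metabolites=[Metabolite(id=m, compartment="c") for m in mets],
        reactions=[
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr) if gpr else None,
            )
            for rid, stoich, lb, ub, gpr in rxns
        ],
        objective_id=objective,
    )


def fig1a_model() -> MetabolicModel:
    """Toy pathway: four knockout candidates A-D plus an objective (X = 4).

    A is the unbranched trunk (singly essential); C and D are parallel
    branches that can each supply the objective precursor, so {C, D} is the
    only minimal synthetic-lethal pair; B is a side branch into a dead end
    that never becomes limiting. The complete minimal lethal structure up to
    level 2 is therefore {{A}, {C, D}}, and the level-2 score of C is
    1!/4 = 0.25. One gene (gA...gD) guards each candidate so the same
    structure exists at the gene level.
    """
    return _model(
        "fig1a",
        ["m1", "m2", "m3"],
        [
            ("A", {"m1": 1.0}, 0.0, 10.0, "gA"),
            ("B", {"m1": -1.0, "m3": 1.0}, 0.0, 1000.0, "gB"),
            ("C", {"m1": -1.0, "m2": 1.0}, 0.0, 1000.0, "gC"),
            ("D", {"m1": -1.0, "m2": 1.0}, 0.0, 1000.0, "gD"),
            ("OBJ", {"m2": -1.0}, 0.0, 1000.0, None),
        ],
        "OBJ",
    )


def fig1b_model() -> MetabolicModel:
    """Toy pathway with a hot-spot reaction (X = 4).

    Two routes reach the objective precursor: B then C, or the direct skip
    D. Hence {B, D} and {C, D} are the minimal synthetic-lethal pairs: D
    participates in two of them and outscores B and C (0.5 vs 0.25 at
    level 2), while trunk A stays essential.
    """
    return _model(
        "fig1b",
        ["m1", "m2", "m3"],
        [
            ("A", {"m1": 1.0}, 0.0, 10.0, "gA"),
            ("B", {"m1": -1.0, "m2": 1.0}, 0.0, 1000.0, "gB"),
            ("C", {"m2": -1.0, "m3": 1.0}, 0.0, 1000.0, "gC"),
            ("D", {"m1": -1.0, "m3": 1.0}, 0.0, 1000.0, "gD"),
            ("OBJ", {"m3": -1.0}, 0.0, 1000.0, None),
        ],
        "OBJ",
    )


def synth_config(
    spec_or_level: "LethalStructureSpec | int", **kwargs
) -> AnalysisConfig:
    """Analysis configuration for a synthetic model.

    Excludes the pseudo uptake reaction from candidacy, mirroring how
    maintenance pseudo-reactions are excluded in real models.
    """
    level = (
        spec_or_level.min_check_level + 0
        if isinstance(spec_or_level, LethalStructureSpec)
        else int(spec_or_level)
    )
    kwargs.setdefault("excluded_ids", frozenset({PSEUDO_UPTAKE_ID}))
    kwargs.setdefault("level_n", max(level, 2))
    return AnalysisConfig(**kwargs)


def _group_components(groups: List[Set[str]]) -> List[List[Set[str]]]:
    """Connected components of groups under shared membership."""
    remaining = list(groups)
    components: List[List[Set[str]]] = []
    while remaining:
        comp = [remaining.pop(0)]
        members = set(comp[0])
        changed = True
        while changed:
            changed = False
            for g in list(remaining):
                if g & members:
                    comp.append(g)
                    members |= g
                    remaining.remove(g)
                    changed = True
        components.append(comp)
    return components


def synth_model(
    spec: LethalStructureSpec,
    seed: int = 0,
    with_genes: bool = False,
    verify: bool = True,
) -> MetabolicModel:
    """Realize a mass-balanced model whose minimal lethal sets equal ``spec``.

    The chain order and decoy placement are drawn from ``seed``; the same
    spec and seed always produce an identical model. With ``with_genes``
    each candidate reaction receives a randomized GPR (single genes,
    isozyme pairs, enzyme complexes, occasional gene sharing). Unless
    ``verify`` is disabled, the exhaustive oracle re-derives the minimal
    lethal structure of the freshly built model and a mismatch raises
    :class:`GenerationError`.

    Realizable specifications: disjoint groups of any size (parallel branch
    bundles) and families of size-2 groups sharing one common member (a skip
    reaction over a series of the other members). Other overlap patterns
    force hidden subset structure and are rejected.
    """
    rng = random.Random(seed)
    components = _group_components(spec.sl_groups)

    # classify components before emitting anything
    segments: List[Tuple[str, object]] = [("essential", e) for e in spec.essential_ids]
    for comp in components:
        if len(comp) == 1:
            segments.append(("bundle", sorted(comp[0])))
            continue
        if any(len(g) != 2 for g in comp):
            raise GenerationError(
                f"overlapping groups {sorted(map(sorted, comp))} with a member "
                "of size != 2 cannot be realized without hidden subsets"
            )
        common = set.intersection(*[set(g) for g in comp])
        if len(common) != 1:
            raise GenerationError(
                f"overlapping pair groups {sorted(map(sorted, comp))} must "
                "share exactly one common member"
            )
        hub = common.pop()
        spokes = sorted({x for g in comp for x in g} - {hub})
        if len(spokes) != len(comp):
            raise GenerationError(
                f"pair groups {sorted(map(sorted, comp))} repeat a non-hub member"
            )
        segments.append(("star", (hub, spokes)))
    rng.shuffle(segments)

    mets = ["m0"]
    rxns: List[Tuple[str, Dict[str, float], float, float, Optional[str]]] = [
        (PSEUDO_UPTAKE_ID, {"m0": 1.0}, 0.0, 10.0, None)
    ]

    def new_met() -> str:
        mets.append(f"m{len(mets)}")
        return mets[-1]

    head = "m0"
    for kind, payload in segments:
        if kind == "essential":
            nxt = new_met()
            rxns.append((payload, {head: -1.0, nxt: 1.0}, 0.0, 1000.0, None))
            head = nxt
        elif kind == "bundle":
            nxt = new_met()
            for rid in payload:
                rxns.append((rid, {head: -1.0, nxt: 1.0}, 0.0, 1000.0, None))
            head = nxt
        else:  # star: hub skips the series of spokes
            hub, spokes = payload
            start = head
            for rid in spokes:
                nxt = new_met()
                rxns.append((rid, {head: -1.0, nxt: 1.0}, 0.0, 1000.0, None))
                head = nxt
            rxns.append((hub, {start: -1.0, head: 1.0}, 0.0, 1000.0, None))
    rxns.append(("OBJ", {head: -1.0}, 0.0, 1000.0, None))

    # blocked decoys: consume a random chain metabolite into a dead end
    n_decoys = spec.n_targets - len(spec.member_ids)
    for i in range(n_decoys):
        src = rng.choice(mets[: len(mets)])
        dead = new_met()
        rxns.append((f"Z{i:02d}", {src: -1.0, dead: 1.0}, 0.0, 1000.0, None))

    if with_genes:
        rxns = _attach_genes(rxns, rng)

    model = _model(f"synth_seed{seed}", mets, rxns, "OBJ")

    if verify:
        from .sla import brute_force_lethal_sets

        config = synth_config(spec)
        got = brute_force_lethal_sets(model, config)
        expected: Dict[int, Set[frozenset]] = {}
        for e in spec.essential_ids:
            expected.setdefault(1, set()).add(frozenset([e]))
        for g in spec.sl_groups:
            expected.setdefault(len(g), set()).add(frozenset(g))
        realized = {
            j: set(v) for j, v in got.sets_by_level.items() if v
        }
        if realized != expected:
            raise GenerationError(
                f"realized lethal structure {realized} does not match the "
                f"requested specification {expected}"
            )
    return model


def _attach_genes(rxns, rng: random.Random):
    out = []
    used_genes: List[str] = []
    for rid, stoich, lb, ub, gpr in rxns:
        if rid in (PSEUDO_UPTAKE_ID, "OBJ"):
            out.append((rid, stoich, lb, ub, None))
            continue
        roll = rng.random()
        g1 = f"g_{rid}"
        if roll < 0.5 or not used_genes:
            rule = g1
        elif roll < 0.7:
            rule = f"{g1} or g_{rid}_iso"
        elif roll < 0.9:
            rule = f"{g1} and g_{rid}_sub"
        else:
            rule = rng.choice(used_genes)  # enzyme shared with another reaction
        used_genes.append(g1)
        out.append((rid, stoich, lb, ub, rule))
    return out
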