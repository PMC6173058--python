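"""Derived network graphs and topology-centrality baselines.

From a constraint-based model three directed graphs can be derived:

* MMN (metabolite-metabolite): edge m1 -> m2 when some reaction consumes m1
  and produces m2; reversible reactions contribute both orientations.
* RRN (reaction-reaction): edge r1 -> r2 when a non-currency product of r1
  is a substrate of r2.
* GGN (gene-gene): edge g1 -> g2 when g1 appears in the GPR of r1, g2 in
  the GPR of r2, and r1 -> r2 is an RRN edge.

Currency metabolites (ubiquitous cofactors and carriers such as ATP or H2O)
are removed before building the RRN and GGN, otherwise nearly every
reaction pair would be connected through them. Node importance is scored by
betweenness, closeness, eccentricity and total degree, computed on the
largest weakly connected component; nodes outside it carry zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .model import MetabolicModel

__all__ = [
    "DerivedGraph",
    "DEFAULT_CURRENCY_METABOLITES",
    "build_graph",
    "centralities",
    "currency_metabolite_ids",
]

# Base names of the shipped currency-metabolite list; matched against
# metabolite ids with their compartment suffix stripped (atp_c, atp_m, ...).
DEFAULT_CURRENCY_METABOLITES: Tuple[str, ...] = (
    "atp", "adp", "amp",
    "nad", "nadh", "nadp", "nadph",
    "h2o", "h", "co2", "pi", "ppi", "coa", "o2",
)


@dataclass
class DerivedGraph:
    kind: str  # "MMN" | "RRN" | "GGN"
    nodes: List[str]
    directed_edges: List[Tuple[str, str]]
    currency_removed: List[str] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(self.directed_edges):
                fh.write(f"{a}\t{b}\n")


def currency_metabolite_ids(
    model: MetabolicModel, currency: Optional[Iterable[str]] = None
) -> Set[str]:
    """Resolve a currency list against a model's metabolite ids.

    Entries match either a full compartment-qualified id (``atp_c``) or a
    base name applied to every compartment (``atp``). Entries resolving to
    nothing are warned about and ignored.
    """
    names = tuple(DEFAULT_CURRENCY_METABOLITES if currency is None else currency)
    met_ids = set(model.metabolite_ids)
    resolved: Set[str] = set()
    for entry in names:
        if entry in met_ids:
            resolved.add(entry)
            continue
        matches = {
            m for m in met_ids if m.rsplit("_", 1)[0] == entry or m == entry
        }
        if matches:
            resolved |= matches
        elif currency is not None:
            warnings.warn(
                f"currency metabolite {entry!r} matches nothing in the model",
                stacklevel=2,
            )
    return resolved


def _production_sets(r) -> Tuple[Set[str], Set[str]]:
    """(consumed, produced) metabolite sets, widened for reversibility."""
    consumed, produced = set(r.substrates), set(r.products)
    if r.reversible:
        consumed, produced = consumed | produced, produced | consumed
    return consumed, produced


def build_graph(
    model: MetabolicModel,
    kind: str,
    currency_ids: Optional[Iterable[str]] = None,
) -> DerivedGraph:
    """Build the MMN, RRN or GGN of a model.

    ``currency_ids`` (base names or full ids) defaults to the shipped list
    and applies to RRN/GGN construction only.
    """
    kind = kind.upper()
    if kind not in ("MMN", "RRN", "GGN"):
        raise ValueError(f"unknown graph kind: {kind!r}")
    currency = currency_metabolite_ids(model, currency_ids)

    if kind == "MMN":
        edges = set()
        for r in model.reactions:
            consumed, produced = _production_sets(r)
            for m1 in consumed:
                for m2 in produced:
                    if m1 != m2:
                        edges.add((m1, m2))
        return DerivedGraph(
            kind="MMN",
            nodes=sorted(model.metabolite_ids),
            directed_edges=sorted(edges),
            currency_removed=[],
        )

    # RRN shared by GGN
    rrn_edges = set()
    prod, cons = {}, {}
    for r in model.reactions:
        consumed, produced = _production_sets(r)
        cons[r.id] = consumed - currency
        prod[r.id] = produced - currency
    for r1 in model.reactions:
        for r2 in model.reactions:
            if r1.id != r2.id and prod[r1.id] & cons[r2.id]:
                rrn_edges.add((r1.id, r2.id))
    if kind == "RRN":
        return DerivedGraph(
            kind="RRN",
            nodes=sorted(model.reaction_ids),
            directed_edges=sorted(rrn_edges),
            currency_removed=sorted(currency),
        )

    genes_of = {
        r.id: (r.gpr.genes if r.gpr is not None else frozenset())
        for r in model.reactions
    }
    ggn_edges = set()
    for r1, r2 in rrn_edges:
        for g1 in genes_of[r1]:
            for g2 in genes_of[r2]:
                if g1 != g2:
                    ggn_edges.add((g1, g2))
    return DerivedGraph(
        kind="GGN",
        nodes=sorted(model.genes),
        directed_edges=sorted(ggn_edges),
        currency_removed=sorted(currency),
    )


def centralities(graph: DerivedGraph, normalized: bool = False) -> pd.DataFrame:
    """Betweenness, closeness, eccentricity and degree per node.

    Computed on the largest weakly connected component of the directed
    graph; nodes outside it get zeros and ``in_lcc = False``. Betweenness is
    directed shortest-path betweenness (raw counts unless ``normalized``);
    closeness uses incoming-distance closeness with the standard
    reachable-set scaling; eccentricity is taken on the undirected view of
    the component so that it is finite for components that are only weakly
    connected; degree is in-degree plus out-degree within the component.
    """
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), sorted(c)))
    lcc_nodes = components[0]
    sub = g.subgraph(lcc_nodes).copy()
    betweenness = nx.betweenness_centrality(sub, normalized=normalized)
    closeness = nx.closeness_centrality(sub)
    eccentricity = nx.eccentricity(sub.to_undirected()) if len(sub) > 1 else {
        n: 0 for n in sub
    }
    rows = []
    for node in graph.nodes:
        if node in lcc_nodes:
            rows.append(
                {
                    "node": node,
                    "betweenness": float(betweenness[node]),
                    "closeness": float(closeness[node]),
                    "eccentricity": float(eccentricity[node]),
                    "degree": int(sub.in_degree(node) + sub.out_degree(node)),
                    "in_lcc": True,
                }
            )
        else:
            rows.append(
                {
                    "node": node,
                    "betweenness": 0.0,
                    "closeness": 0.0,
                    "eccentricity": 0.0,
                    "degree": 0,
                    "in_lcc": False,
                }
            )
    return pd.DataFrame(rows).set_index("node").sort_index()
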