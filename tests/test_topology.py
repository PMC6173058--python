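"""Derived graphs (MMN/RRN/GGN) and centrality baselines."""

import pytest

import ess
from ess.model import MetabolicModel, Metabolite, Reaction
from ess.topology import DerivedGraph, build_graph, centralities


def _linear_chain(currency_mid=False):
    """EX -> r1 -> r2 -> r3, optionally coupled only through a currency met."""
    mid1 = "atp_c" if currency_mid else "b"
    mid2 = "atp_c" if currency_mid else "c"
    mets = ["a", "d"] + (["atp_c"] if currency_mid else ["b", "c"])
    return MetabolicModel(
        id="chain3",
        metabolites=[Metabolite(m, compartment="c") for m in dict.fromkeys(mets)],
        reactions=[
            Reaction("r1", {"a": -1.0, mid1: 1.0}, 0.0, 10.0, gpr=ess.parse_gpr("g1")),
            Reaction("r2", {mid1: -1.0, mid2: 1.0}, 0.0, 10.0, gpr=ess.parse_gpr("g2")),
            Reaction("r3", {mid2: -1.0, "d": 1.0}, 0.0, 10.0, gpr=ess.parse_gpr("g3")),
            Reaction("EX", {"a": 1.0}, 0.0, 10.0),
        ],
        objective_id="r3",
    )


def test_rrn_of_linear_chain_is_a_path():
    g = build_graph(_linear_chain(), "RRN")
    assert ("r1", "r2") in g.directed_edges and ("r2", "r3") in g.directed_edges
    assert ("r1", "r3") not in g.directed_edges
    assert ("r2", "r1") not in g.directed_edges


def test_currency_coupling_severs_rrn():
    g = build_graph(_linear_chain(currency_mid=True), "RRN")
    assert ("r1", "r2") not in g.directed_edges
    assert ("r2", "r3") not in g.directed_edges
    assert "atp_c" in g.currency_removed


def test_shrinking_currency_list_never_removes_rrn_edges():
    model = _linear_chain(currency_mid=True)
    with_currency = build_graph(model, "RRN")
    without = build_graph(model, "RRN", currency_ids=[])
    assert set(with_currency.directed_edges) <= set(without.directed_edges)
    assert len(without.directed_edges) > len(with_currency.directed_edges)


def test_reversible_reaction_gives_both_mmn_orientations():
    model = MetabolicModel(
        id="rev",
        metabolites=[Metabolite("A", compartment="c"), Metabolite("B", compartment="c")],
        reactions=[Reaction("r", {"A": -1.0, "B": 1.0}, -10.0, 10.0)],
        objective_id="r",
    )
    g = build_graph(model, "MMN")
    assert ("A", "B") in g.directed_edges and ("B", "A") in g.directed_edges


def test_ggn_follows_rrn_edges():
    g = build_graph(_linear_chain(), "GGN")
    assert ("g1", "g2") in g.directed_edges and ("g2", "g3") in g.directed_edges
    assert ("g1", "g3") not in g.directed_edges


def test_no_self_loops_in_any_graph(ecoli):
    for kind in ("MMN", "RRN"):
        g = build_graph(ecoli, kind)
        assert all(a != b for a, b in g.directed_edges)


def test_path_betweenness_peaks_in_middle():
    g = DerivedGraph("RRN", ["a", "b", "c"], [("a", "b"), ("b", "c")])
    table = centralities(g)
    assert table.loc["b", "betweenness"] > 0
    assert table.loc["a", "betweenness"] == table.loc["c", "betweenness"] == 0.0


def test_isolated_node_out_of_lcc_zeroed():
    g = DerivedGraph("RRN", ["a", "b", "c", "lonely"], [("a", "b"), ("b", "c")])
    table = centralities(g)
    row = table.loc["lonely"]
    assert not row["in_lcc"]
    assert row["betweenness"] == row["closeness"] == row["eccentricity"] == 0.0
    assert row["degree"] == 0


def test_cycle_betweenness_symmetric():
    nodes = ["a", "b", "c", "d"]
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
    table = centralities(DerivedGraph("RRN", nodes, edges))
    values = table["betweenness"].round(9).unique()
    assert len(values) == 1
    # 12 ordered shortest paths of lengths 1..3; each source contributes
    # 0+1+2 = 3 interior crossings, 12 total shared evenly over 4 nodes
    assert values[0] == pytest.approx(3.0)


def test_centralities_permutation_invariant():
    nodes = ["a", "b", "c", "d"]
    edges = [("a", "b"), ("b", "c"), ("b", "d")]
    relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
    t1 = centralities(DerivedGraph("RRN", nodes, edges))
    t2 = centralities(
        DerivedGraph(
            "RRN",
            [relabel[n] for n in nodes],
            [(relabel[a], relabel[b]) for a, b in edges],
        )
    )
    for old, new in relabel.items():
        for col in ("betweenness", "closeness", "eccentricity", "degree"):
            assert t1.loc[old, col] == pytest.approx(t2.loc[new, col])


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="empty"):
        centralities(DerivedGraph("RRN", [], []))


def test_unknown_currency_id_warned():
    with pytest.warns(UserWarning, match="matches nothing"):
        build_graph(_linear_chain(), "RRN", currency_ids=["unobtainium"])
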