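"""Score-table comparison, rank correlation and zero/non-zero overlap."""

import numpy as np
import pandas as pd
import pytest

import ess
from ess.scoring import EScoreTable


def _table(scores, X=4, n=2):
    return EScoreTable(scores=dict(scores), X=X, level_n=n, target_kind="reactions")


def test_self_comparison_all_unchanged():
    t = _table({"a": 0.5, "b": 0.0, "c": 1.0})
    rep = ess.compare_escores(t, t)
    assert rep.summary["n_unchanged"] == 3
    assert rep.summary["n_up"] == rep.summary["n_down"] == 0


def test_single_raised_score_counts_one_up():
    a = _table({"a": 0.5, "b": 0.2})
    b = _table({"a": 0.5, "b": 0.3})
    rep = ess.compare_escores(a, b)
    assert rep.summary["n_up"] == 1 and rep.summary["n_down"] == 0
    assert rep.table.loc["b", "status"] == "up"
    assert rep.table.loc["b", "delta"] == pytest.approx(0.1)


def test_comparison_antisymmetric():
    a = _table({"a": 0.5, "b": 0.2, "c": 0.9})
    b = _table({"a": 0.4, "b": 0.6, "c": 0.9})
    fwd = ess.compare_escores(a, b)
    rev = ess.compare_escores(b, a)
    assert fwd.summary["n_up"] == rev.summary["n_down"]
    assert fwd.summary["n_down"] == rev.summary["n_up"]
    for tid in a.scores:
        assert fwd.table.loc[tid, "delta"] == pytest.approx(
            -rev.table.loc[tid, "delta"]
        )


def test_carryover_fills_missing_target():
    a = _table({"a": 0.5, "gone": 0.3})
    b = _table({"a": 0.5})
    rep = ess.compare_escores(a, b, carryover_ids=["gone"])
    assert rep.table.loc["gone", "status"] == "unchanged"
    assert rep.table.loc["gone", "score_b"] == pytest.approx(0.3)


def test_carryover_must_exist_in_table_a():
    with pytest.raises(ValueError, match="BOGUS"):
        ess.compare_escores(_table({"a": 1.0}), _table({"a": 1.0}), ["BOGUS"])


def test_targets_present_in_only_one_table_flagged():
    rep = ess.compare_escores(_table({"a": 1.0, "x": 0.1}), _table({"a": 1.0, "y": 0.2}))
    assert rep.table.loc["x", "status"] == "only_a"
    assert rep.table.loc["y", "status"] == "only_b"
    counts = rep.summary
    assert (
        counts["n_up"] + counts["n_down"] + counts["n_unchanged"]
        + counts["n_only_a"] + counts["n_only_b"]
        == len(rep.table)
    )


def test_spearman_monotone_and_reversed():
    x = [1.0, 2.0, 5.0, 9.0, 12.0]
    rho, _ = ess.spearman_rank(x, [v**3 + 1 for v in x])
    assert rho == pytest.approx(1.0)
    rho, _ = ess.spearman_rank(x, [-v for v in x])
    assert rho == pytest.approx(-1.0)


def test_spearman_hand_computed_example():
    # ranks differ by d^2 = (0,1,1,1,1): rho = 1 - 6*4/(5*24) = 0.8
    rho, p = ess.spearman_rank([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert rho == pytest.approx(0.8)
    assert 0 < p <= 1


def test_spearman_invariant_under_monotone_transform():
    x = [0.5, 3.0, 1.0, 9.0, 4.0, 2.5]
    y = [1.0, 0.2, 5.0, 4.0, 2.0, 3.3]
    rho1, _ = ess.spearman_rank(x, y)
    rho2, _ = ess.spearman_rank(np.exp(x), [v**3 for v in y])
    assert rho1 == pytest.approx(rho2)


def test_spearman_rejects_constant_vector():
    with pytest.raises(ValueError, match="constant"):
        ess.spearman_rank([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _cent(rows):
    return pd.DataFrame(
        [{"node": k, "betweenness": v} for k, v in rows.items()]
    ).set_index("node")


def test_overlap_counts_partition():
    scores = _table({"a": 0.5, "b": 0.0, "c": 0.2, "d": 0.0})
    cent = _cent({"a": 1.0, "b": 0.0, "c": 0.0, "d": 2.0})
    res = ess.score_overlap_counts(scores, cent)
    assert res["n_both_nonzero"] == 1 and res["members"]["both_nonzero"] == ["a"]
    assert res["n_escore_only"] == 1 and res["members"]["escore_only"] == ["c"]
    assert res["n_centrality_only"] == 1
    assert res["n_both_zero"] == 1 and res["members"]["both_zero"] == ["b"]
    assert res["n_shared"] == 4


def test_overlap_all_zero_tables():
    res = ess.score_overlap_counts(
        _table({"a": 0.0, "b": 0.0}), _cent({"a": 0.0, "b": 0.0})
    )
    assert res["n_both_zero"] == 2 and res["n_shared"] == 2


def test_overlap_single_target():
    res = ess.score_overlap_counts(_table({"a": 0.5}), _cent({"a": 0.0}))
    assert res["n_escore_only"] == 1


def test_overlap_requires_shared_namespace():
    with pytest.raises(ValueError, match="shared"):
        ess.score_overlap_counts(_table({"a": 1.0}), _cent({"z": 1.0}))


def test_subsystem_mean_scores():
    table = _table({"a": 1.0, "b": 0.5, "c": 0.0})
    grouped = ess.subsystem_mean_scores(table, {"a": "glycolysis", "b": "glycolysis", "c": "tca"})
    assert grouped.loc["glycolysis", "mean_escore"] == pytest.approx(0.75)
    assert grouped.loc["tca", "n_targets"] == 1
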