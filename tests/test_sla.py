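"""Minimal lethal set enumeration: pruned path, exhaustive oracle, formats."""

import random

import pytest

import ess
from ess.sla import BudgetExceededError, LethalSetCollection


def _sets(collection):
    return {j: {tuple(sorted(s)) for s in v} for j, v in collection.sets_by_level.items() if v}


def test_fig1a_level2_structure(fig1a):
    cfg = ess.AnalysisConfig(level_n=2)
    col = ess.enumerate_minimal_lethal_sets(fig1a, cfg)
    assert _sets(col) == {1: {("A",)}, 2: {("C", "D")}}
    assert col.candidate_ids == ["A", "B", "C", "D"]


def test_level1_equals_find_essential(fig1b):
    cfg = ess.AnalysisConfig(level_n=1)
    col = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    assert sorted(x for (x,) in _sets(col).get(1, set())) == \
        ess.find_essential(fig1b, cfg)
    assert set(col.sets_by_level) == {1}


def test_three_redundant_bundles_give_three_pairs():
    # three 2-way redundant branch bundles in series: of the 21 candidate
    # pairs over 7 targets exactly the three within-bundle ones are lethal
    spec = ess.LethalStructureSpec(
        n_targets=7,
        essential_ids=["T"],
        sl_groups=[{"P1a", "P1b"}, {"P2a", "P2b"}, {"P3a", "P3b"}],
    )
    model = ess.synth_model(spec, seed=11, verify=False)
    cfg = ess.synth_config(2)
    brute = ess.brute_force_lethal_sets(model, cfg)
    pruned = ess.enumerate_minimal_lethal_sets(model, cfg)
    expected = {
        1: {("T",)},
        2: {("P1a", "P1b"), ("P2a", "P2b"), ("P3a", "P3b")},
    }
    assert _sets(brute) == expected
    assert pruned == brute


def test_excluded_ids_and_objective_never_appear(ecoli):
    cfg = ess.AnalysisConfig(level_n=1, excluded_ids=frozenset({"ATPM"}))
    col = ess.enumerate_minimal_lethal_sets(ecoli, cfg)
    assert "ATPM" not in col.candidate_ids
    assert ecoli.objective_id not in col.candidate_ids
    assert col.X == 93
    for s in col.all_sets():
        assert "ATPM" not in s and ecoli.objective_id not in s


def test_enumeration_deterministic(fig1b):
    cfg = ess.AnalysisConfig(level_n=3)
    a = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    b = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    assert a == b


def test_minimality_by_direct_fba(fig1b):
    cfg = ess.AnalysisConfig(level_n=3)
    col = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    for s in col.all_sets():
        assert ess.is_lethal(fig1b, s, "reactions")
        for r in s:
            assert not ess.is_lethal(fig1b, s - {r}, "reactions")


@pytest.mark.parametrize("targets", ["reactions", "genes"])
def test_pruned_equals_oracle_on_random_models(targets):
    rng = random.Random(7 if targets == "reactions" else 8)
    for _ in range(6):
        spec = _random_spec(rng)
        model = ess.synth_model(
            spec, seed=rng.randrange(2**31), with_genes=(targets == "genes")
        )
        cfg = ess.synth_config(3, level_n=3, targets=targets)
        assert ess.enumerate_minimal_lethal_sets(model, cfg) == \
            ess.brute_force_lethal_sets(model, cfg)


def _random_spec(rng):
    ids = [f"R{i:02d}" for i in range(12)]
    rng.shuffle(ids)
    it = iter(ids)
    essentials = [next(it) for _ in range(rng.randint(0, 2))]
    groups = [
        {next(it) for _ in range(rng.randint(2, 3))}
        for _ in range(rng.randint(0, 2))
    ]
    return ess.LethalStructureSpec(
        n_targets=rng.randint(8, 12), essential_ids=essentials, sl_groups=groups
    )


def test_serialization_round_trips(fig1b, tmp_path):
    cfg = ess.AnalysisConfig(level_n=2)
    col = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    col.to_json(tmp_path / "sets.json")
    assert LethalSetCollection.from_json(tmp_path / "sets.json") == col
    col.to_tsv(tmp_path / "sets.tsv")
    text = (tmp_path / "sets.tsv").read_text().splitlines()
    assert text[0] == "level\tmembers"
    assert "1\tA" in text and "2\tB,D" in text


def test_collection_rejects_superset_storage():
    with pytest.raises(ValueError, match="minimality"):
        LethalSetCollection(
            level_n=2,
            target_kind="reactions",
            candidate_ids=["a", "b"],
            sets_by_level={1: [frozenset({"a"})], 2: [frozenset({"a", "b"})]},
        )


def test_brute_force_budget_refusal(fig1b):
    cfg = ess.AnalysisConfig(level_n=3, brute_force_budget=3)
    with pytest.raises(BudgetExceededError, match="14 combinations"):
        ess.brute_force_lethal_sets(fig1b, cfg)


def test_checkpoint_resume_matches_fresh_run(fig1b, tmp_path):
    cfg = ess.AnalysisConfig(level_n=3)
    fresh = ess.enumerate_minimal_lethal_sets(fig1b, cfg)
    first = ess.enumerate_minimal_lethal_sets(fig1b, cfg, checkpoint_dir=tmp_path)
    assert (tmp_path / "sla_checkpoint.json").exists()
    resumed = ess.enumerate_minimal_lethal_sets(fig1b, cfg, checkpoint_dir=tmp_path)
    assert first == fresh == resumed


def test_level_warning_above_three(fig1a):
    with pytest.warns(UserWarning, match="level"):
        ess.enumerate_minimal_lethal_sets(fig1a, ess.AnalysisConfig(level_n=4))
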