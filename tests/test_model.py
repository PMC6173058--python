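"""Model construction, I/O round trips and knockout semantics."""

import itertools

import pytest

import ess
from ess.io import load_json_model, model_from_dict, save_json_model
from ess.model import ModelValidationError


def _gpr_truth_tables(model):
    tables = {}
    for r in model.reactions:
        tables[r.id] = r.gpr.to_dnf() if r.gpr is not None else None
    return tables


def test_json_round_trip_preserves_structure(fig1a, tmp_path):
    path = tmp_path / "fig1a.json"
    save_json_model(fig1a, path)
    again = load_json_model(path)
    assert again.reaction_ids == fig1a.reaction_ids
    assert again.objective_id == fig1a.objective_id
    for rid in fig1a.reaction_ids:
        a, b = fig1a.reaction(rid), again.reaction(rid)
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert a.stoichiometry == b.stoichiometry
    assert _gpr_truth_tables(again) == _gpr_truth_tables(fig1a)


def test_sbml_round_trip_preserves_structure(fig1a, tmp_path):
    path = tmp_path / "fig1a.xml"
    ess.save_sbml_model(fig1a, path)
    again = ess.load_model(path)  # format inferred from suffix
    assert sorted(again.reaction_ids) == sorted(fig1a.reaction_ids)
    assert again.objective_id == fig1a.objective_id
    for rid in fig1a.reaction_ids:
        a, b = fig1a.reaction(rid), again.reaction(rid)
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert a.stoichiometry == b.stoichiometry
    assert _gpr_truth_tables(again) == _gpr_truth_tables(fig1a)


def test_minimal_single_reaction_document():
    doc = {
        "id": "tiny",
        "metabolites": [{"id": "m", "compartment": "c"}],
        "reactions": [
            {
                "id": "R",
                "metabolites": {"m": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 5.0,
                "objective_coefficient": 1.0,
            }
        ],
    }
    model = model_from_dict(doc)
    assert len(model.reactions) == 1 and len(model.metabolites) == 1
    assert model.objective_id == "R"


def test_missing_objective_is_configuration_error():
    doc = {
        "metabolites": [{"id": "m"}],
        "reactions": [{"id": "R", "metabolites": {"m": 1.0}}],
    }
    with pytest.raises(ModelValidationError, match="objective"):
        model_from_dict(doc)
    assert model_from_dict(doc, objective_id="R").objective_id == "R"


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError):
        ess.load_model("does_not_exist.xml")


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda d: d["reactions"].append(dict(d["reactions"][1])), "duplicate"),
        (
            lambda d: d["reactions"][1]["metabolites"].update({"ghost": 1.0}),
            "undeclared",
        ),
        (
            lambda d: d["reactions"][1].update(lower_bound=5.0, upper_bound=1.0),
            "bound",
        ),
    ],
)
def test_validation_errors_name_offender(fig1a, mutate, message):
    from ess.io import model_to_dict

    doc = model_to_dict(fig1a)
    mutate(doc)
    with pytest.raises(ModelValidationError, match=message):
        model_from_dict(doc)


def test_reaction_knockout_zeroes_bounds(fig1a):
    ko = ess.apply_knockout(fig1a, {"C"}, "reactions")
    assert (ko.reaction("C").lower_bound, ko.reaction("C").upper_bound) == (0, 0)
    # original untouched
    assert fig1a.reaction("C").upper_bound > 0


def test_empty_knockout_is_identity(fig1a):
    ko = ess.apply_knockout(fig1a, set(), "reactions")
    for rid in fig1a.reaction_ids:
        a, b = fig1a.reaction(rid), ko.reaction(rid)
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)


def test_gene_knockout_disables_reaction_via_gpr():
    model = ess.fig1a_model()
    model.reaction("C").gpr = ess.parse_gpr("g1 or g2")
    model.validate()
    ko = ess.apply_knockout(model, {"g1"}, "genes")
    assert ko.reaction("C").upper_bound > 0  # isozyme keeps it alive
    ko2 = ess.apply_knockout(model, {"g1", "g2"}, "genes")
    assert (ko2.reaction("C").lower_bound, ko2.reaction("C").upper_bound) == (0, 0)


def test_knockout_idempotent_and_commutative(fig1a):
    ids = ["B", "C"]
    for order in itertools.permutations(ids):
        step = fig1a
        for rid in order:
            step = ess.apply_knockout(step, {rid}, "reactions")
        joint = ess.apply_knockout(fig1a, set(ids), "reactions")
        twice = ess.apply_knockout(joint, set(ids), "reactions")
        for m in (step, twice):
            for rid in fig1a.reaction_ids:
                a, b = joint.reaction(rid), m.reaction(rid)
                assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)


def test_unknown_knockout_id_named_in_error(fig1a):
    with pytest.raises(KeyError, match="NOPE"):
        ess.apply_knockout(fig1a, {"NOPE"}, "reactions")
    with pytest.raises(KeyError, match="gNOPE"):
        ess.apply_knockout(fig1a, {"gNOPE"}, "genes")


def test_logical_transform_keeps_deletion_outcomes(fig1b):
    model = fig1b.copy()
    model.reaction("B").gpr = ess.parse_gpr("(gx and gy) or gx")
    model.reaction("C").gpr = ess.parse_gpr("gx and (gy or gz)")
    model.validate()
    out = ess.logical_transform(model)
    genes = sorted(set(model.genes))
    for mask in range(2 ** len(genes)):
        deleted = {g for k, g in enumerate(genes) if mask >> k & 1}
        for rid in model.reaction_ids:
            assert ess.evaluate_gpr(model.reaction(rid).gpr, deleted) == \
                ess.evaluate_gpr(out.reaction(rid).gpr, deleted)


def test_excluded_never_contains_objective_implicitly(fig1a):
    cfg = ess.AnalysisConfig(level_n=2)
    assert "OBJ" not in cfg.candidate_ids(fig1a)
    assert cfg.candidate_ids(fig1a) == ["A", "B", "C", "D"]
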