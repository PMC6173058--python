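"""Model input/output.

SBML Level 3 (+fbc) files are read and written through cobrapy, the standard
Python constraint-based-modeling library; the BiGG-style JSON dialect is
handled natively so that fixtures round-trip without external machinery.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional

from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction

__all__ = [
    "load_model",
    "load_json_model",
    "save_json_model",
    "load_sbml_model",
    "save_sbml_model",
    "load_ecoli_core",
    "model_summary_tsv",
]


def load_model(
    path: str | Path,
    format: Optional[str] = None,
    objective_id: Optional[str] = None,
) -> MetabolicModel:
    """Load a model from SBML (``.xml``/``.xml.gz``) or BiGG-style JSON.

    ``format`` may be "sbml" or "json"; when omitted it is inferred from the
    file suffix. ``objective_id`` overrides (or supplies, for files that do
    not declare one) the objective reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    if format is None:
        name = path.name.lower()
        if name.endswith((".json",)):
            format = "json"
        elif name.endswith((".xml", ".sbml", ".xml.gz", ".sbml.gz")):
            format = "sbml"
        else:
            raise ValueError(
                f"cannot infer model format from suffix of {path.name!r}; "
                "pass format='sbml' or 'json'"
            )
    if format == "json":
        return load_json_model(path, objective_id=objective_id)
    if format == "sbml":
        return load_sbml_model(path, objective_id=objective_id)
    raise ValueError(f"unknown model format: {format!r}")


# ---------------------------------------------------------------------------
# BiGG-style JSON dialect
# ---------------------------------------------------------------------------

def load_json_model(
    path: str | Path, objective_id: Optional[str] = None
) -> MetabolicModel:
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"malformed JSON model {path}: {exc}") from exc
    return model_from_dict(doc, objective_id=objective_id)


def model_from_dict(
    doc: dict, objective_id: Optional[str] = None
) -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelValidationError(f"model document lacks {key!r}")
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
        )
        for m in doc["metabolites"]
    ]
    reactions = []
    declared_objective = None
    for r in doc["reactions"]:
        coeff = float(r.get("objective_coefficient", 0.0))
        if coeff:
            declared_objective = r["id"]
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry={m: float(c) for m, c in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                name=r.get("name", ""),
                subsystem=r.get("subsystem", ""),
            )
        )
    objective = objective_id or declared_objective
    if objective is None:
        raise ModelValidationError(
            "model declares no objective reaction and none was supplied"
        )
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])]
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective,
        genes=genes,
    )


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {m: c for m, c in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": str(r.gpr) if r.gpr is not None else "",
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
    }


def save_json_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model."""
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(cm)
    objective = None
    if coeffs:
        # use the (unique, for FBA models) reaction with a linear coefficient
        objective = max(coeffs, key=lambda r: abs(coeffs[r])).id
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=parse_gpr(r.gene_reaction_rule),
            name=r.name or "",
            subsystem=r.subsystem or "",
        )
        for r in cm.reactions
    ]
    if objective is None:
        raise ModelValidationError(
            "model declares no objective reaction and none was supplied"
        )
    return MetabolicModel(
        id=cm.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective,
        genes=sorted(g.id for g in cm.genes),
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML export)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = str(r.gpr)
        if r.subsystem:
            cr.subsystem = r.subsystem
    cm.objective = model.objective_id
    return cm


def load_sbml_model(
    path: str | Path, objective_id: Optional[str] = None
) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cm = read_sbml_model(str(path))
    model = (
        from_cobra(cm)
        if objective_id is None
        else _from_cobra_with_objective(cm, objective_id)
    )
    return model


def _from_cobra_with_objective(cm, objective_id: str) -> MetabolicModel:
    cm.objective = objective_id
    return from_cobra(cm)


def save_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def load_ecoli_core() -> MetabolicModel:
    """The Orth et al. E. coli core model (95 reactions, BiGG identifiers).

    Loaded from the copy cobrapy ships as package data, so no network access
    is needed.
    """
    import cobra

    path = Path(cobra.__file__).parent / "data" / "textbook.xml.gz"
    return load_sbml_model(path)


def model_summary_tsv(model: MetabolicModel, path: str | Path) -> None:
    """Write a per-reaction summary (id, lb, ub, gpr string)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tlower_bound\tupper_bound\tgpr\n")
        for r in model.reactions:
            gpr = str(r.gpr) if r.gpr is not None else ""
            fh.write(f"{r.id}\t{r.lower_bound:g}\t{r.upper_bound:g}\t{gpr}\n")
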