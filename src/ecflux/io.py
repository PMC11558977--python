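"""Readers and writers for constraint-based models.

COBRA-style JSON (the widely used ``metabolites``/``reactions``/``genes``
schema) is handled natively so that round-trips are exact field-for-field,
including annotation keys this package adds (``kcat_s``, ``mw_kda``, ...) and
any unknown keys, which are preserved opaquely.  SBML Level 3 FBC import and
export (bounds and GPR only) is delegated to COBRApy/libsbml.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from .model_core import (
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
)

__all__ = ["read_model", "write_model", "to_cobra", "from_cobra", "ModelFormatError"]

_KNOWN_MET_KEYS = {"id", "name", "compartment", "formula", "carbon_count", "annotation"}
_KNOWN_RXN_KEYS = {
    "id",
    "name",
    "metabolites",
    "lower_bound",
    "upper_bound",
    "gene_reaction_rule",
    "subsystem",
    "objective_coefficient",
    "annotation",
}
_KNOWN_GENE_KEYS = {"id", "protein", "mw_kda", "annotation"}


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or fails validation."""


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    return "sbml" if suffix in (".xml", ".sbml") else "cobra-json"


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from COBRA-style JSON or SBML (L3 FBC).

    The format is inferred from the file suffix (``.xml``/``.sbml`` -> SBML)
    unless given explicitly.  The returned model is validated; dangling
    references raise :class:`ModelFormatError`.
    """
    fmt = _infer_format(path, format)
    if fmt == "cobra-json":
        model = _read_json(path)
    elif fmt == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    findings = validate_model(model)
    fatal = [f for f in findings if f.startswith(("dangling", "duplicate", "gpr-parse"))]
    if fatal:
        raise ModelFormatError(f"{path}: " + "; ".join(fatal))
    return model


def write_model(model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a model to COBRA-style JSON or SBML; re-reading gives an equal model."""
    fmt = _infer_format(path, format)
    if fmt == "cobra-json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# native COBRA JSON
# ---------------------------------------------------------------------------

def _read_json(path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level {key!r} array")
    model = MetabolicModel(id=doc.get("id", "model"))
    for entry in doc["metabolites"]:
        if "id" not in entry:
            raise ModelFormatError(f"{path}: metabolite entry without id: {entry}")
        met = Metabolite(
            id=entry["id"],
            name=entry.get("name", ""),
            compartment=entry.get("compartment", ""),
            formula=entry.get("formula"),
            carbon_count=entry.get("carbon_count"),
            annotation=dict(entry.get("annotation", {})),
        )
        extra = {k: v for k, v in entry.items() if k not in _KNOWN_MET_KEYS}
        if extra:
            met.annotation["_extra"] = extra
        model.metabolites.append(met)
    objective_id = ""
    for entry in doc["reactions"]:
        if "id" not in entry:
            raise ModelFormatError(f"{path}: reaction entry without id: {entry}")
        rxn = Reaction(
            id=entry["id"],
            name=entry.get("name", ""),
            stoichiometry={m: float(c) for m, c in entry.get("metabolites", {}).items()},
            lower_bound=float(entry.get("lower_bound", 0.0)),
            upper_bound=float(entry.get("upper_bound", 1000.0)),
            gpr=entry.get("gene_reaction_rule", ""),
            subsystem=entry.get("subsystem"),
            annotation=dict(entry.get("annotation", {})),
        )
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            objective_id = rxn.id
        extra = {k: v for k, v in entry.items() if k not in _KNOWN_RXN_KEYS}
        if extra:
            rxn.annotation["_extra"] = extra
        model.reactions.append(rxn)
    for entry in doc.get("genes", []):
        gene = Gene(id=entry["id"], protein=entry.get("protein"), mw_kda=entry.get("mw_kda"))
        model.genes.append(gene)
    model.objective_reaction_id = doc.get("objective_reaction_id", objective_id)
    model.annotation = {
        k: v
        for k, v in doc.items()
        if k not in ("id", "metabolites", "reactions", "genes", "objective_reaction_id", "version")
    }
    return model


def _met_to_json(met: Metabolite) -> dict:
    entry = {"id": met.id, "name": met.name, "compartment": met.compartment}
    if met.formula is not None:
        entry["formula"] = met.formula
    if met.carbon_count is not None:
        entry["carbon_count"] = met.carbon_count
    ann = dict(met.annotation)
    extra = ann.pop("_extra", {})
    if ann:
        entry["annotation"] = ann
    entry.update(extra)
    return entry


def _rxn_to_json(rxn: Reaction, objective_id: str) -> dict:
    entry = {
        "id": rxn.id,
        "name": rxn.name,
        "metabolites": {m: rxn.stoichiometry[m] for m in sorted(rxn.stoichiometry)},
        "lower_bound": rxn.lower_bound,
        "upper_bound": rxn.upper_bound,
        "gene_reaction_rule": rxn.gpr,
    }
    if rxn.subsystem is not None:
        entry["subsystem"] = rxn.subsystem
    if rxn.id == objective_id:
        entry["objective_coefficient"] = 1.0
    ann = dict(rxn.annotation)
    extra = ann.pop("_extra", {})
    if ann:
        entry["annotation"] = ann
    entry.update(extra)
    return entry


def _write_json(model: MetabolicModel, path) -> None:
    doc = dict(model.annotation)
    doc["id"] = model.id
    doc["metabolites"] = [_met_to_json(m) for m in model.metabolites]
    doc["reactions"] = [_rxn_to_json(r, model.objective_reaction_id) for r in model.reactions]
    doc["genes"] = [
        {"id": g.id, **({"protein": g.protein} if g.protein else {}), **(
            {"mw_kda": g.mw_kda} if g.mw_kda is not None else {})}
        for g in model.genes
    ]
    doc["objective_reaction_id"] = model.objective_reaction_id
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML via COBRApy, and model conversion to/from cobra objects
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for SBML and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        m = cobra.Metabolite(met.id, name=met.name, compartment=met.compartment or "c")
        if met.formula:
            m.formula = met.formula
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions:
        r = cobra.Reaction(rxn.id, name=rxn.name)
        r.lower_bound = rxn.lower_bound
        r.upper_bound = rxn.upper_bound
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions:
        r = cm.reactions.get_by_id(rxn.id)
        r.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            r.gene_reaction_rule = rxn.gpr
        if rxn.subsystem:
            r.subsystem = rxn.subsystem
    if model.objective_reaction_id:
        cm.objective = model.objective_reaction_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` into the native container."""
    model = MetabolicModel(id=cm.id or "model")
    for m in cm.metabolites:
        model.metabolites.append(
            Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "",
                       formula=m.formula or None)
        )
    objective_ids = [r.id for r in cm.reactions if r.objective_coefficient]
    for r in cm.reactions:
        model.reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                subsystem=r.subsystem or None,
            )
        )
    for g in cm.genes:
        model.genes.append(Gene(id=g.id))
    if objective_ids:
        model.objective_reaction_id = objective_ids[0]
    return model


def _read_sbml(path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a grab-bag of error types
        raise ModelFormatError(f"{path}: SBML parse failed ({exc})") from exc
    model = from_cobra(cm)
    # SBML stores no gene MW annotation; gene list still carries ids
    return model


def _write_sbml(model: MetabolicModel, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))
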