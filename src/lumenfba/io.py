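"""Readers and writers for the two standard model formats.

SBML Level 3 + FBC v2 is handled through ``python-libsbml``; the COBRA-JSON
dialect through the standard library (the schema is a flat JSON document).
``.gz`` paths are compressed and decompressed transparently.  Reading a file
written by :func:`write_model` reproduces the model structurally (ids,
stoichiometry, bounds, subsystems, compartments, objective).

Bounds absent from a file default to +/-1000.  Gene-protein-reaction rules
are accepted in input files but ignored.
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ValidationFinding,
    detect_exchange,
    require_valid,
)

__all__ = ["read_model", "write_model", "FormatError"]


class FormatError(ValueError):
    """A file could not be parsed in the requested dialect."""


# ---------------------------------------------------------------------------
# helpers


def _read_bytes(path: str | Path) -> bytes:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":  # gzip magic
        raw = gzip.decompress(raw)
    return raw


def _write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        data = gzip.compress(data)
    path.write_bytes(data)


def _strip_gz(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".gz" else path


def _detect_format(path: str | Path) -> str:
    path = Path(path)
    suffix = _strip_gz(path).suffix.lower()
    if suffix == ".json":
        return "cobra-json"
    if suffix in (".xml", ".sbml"):
        return "sbml-fbc"
    # content sniffing
    head = _read_bytes(path).lstrip()[:1]
    if head == b"{":
        return "cobra-json"
    if head == b"<":
        return "sbml-fbc"
    raise FormatError(f"cannot determine model format of {path}")


def read_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Read a model from SBML-FBC or COBRA-JSON (``format='auto'`` inspects
    the extension, then the content).  The returned model satisfies all
    structural invariants or a validation error is raised."""
    if format == "auto":
        format = _detect_format(path)
    if format == "cobra-json":
        model = _read_json(path)
    elif format == "sbml-fbc":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    require_valid(model)
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str = "auto") -> None:
    """Write a model; ``read_model(write_model(m))`` is the structural
    identity.  The model must pass validation first."""
    require_valid(model)
    if format == "auto":
        suffix = _strip_gz(Path(path)).suffix.lower()
        format = "cobra-json" if suffix == ".json" else "sbml-fbc"
    if format == "cobra-json":
        _write_json(model, path)
    elif format == "sbml-fbc":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# COBRA-JSON


def _read_json(path: str | Path) -> MetabolicModel:
    try:
        doc = json.loads(_read_bytes(path).decode())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    model = MetabolicModel(id=doc.get("id", Path(path).stem))
    for cid, cname in doc.get("compartments", {}).items():
        model.compartments[cid] = cname or cid
    for m in doc.get("metabolites", []):
        met = Metabolite(
            id=m["id"],
            compartment=m.get("compartment", ""),
            name=m.get("name", ""),
            formula=m.get("formula") or None,
            charge=m.get("charge"),
        )
        if met.compartment and met.compartment not in model.compartments:
            model.compartments[met.compartment] = met.compartment
        if met.id in model.metabolites:
            raise ModelValidationError([_dup_finding("metabolite", met.id)])
        model.metabolites[met.id] = met
    for r in doc.get("reactions", []):
        rxn = Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
            lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
            upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
            name=r.get("name", ""),
            subsystem=r.get("subsystem") or "",
        )
        rxn.is_exchange = detect_exchange(rxn)
        if rxn.id in model.reactions:
            raise ModelValidationError([_dup_finding("reaction", rxn.id)])
        model.reactions[rxn.id] = rxn
        coef = float(r.get("objective_coefficient", 0.0) or 0.0)
        if coef:
            model.objective[rxn.id] = coef
    model.annotations = dict(doc.get("annotations", {}))
    return model


def _write_json(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_reaction_rule": "",
                "objective_coefficient": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions.values()
        ],
        "genes": [],
        "annotations": dict(model.annotations),
    }
    _write_bytes(path, json.dumps(doc, indent=1, sort_keys=False).encode())


def _dup_finding(kind: str, offender: str):
    from .model import ValidationFinding

    return ValidationFinding(
        "error", f"duplicate-{kind}", offender, f"duplicate {kind} id {offender!r}"
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2

_SBML_NS = libsbml.SBMLNamespaces(3, 1, "fbc", 2)


def _read_sbml(path: str | Path) -> MetabolicModel:
    data = _read_bytes(path).decode()
    doc = libsbml.readSBMLFromString(data)
    if doc.getNumErrors() > 0:
        errors = []
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                errors.append(f"line {err.getLine()}: {err.getMessage().strip()}")
        if errors:
            raise FormatError(f"{path}: " + "; ".join(errors))
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: no <model> element")

    model = MetabolicModel(id=sm.getId() or Path(path).stem)
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = _unprefix(sp.getId(), "M_")
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = fbc_sp.getChemicalFormula()
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        met = Metabolite(
            id=mid,
            compartment=sp.getCompartment(),
            name=sp.getName() or "",
            formula=formula,
            charge=charge,
        )
        if met.id in model.metabolites:
            raise ModelValidationError([_dup_finding("metabolite", met.id)])
        model.metabolites[met.id] = met

    # flux-bound parameters
    params: dict[str, float] = {}
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        params[p.getId()] = p.getValue()

    undeclared: list[str] = []
    for i in range(sm.getNumReactions()):
        srxn = sm.getReaction(i)
        rid = _unprefix(srxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            mid = _unprefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            mid = _unprefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        for mid in stoich:
            if mid not in model.metabolites:
                undeclared.append(f"{rid} -> {mid}")
        fbc_r = srxn.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if fbc_r is not None:
            if fbc_r.isSetLowerFluxBound():
                lb = params.get(fbc_r.getLowerFluxBound(), lb)
            if fbc_r.isSetUpperFluxBound():
                ub = params.get(fbc_r.getUpperFluxBound(), ub)
        subsystem = ""
        notes = srxn.getNotesString() if srxn.isSetNotes() else ""
        if "SUBSYSTEM:" in notes:
            subsystem = notes.split("SUBSYSTEM:", 1)[1].split("<", 1)[0].strip()
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            name=srxn.getName() or "",
            subsystem=subsystem,
        )
        rxn.is_exchange = detect_exchange(rxn)
        if rxn.id in model.reactions:
            raise ModelValidationError([_dup_finding("reaction", rxn.id)])
        model.reactions[rid] = rxn

    if undeclared:
        raise ModelValidationError(
            [
                ValidationFinding(
                    "error",
                    "unknown-metabolite",
                    ref,
                    "reaction references undeclared species",
                )
                for ref in undeclared
            ]
        )

    fbc_m = sm.getPlugin("fbc")
    if fbc_m is not None and fbc_m.getNumObjectives() > 0:
        obj = fbc_m.getActiveObjective() or fbc_m.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            model.objective[_unprefix(fo.getReaction(), "R_")] = fo.getCoefficient()
    return model


def _unprefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _sid(raw: str, prefix: str) -> str:
    """Make an SBML SId: conventional type prefix + sanitized id."""
    safe = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    return prefix + safe


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    doc = libsbml.SBMLDocument(_SBML_NS)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    fbc_m = sm.getPlugin("fbc")
    fbc_m.setStrict(True)

    for cid, cname in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid(met.id, "M_"))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula:
            fbc_sp.setChemicalFormula(met.formula)
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        srxn = sm.createReaction()
        srxn.setId(_sid(rxn.id, "R_"))
        srxn.setName(rxn.name or rxn.id)
        srxn.setReversible(rxn.lower_bound < 0)
        srxn.setFast(False)
        if rxn.subsystem:
            srxn.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for mid, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = srxn.createReactant()
            else:
                ref = srxn.createProduct()
            ref.setSpecies(_sid(mid, "M_"))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        fbc_r = srxn.getPlugin("fbc")
        fbc_r.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_r.setUpperFluxBound(bound_param(rxn.upper_bound))

    if model.objective:
        obj = fbc_m.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fbc_m.setActiveObjectiveId("obj")
        for rid, coeff in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(_sid(rid, "R_"))
            fo.setCoefficient(float(coeff))

    data = libsbml.writeSBMLToString(doc)
    if data is None or not math.isfinite(len(data)):  # pragma: no cover
        raise IOError(f"failed to serialize SBML for {model.id}")
    _write_bytes(path, data.encode())
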