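"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` carries everything a flux balance analysis (FBA)
problem needs: the stoichiometric matrix ``S`` (assembled on demand from
per-reaction stoichiometries), flux bounds ``lb``/``ub`` and the linear
objective ``c``.  The flux sign convention is fixed package-wide: for an
exchange (boundary) reaction, negative flux is uptake into the system and
positive flux is secretion out of it.  Bounds default to +/-1000, the COBRA
convention, and flux units are carried as an opaque annotation (the models
this package targets use mmol per gram dry weight per hour).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

DEFAULT_BOUND = 1000.0

#: reaction-id prefix conventionally marking exchange reactions (VMH/BiGG)
EXCHANGE_PREFIX = "EX_"


@dataclass
class Metabolite:
    """A metabolite node of the network, living in one compartment."""

    id: str
    compartment: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients; negative
    coefficients are consumed, positive produced.  ``is_exchange`` marks
    boundary reactions (single metabolite, or id starting with ``EX_``).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""
    is_exchange: bool = False

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        self.lower_bound, self.upper_bound = value

    def reversed_copy(self) -> "Reaction":
        r = copy.deepcopy(self)
        r.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
        r.lower_bound, r.upper_bound = -self.upper_bound, -self.lower_bound
        return r


def detect_exchange(reaction: Reaction, prefix: str = EXCHANGE_PREFIX) -> bool:
    """Exchange detection: single-metabolite reactions or the id prefix.

    The prefix convention wins on conflict (a multi-metabolite reaction named
    ``EX_...`` is still treated as an exchange, as VMH files rely on the
    naming).
    """
    if prefix and reaction.id.startswith(prefix):
        return True
    return len(reaction.stoichiometry) == 1


@dataclass
class ValidationFinding:
    severity: str  # "error" | "warning"
    code: str
    offender: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code} ({self.offender}): {self.message}"


class ModelValidationError(ValueError):
    """Raised when an operation requires a valid model and gets findings."""

    def __init__(self, findings: list[ValidationFinding]):
        self.findings = findings
        super().__init__("; ".join(str(f) for f in findings))


@dataclass
class MetabolicModel:
    """A genome-scale (or toy-scale) metabolic network model."""

    id: str
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            self.compartments[met.compartment] = met.compartment
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- numerical views --------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Assemble sparse ``S`` with one row per metabolite, one column per
        reaction; column ``j``'s nonzeros equal reaction ``j``'s
        stoichiometry.  Returns ``(S, metabolite_ids, reaction_ids)``."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                data.append(coeff)
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, rid in enumerate(self.reactions):
            if rid in self.objective:
                c[j] = self.objective[rid]
        return c

    # -- conveniences ------------------------------------------------------
    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def reactions_of_subsystem(self, subsystem: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.subsystem == subsystem]


_BIOMASS_RE = re.compile(r"biomass", re.IGNORECASE)


def find_biomass_reaction(
    model: MetabolicModel, pattern: str | re.Pattern = _BIOMASS_RE
) -> str | None:
    """First reaction whose id or name matches the biomass pattern."""
    pat = re.compile(pattern, re.IGNORECASE) if isinstance(pattern, str) else pattern
    for rxn in model.reactions.values():
        if pat.search(rxn.id) or (rxn.name and pat.search(rxn.name)):
            return rxn.id
    return None


def validate_model(model: MetabolicModel) -> list[ValidationFinding]:
    """Check all structural invariants; returns findings, raises nothing.

    An empty report means the model satisfies every type invariant: unique
    ids, resolvable compartments and metabolites, ordered bounds, non-empty
    stoichiometries, single-metabolite exchanges and resolvable objective.
    """
    findings: list[ValidationFinding] = []

    def err(code: str, offender: str, msg: str) -> None:
        findings.append(ValidationFinding("error", code, offender, msg))

    def warn(code: str, offender: str, msg: str) -> None:
        findings.append(ValidationFinding("warning", code, offender, msg))

    for mid, met in model.metabolites.items():
        if mid != met.id:
            err("met-id-mismatch", mid, f"keyed {mid!r} but id is {met.id!r}")
        if met.compartment not in model.compartments:
            err(
                "unknown-compartment",
                mid,
                f"compartment {met.compartment!r} not declared",
            )

    for rid, rxn in model.reactions.items():
        if rid != rxn.id:
            err("rxn-id-mismatch", rid, f"keyed {rid!r} but id is {rxn.id!r}")
        if rxn.lower_bound > rxn.upper_bound:
            err(
                "bounds-order",
                rid,
                f"lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}",
            )
        if not rxn.stoichiometry:
            err("empty-stoichiometry", rid, "reaction has no metabolites")
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                err(
                    "unknown-metabolite",
                    rid,
                    f"references undeclared metabolite {mid!r}",
                )
        if rxn.is_exchange and len(rxn.stoichiometry) != 1:
            err(
                "exchange-arity",
                rid,
                f"is_exchange with {len(rxn.stoichiometry)} metabolites (expected 1)",
            )

    for rid in model.objective:
        if rid not in model.reactions:
            err("unknown-objective", rid, "objective references missing reaction")
    if model.reactions and not model.objective:
        warn("no-objective", model.id, "model has no objective set")

    return findings


def require_valid(model: MetabolicModel) -> None:
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ModelValidationError(errors)


def models_structurally_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Structural equality on ids, stoichiometry, bounds, subsystems,
    compartment sets and objective (order-insensitive, exact values)."""
    if set(a.compartments) != set(b.compartments):
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if ma.compartment != mb.compartment:
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound) != (rb.lower_bound, rb.upper_bound):
            return False
        if ra.subsystem != rb.subsystem:
            return False
    return a.objective == b.objective


def build_model(
    model_id: str,
    compartments: Mapping[str, str],
    metabolites: Iterable[Metabolite],
    reactions: Iterable[Reaction],
    objective: Mapping[str, float],
    annotations: Mapping[str, str] | None = None,
) -> MetabolicModel:
    """Assemble and tag exchanges; convenience used by the synthetic module."""
    model = MetabolicModel(id=model_id, compartments=dict(compartments))
    for met in metabolites:
        model.add_metabolite(met)
    for rxn in reactions:
        rxn.is_exchange = detect_exchange(rxn)
        model.add_reaction(rxn)
    model.objective = dict(objective)
    model.annotations = dict(annotations or {"units": "mmol/gDW/h"})
    return model
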