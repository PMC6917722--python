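"""Merge a host and a microbe model through a shared lumen compartment.

The co-metabolism construction mirrors how host-gut-microbe models are
built for gut simulations: two complete genome-scale networks are kept
side by side under distinct id namespaces, and every boundary metabolite
both organisms expose extracellularly is re-routed through a new ``lu``
(lumen) compartment.  Food components enter the lumen through diet
exchange reactions; from there each metabolite can be taken up by the
host and/or the microbe, depending on their transport capabilities, or
leave through lumen efflux.

Each organism's former exchange reaction for a shared metabolite is
rewritten as a pair of directed transports (lumen->organism uptake and
organism->lumen secretion) that inherit the original exchange bounds, so
an organism's published uptake limits survive the merge.  The directed
split keeps the four transport sets (host/microbe x uptake/secretion)
disjoint and makes secretion caps and knock-offs one-bound operations.

The Fig.-1-style control condition — microbe secretion restricted to a
limiting value so that the system stays viable but cannot feed the host —
is provided by :func:`cap_microbe_secretion`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .fba import check_feasible
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationFinding,
    find_biomass_reaction,
    require_valid,
    validate_model,
)

__all__ = [
    "JoinPolicy",
    "CoMetabolismModel",
    "merge_into_comodel",
    "cap_microbe_secretion",
    "validate_comodel",
    "InfeasibleSystemError",
]


class InfeasibleSystemError(RuntimeError):
    """A constraint set left the co-model without any feasible flux state."""

    def __init__(self, message: str, binding_reactions: list[str] | None = None):
        super().__init__(message)
        self.binding_reactions = binding_reactions or []


@dataclass
class JoinPolicy:
    """Which boundary metabolites are lumen-shared and how transports are
    bounded.

    ``host_open_uptake`` / ``microbe_open_uptake`` list base metabolite ids
    whose uptake transport is created with default capacity even when the
    organism's standalone exchange was closed to uptake — used when the
    organism's absorption of a lumen metabolite (e.g. the gut epithelium
    absorbing microbial fermentation acids) is precisely what the co-model
    is meant to add.
    """

    host_prefix: str = "H_"
    microbe_prefix: str = "M_"
    lumen_compartment: str = "lu"
    shared_compartments: frozenset[str] = frozenset({"e"})
    shared_metabolites: frozenset[str] | None = None  # base ids; None = all
    host_open_uptake: frozenset[str] = frozenset()
    microbe_open_uptake: frozenset[str] = frozenset()
    biomass_pattern: str = "biomass"
    min_biomass: float = 0.01
    default_bound: float = DEFAULT_BOUND


@dataclass
class CoMetabolismModel:
    """Merged host+microbe network with transport/diet bookkeeping."""

    model: MetabolicModel
    host_prefix: str
    microbe_prefix: str
    lumen_compartment: str
    diet_exchanges: set[str] = field(default_factory=set)
    host_uptake: set[str] = field(default_factory=set)
    host_secretion: set[str] = field(default_factory=set)
    microbe_uptake: set[str] = field(default_factory=set)
    microbe_secretion: set[str] = field(default_factory=set)
    biomass_reaction: str | None = None
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def copy(self) -> "CoMetabolismModel":
        return CoMetabolismModel(
            model=self.model.copy(),
            host_prefix=self.host_prefix,
            microbe_prefix=self.microbe_prefix,
            lumen_compartment=self.lumen_compartment,
            diet_exchanges=set(self.diet_exchanges),
            host_uptake=set(self.host_uptake),
            host_secretion=set(self.host_secretion),
            microbe_uptake=set(self.microbe_uptake),
            microbe_secretion=set(self.microbe_secretion),
            biomass_reaction=self.biomass_reaction,
            provenance={k: list(v) for k, v in self.provenance.items()},
        )

    # -- id helpers -------------------------------------------------------
    def lumen_metabolite(self, base: str) -> str:
        return f"{base}_{self.lumen_compartment}"

    def diet_exchange_id(self, base: str) -> str:
        return f"EX_{self.lumen_metabolite(base)}"

    def uptake_id(self, organism: str, base: str) -> str:
        prefix = self.host_prefix if organism == "host" else self.microbe_prefix
        return f"{prefix}UPT_{base}"

    def secretion_id(self, organism: str, base: str) -> str:
        prefix = self.host_prefix if organism == "host" else self.microbe_prefix
        return f"{prefix}SEC_{base}"


def _base_id(met: Metabolite) -> str:
    suffix = "_" + met.compartment
    if met.id.endswith(suffix):
        return met.id[: -len(suffix)]
    return met.id


def merge_into_comodel(
    host: MetabolicModel,
    microbe: MetabolicModel,
    policy: JoinPolicy | None = None,
) -> CoMetabolismModel:
    """Join two validated models through a common lumen compartment.

    Every exchange reaction on a shared extracellular metabolite is
    replaced by directed lumen transports inheriting its bounds; one lumen
    boundary exchange per lumen metabolite is created (diet in, efflux
    out, bounds +/-default until a diet is applied).  Non-shared boundary
    exchanges stay organism-level.  The host objective (prefixed) becomes
    the merged objective; the microbe biomass reaction, when found, gets
    ``policy.min_biomass`` as its lower bound so the microbe must grow.
    """
    policy = policy or JoinPolicy()
    require_valid(host)
    require_valid(microbe)
    if policy.host_prefix == policy.microbe_prefix:
        raise ValueError("host and microbe prefixes must differ")

    merged = MetabolicModel(id=f"{host.id}__{microbe.id}")
    merged.compartments[policy.lumen_compartment] = "lumen"
    merged.annotations = dict(host.annotations)
    co = CoMetabolismModel(
        model=merged,
        host_prefix=policy.host_prefix,
        microbe_prefix=policy.microbe_prefix,
        lumen_compartment=policy.lumen_compartment,
    )

    for organism, source, prefix, open_uptake in (
        ("host", host, policy.host_prefix, policy.host_open_uptake),
        ("microbe", microbe, policy.microbe_prefix, policy.microbe_open_uptake),
    ):
        _merge_organism(co, organism, source, prefix, open_uptake, policy)

    # one lumen boundary exchange per lumen metabolite
    for mid, met in list(merged.metabolites.items()):
        if met.compartment != policy.lumen_compartment:
            continue
        ex_id = f"EX_{mid}"
        if ex_id in merged.reactions:
            raise ValueError(f"id collision creating lumen exchange {ex_id!r}")
        merged.add_reaction(
            Reaction(
                id=ex_id,
                stoichiometry={mid: -1.0},
                lower_bound=-policy.default_bound,
                upper_bound=policy.default_bound,
                name=f"lumen exchange of {met.name or mid}",
                subsystem="Exchange",
                is_exchange=True,
            )
        )
        co.diet_exchanges.add(ex_id)

    # microbe biomass / growth requirement
    microbe_rxns = {
        rid: r
        for rid, r in merged.reactions.items()
        if rid.startswith(policy.microbe_prefix)
    }
    probe = MetabolicModel(id="probe", reactions=microbe_rxns)
    biomass = find_biomass_reaction(probe, policy.biomass_pattern)
    if biomass is not None:
        co.biomass_reaction = biomass
        if policy.min_biomass > 0:
            rxn = merged.reactions[biomass]
            rxn.lower_bound = max(rxn.lower_bound, policy.min_biomass)
    elif policy.min_biomass > 0:
        warnings.warn(
            f"no microbe biomass reaction matches {policy.biomass_pattern!r}; "
            "growth requirement not enforced",
            stacklevel=2,
        )

    require_valid(merged)
    findings = validate_comodel(co)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValueError("; ".join(str(f) for f in errors))
    return co


def _merge_organism(
    co: CoMetabolismModel,
    organism: str,
    source: MetabolicModel,
    prefix: str,
    open_uptake: frozenset[str],
    policy: JoinPolicy,
) -> None:
    merged = co.model

    def pref_comp(comp: str) -> str:
        return prefix + comp

    def pref_met(mid: str) -> str:
        return prefix + mid

    for comp, name in source.compartments.items():
        merged.compartments[pref_comp(comp)] = f"{organism} {name}"
    for met in source.metabolites.values():
        merged.add_metabolite(
            Metabolite(
                id=pref_met(met.id),
                compartment=pref_comp(met.compartment),
                name=met.name,
                formula=met.formula,
                charge=met.charge,
            )
        )

    uptake_set = co.host_uptake if organism == "host" else co.microbe_uptake
    secretion_set = co.host_secretion if organism == "host" else co.microbe_secretion

    for rxn in source.reactions.values():
        met0 = source.metabolites[next(iter(rxn.stoichiometry))]
        shared = (
            rxn.is_exchange
            and len(rxn.stoichiometry) == 1
            and met0.compartment in policy.shared_compartments
            and (
                policy.shared_metabolites is None
                or _base_id(met0) in policy.shared_metabolites
            )
        )
        if not shared:
            new_id = prefix + rxn.id
            if new_id in merged.reactions:
                raise ValueError(f"id collision after prefixing: {new_id!r}")
            merged.add_reaction(
                Reaction(
                    id=new_id,
                    stoichiometry={
                        pref_met(mid): c for mid, c in rxn.stoichiometry.items()
                    },
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    name=rxn.name,
                    subsystem=rxn.subsystem,
                    is_exchange=rxn.is_exchange,
                )
            )
            co.provenance.setdefault(f"{organism}:{rxn.id}", []).append(new_id)
            continue

        # rewrite the exchange as directed lumen transports
        base = _base_id(met0)
        lumen_mid = co.lumen_metabolite(base)
        if lumen_mid not in merged.metabolites:
            merged.add_metabolite(
                Metabolite(
                    id=lumen_mid,
                    compartment=policy.lumen_compartment,
                    name=met0.name or base,
                    formula=met0.formula,
                    charge=met0.charge,
                )
            )
        org_mid = pref_met(met0.id)
        k = abs(rxn.stoichiometry[met0.id])
        created: list[str] = []
        open_here = base in open_uptake
        if rxn.lower_bound < 0 or open_here:
            capacity = (
                policy.default_bound if open_here else -rxn.lower_bound
            )
            up_id = co.uptake_id(organism, base)
            if up_id in merged.reactions:
                raise ValueError(f"id collision after prefixing: {up_id!r}")
            merged.add_reaction(
                Reaction(
                    id=up_id,
                    stoichiometry={lumen_mid: -k, org_mid: k},
                    lower_bound=0.0,
                    upper_bound=capacity,
                    name=f"{organism} uptake of {base}",
                    subsystem="Lumen transport",
                )
            )
            uptake_set.add(up_id)
            created.append(up_id)
        if rxn.upper_bound > 0:
            sec_id = co.secretion_id(organism, base)
            if sec_id in merged.reactions:
                raise ValueError(f"id collision after prefixing: {sec_id!r}")
            merged.add_reaction(
                Reaction(
                    id=sec_id,
                    stoichiometry={org_mid: -k, lumen_mid: k},
                    lower_bound=0.0,
                    upper_bound=rxn.upper_bound,
                    name=f"{organism} secretion of {base}",
                    subsystem="Lumen transport",
                )
            )
            secretion_set.add(sec_id)
            created.append(sec_id)
        co.provenance.setdefault(f"{organism}:{rxn.id}", []).extend(created)

    if organism == "host" and source.objective:
        for rid, coeff in source.objective.items():
            new_id = prefix + rid
            if new_id in merged.reactions:
                merged.objective[new_id] = coeff
            else:
                # objective sat on a rewritten exchange; point it at the
                # host secretion transport for that metabolite
                rxn = source.reactions[rid]
                base = _base_id(source.metabolites[next(iter(rxn.stoichiometry))])
                merged.objective[co.secretion_id("host", base)] = coeff


def validate_comodel(co: CoMetabolismModel) -> list[ValidationFinding]:
    """Co-model invariants: disjoint transport sets, every transport crosses
    the lumen boundary, diet exchanges are lumen boundary reactions, and
    lumen metabolites are only touched by transports and their own exchange
    (mass exchange closure)."""
    findings = list(validate_model(co.model))
    sets = [
        ("host_uptake", co.host_uptake),
        ("host_secretion", co.host_secretion),
        ("microbe_uptake", co.microbe_uptake),
        ("microbe_secretion", co.microbe_secretion),
    ]
    seen: dict[str, str] = {}
    for name, ids in sets:
        for rid in ids:
            if rid in seen:
                findings.append(
                    ValidationFinding(
                        "error",
                        "transport-overlap",
                        rid,
                        f"in both {seen[rid]} and {name}",
                    )
                )
            seen[rid] = name
            rxn = co.model.reactions.get(rid)
            if rxn is None:
                findings.append(
                    ValidationFinding("error", "missing-transport", rid, "not in model")
                )
                continue
            comps = {
                co.model.metabolites[mid].compartment for mid in rxn.stoichiometry
            }
            if co.lumen_compartment not in comps or len(comps) < 2:
                findings.append(
                    ValidationFinding(
                        "error",
                        "not-a-lumen-transport",
                        rid,
                        f"compartments {sorted(comps)} do not cross the lumen",
                    )
                )
    lumen_touchers = set(seen) | set(co.diet_exchanges)
    for ex in co.diet_exchanges:
        rxn = co.model.reactions.get(ex)
        if rxn is None or len(rxn.stoichiometry) != 1:
            findings.append(
                ValidationFinding(
                    "error", "bad-diet-exchange", ex, "not a single-metabolite reaction"
                )
            )
            continue
        mid = next(iter(rxn.stoichiometry))
        if co.model.metabolites[mid].compartment != co.lumen_compartment:
            findings.append(
                ValidationFinding(
                    "error", "bad-diet-exchange", ex, "metabolite not in lumen"
                )
            )
    for rid, rxn in co.model.reactions.items():
        touches_lumen = any(
            co.model.metabolites[mid].compartment == co.lumen_compartment
            for mid in rxn.stoichiometry
        )
        if touches_lumen and rid not in lumen_touchers:
            findings.append(
                ValidationFinding(
                    "error",
                    "lumen-closure",
                    rid,
                    "reaction touches the lumen but is neither a registered "
                    "transport nor a diet exchange",
                )
            )
    return findings


def cap_microbe_secretion(
    co: CoMetabolismModel,
    cap: float | str = 0.0,
    viability_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0),
) -> CoMetabolismModel:
    """Restrict every microbe secretion transport to at most ``cap``.

    This is the control condition: with the cap at (or near) zero the
    microbe cannot feed the host, so prebiotic dose response of the host
    objective goes flat.  ``cap="viability"`` picks the smallest value on
    ``viability_grid`` that keeps the co-model feasible (microbe growth
    requirement included).  A numeric cap that leaves the system infeasible
    raises :class:`InfeasibleSystemError` naming the capped reactions.
    """
    if cap == "viability":
        for candidate in sorted(viability_grid):
            capped = _apply_cap(co, float(candidate))
            if check_feasible(capped.model):
                return capped
        raise InfeasibleSystemError(
            "no cap on the viability grid keeps the co-model feasible",
            sorted(co.microbe_secretion),
        )
    cap = float(cap)
    if cap < 0:
        raise ValueError("cap must be >= 0")
    capped = _apply_cap(co, cap)
    if not check_feasible(capped.model):
        raise InfeasibleSystemError(
            f"cap {cap} leaves the co-model infeasible at the configured "
            "minimum growth",
            sorted(co.microbe_secretion),
        )
    return capped


def _apply_cap(co: CoMetabolismModel, cap: float) -> CoMetabolismModel:
    capped = co.copy()
    for rid in capped.microbe_secretion:
        rxn = capped.model.reactions[rid]
        rxn.upper_bound = min(rxn.upper_bound, cap)
        rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    return capped
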