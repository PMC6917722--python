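"""Diet presets and prebiotic supplementation as exchange-bound constraints.

A prebiotic dose given in grams is amortized over a time horizon and
converted to a molar uptake bound per component:

    b_i = dose_grams * mass_fraction_i / grams_per_mmol_i / horizon_hours

scaled by a per-gram-dry-weight normalization constant (default 1), in
mmol/h.  Supplementation then sets the component's diet-exchange bounds to
``(-b_i, 0)`` — uptake *allowed up to* the dose, not forced.  Forced uptake
could render the system infeasible and would break the monotone,
saturating dose response the allow-up-to reading produces.

scFOS is a mixture of kestose (GF2), kestotetraose (GF3) and kestopentaose
(GF4); its default composition here is equal mass thirds, and the default
molar masses are the average formula weights of the three oligomers.
Inulin is treated as a fructan polymer of configurable degree of
polymerization (default 10).  All of these are overridable through the
YAML presets, since absolute gram-to-flux calibration dominates any
absolute-flux comparison between model variants.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .comodel import CoMetabolismModel
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "DietSpec",
    "PrebioticComponent",
    "PrebioticSpec",
    "apply_diet",
    "dose_to_flux",
    "apply_prebiotic",
    "apply_prebiotic_to_model",
    "apply_diet_to_model",
    "load_diet_preset",
    "load_prebiotic_preset",
    "inulin_grams_per_mmol",
]

_GLUCOSE_MW = 180.156  # g/mol
_ANHYDROFRUCTOSE_MW = 162.141  # g/mol, fructose unit in a fructan chain


def inulin_grams_per_mmol(degree_of_polymerization: int = 10) -> float:
    """Average molar mass (g/mmol) of a GF(n) fructan chain."""
    if degree_of_polymerization < 1:
        raise ValueError("degree of polymerization must be >= 1")
    mw = _GLUCOSE_MW + _ANHYDROFRUCTOSE_MW * degree_of_polymerization
    return mw / 1000.0


@dataclass
class DietSpec:
    """Named set of diet-exchange bounds (flux units)."""

    name: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"diet bound {key!r}: lower {lo} > upper {hi}")


@dataclass
class PrebioticComponent:
    exchange: str  # diet-exchange id (or base metabolite id)
    mass_fraction: float
    grams_per_mmol: float


@dataclass
class PrebioticSpec:
    """A prebiotic as a list of components with a dose-to-flux conversion."""

    name: str
    components: list[PrebioticComponent]
    horizon_hours: float = 24.0
    gdw_scale: float = 1.0

    def __post_init__(self) -> None:
        total = sum(c.mass_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"prebiotic {self.name!r}: mass fractions sum to {total}, not 1"
            )
        for c in self.components:
            if c.grams_per_mmol <= 0:
                raise ValueError(
                    f"prebiotic {self.name!r}: grams_per_mmol must be positive "
                    f"({c.exchange}: {c.grams_per_mmol})"
                )
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be positive")


def dose_to_flux(prebiotic: PrebioticSpec, dose_grams: float) -> dict[str, float]:
    """Per-component uptake bound (mmol/h, >= 0) for a dose in grams."""
    if dose_grams < 0:
        raise ValueError("dose must be >= 0")
    return {
        c.exchange: dose_grams
        * c.mass_fraction
        / c.grams_per_mmol
        / prebiotic.horizon_hours
        * prebiotic.gdw_scale
        for c in prebiotic.components
    }


# ---------------------------------------------------------------------------
# resolution of exchange ids against a model


def _strip_exchange(target: str) -> str:
    base = target
    if base.startswith("EX_"):
        base = base[3:]
    if "_" in base:
        head, _, comp = base.rpartition("_")
        if head and len(comp) <= 3:  # compartment suffixes are short (e, lu, c0)
            base = head
    return base


def _met_base(model: MetabolicModel, mid: str) -> str:
    met = model.metabolites[mid]
    suffix = "_" + met.compartment
    return met.id[: -len(suffix)] if met.id.endswith(suffix) else met.id


def resolve_exchange(
    model: MetabolicModel,
    target: str,
    restrict_to: set[str] | None = None,
) -> str | None:
    """Find the exchange reaction a diet/prebiotic key refers to.

    Exact reaction id first; otherwise the key is reduced to a base
    metabolite id and matched against single-metabolite exchanges, so one
    preset works against both a co-model (lumen exchanges) and a standalone
    organism model (``_e`` exchanges)."""
    pool = restrict_to if restrict_to is not None else set(model.reactions)
    if target in pool:
        return target
    base = _strip_exchange(target)
    for rid in pool:
        rxn = model.reactions[rid]
        if not rxn.is_exchange or len(rxn.stoichiometry) != 1:
            continue
        mid = next(iter(rxn.stoichiometry))
        if _met_base(model, mid) == base:
            return rid
    return None


def _unresolved(model: MetabolicModel, target: str, pool: set[str]) -> KeyError:
    near = difflib.get_close_matches(target, sorted(pool), n=3)
    hint = f"; nearest matches: {near}" if near else ""
    return KeyError(f"cannot resolve exchange {target!r}{hint}")


# ---------------------------------------------------------------------------
# application to co-models


def apply_diet(co: CoMetabolismModel, diet: DietSpec) -> CoMetabolismModel:
    """Set the named diet-exchange bounds; close uptake (lb=0) on every
    unlisted diet exchange, leaving secretion open.  Idempotent."""
    out = co.copy()
    resolved: dict[str, tuple[float, float]] = {}
    for key, bounds in diet.bounds.items():
        rid = resolve_exchange(out.model, key, out.diet_exchanges)
        if rid is None:
            raise _unresolved(out.model, key, out.diet_exchanges)
        resolved[rid] = bounds
    for rid in out.diet_exchanges:
        rxn = out.model.reactions[rid]
        if rid in resolved:
            rxn.bounds = resolved[rid]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


def apply_prebiotic(
    co: CoMetabolismModel, prebiotic: PrebioticSpec, dose_grams: float
) -> CoMetabolismModel:
    """Constrain the prebiotic components' lumen exchanges to ``(-b_i, 0)``.

    Components without a matching lumen exchange are created (with a
    warning) so that supplementation of a model lacking the food metabolite
    is explicit rather than silently absent.  Re-application overwrites:
    the final bounds always reflect the last dose."""
    out = co.copy()
    for exchange, bound in dose_to_flux(prebiotic, dose_grams).items():
        rid = resolve_exchange(out.model, exchange, out.diet_exchanges)
        if rid is None:
            rid = _create_lumen_exchange(out, exchange)
        out.model.reactions[rid].bounds = (-bound, 0.0)
    return out


def _create_lumen_exchange(co: CoMetabolismModel, exchange: str) -> str:
    base = _strip_exchange(exchange)
    mid = co.lumen_metabolite(base)
    warnings.warn(
        f"prebiotic exchange {exchange!r} absent from the co-model; creating "
        f"lumen exchange for {base!r} (no organism consumes it)",
        stacklevel=3,
    )
    if mid not in co.model.metabolites:
        co.model.add_metabolite(
            Metabolite(id=mid, compartment=co.lumen_compartment, name=base)
        )
    rid = co.diet_exchange_id(base)
    co.model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry={mid: -1.0},
            lower_bound=0.0,
            upper_bound=0.0,
            subsystem="Exchange",
            is_exchange=True,
        )
    )
    co.diet_exchanges.add(rid)
    return rid


# ---------------------------------------------------------------------------
# application to standalone organism models (collection screening)


def apply_diet_to_model(model: MetabolicModel, diet: DietSpec) -> MetabolicModel:
    """Same contract as :func:`apply_diet` but on a standalone model's own
    exchange reactions."""
    out = model.copy()
    exchanges = {r.id for r in out.exchanges}
    resolved: dict[str, tuple[float, float]] = {}
    for key, bounds in diet.bounds.items():
        rid = resolve_exchange(out, key, exchanges)
        if rid is None:
            continue  # a diet component the organism has no exchange for
        resolved[rid] = bounds
    for rid in exchanges:
        rxn = out.reactions[rid]
        if rid in resolved:
            rxn.bounds = resolved[rid]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


def apply_prebiotic_to_model(
    model: MetabolicModel, prebiotic: PrebioticSpec, dose_grams: float
) -> tuple[MetabolicModel, bool]:
    """Standalone variant; returns ``(model, found)`` where ``found`` is
    False when the organism has no exchange for any component."""
    out = model.copy()
    exchanges = {r.id for r in out.exchanges}
    found = False
    for exchange, bound in dose_to_flux(prebiotic, dose_grams).items():
        rid = resolve_exchange(out, exchange, exchanges)
        if rid is None:
            continue
        out.reactions[rid].bounds = (-bound, 0.0)
        found = True
    return out, found


# ---------------------------------------------------------------------------
# presets


def _preset_text(filename: str) -> str:
    return resources.files("lumenfba.presets").joinpath(filename).read_text()


def load_diet_preset(name: str, path: str | Path | None = None) -> DietSpec:
    """Load a diet preset from the bundled YAML (or a user file)."""
    text = Path(path).read_text() if path else _preset_text("diets.yaml")
    doc = yaml.safe_load(text)
    if name not in doc:
        raise KeyError(f"no diet preset {name!r}; available: {sorted(doc)}")
    entry = doc[name]
    return DietSpec(
        name=name,
        bounds={k: (float(v[0]), float(v[1])) for k, v in entry["bounds"].items()},
    )


def load_prebiotic_preset(name: str, path: str | Path | None = None) -> PrebioticSpec:
    """Load a prebiotic preset from the bundled YAML (or a user file)."""
    text = Path(path).read_text() if path else _preset_text("prebiotics.yaml")
    doc = yaml.safe_load(text)
    if name not in doc:
        raise KeyError(f"no prebiotic preset {name!r}; available: {sorted(doc)}")
    entry = doc[name]
    components = [
        PrebioticComponent(
            exchange=c["exchange"],
            mass_fraction=float(c["mass_fraction"]),
            grams_per_mmol=float(c["grams_per_mmol"]),
        )
        for c in entry["components"]
    ]
    return PrebioticSpec(
        name=name,
        components=components,
        horizon_hours=float(entry.get("horizon_hours", 24.0)),
        gdw_scale=float(entry.get("gdw_scale", 1.0)),
    )
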