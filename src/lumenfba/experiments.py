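"""The four co-metabolism analyses.

* dose response: sweep the prebiotic dose, maximize host
  25-hydroxyvitamin-D3 secretion, track the 7-DHC chain fluxes (with an
  optional microbe-secretion-capped control that should stay flat);
* secretion/absorption profiling and single-reaction knock-off scanning of
  the acetate/lactate/pyruvate routes;
* collection screening: which organisms of a model collection utilize a
  prebiotic, and the maximum acid secretion each reaches over the dose
  grid (the heatmap statistic);
* flux-mode extraction and the subsystem flux-change fraction

      subsystem fraction = reactions of the subsystem with flux change
                           / total reactions of the subsystem

  computed over the host's internal reactions after retaining the top
  90% of changed reactions ranked by percent relative flux change.

All reported flux vectors come from parsimonious FBA so that individual
reaction fluxes are reproducible; results serialize to TSV with a fixed
column order and float format, so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .comodel import CoMetabolismModel, cap_microbe_secretion
from .conditions import (
    PrebioticSpec,
    DietSpec,
    apply_diet_to_model,
    apply_prebiotic,
    apply_prebiotic_to_model,
    resolve_exchange,
)
from .fba import FluxSolution, knock_off, solve_fba, solve_pfba
from .io import read_model
from .model import MetabolicModel

__all__ = [
    "DoseResponse",
    "KnockoffResult",
    "ScreenResult",
    "SubsystemReport",
    "FluxMode",
    "run_dose_response",
    "profile_secretion_absorption",
    "run_knockoff_scan",
    "screen_collection",
    "extract_flux_modes",
    "subsystem_flux_change",
]

_FLOAT_FMT = "%.10g"
ACID_BASES = ("ac", "lac", "pyr")


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseResponse:
    prebiotic: str
    doses: list[float]
    records: pd.DataFrame  # one row per dose
    control: bool = False

    def objective_curve(self) -> pd.Series:
        return self.records.set_index("dose")["objective"]

    def fold_change(self) -> float:
        """Objective at the top dose over the zero/lowest-dose baseline."""
        curve = self.records["objective"]
        base = curve.iloc[0]
        return float(curve.iloc[-1] / base) if base else math.inf

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_dose_response(
    co: CoMetabolismModel,
    prebiotic: PrebioticSpec,
    doses: list[float],
    objective: str | dict[str, float] | None = None,
    tracked_reactions: tuple[str, ...] = (),
    control: bool = False,
    control_cap: float = 0.0,
) -> DoseResponse:
    """Objective and tracked fluxes along a strictly increasing dose grid.

    With ``control=True`` every microbe secretion transport is capped at
    ``control_cap`` first (the viability-preserving control), which should
    flatten the response.  Infeasible dose points are recorded with their
    status and the sweep continues.
    """
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")
    for rid in tracked_reactions:
        if rid not in co.model.reactions:
            raise KeyError(f"tracked reaction {rid!r} not in co-model")
    base = cap_microbe_secretion(co, control_cap) if control else co
    rows = []
    for dose in doses:
        dosed = apply_prebiotic(base, prebiotic, dose)
        sol = solve_pfba(dosed.model, objective)
        row: dict[str, object] = {
            "dose": dose,
            "status": sol.status,
            "objective": sol.objective_value if sol.optimal else float("nan"),
        }
        for rid in tracked_reactions:
            row[rid] = sol.flux(rid) if sol.optimal else float("nan")
        rows.append(row)
    records = pd.DataFrame(
        rows, columns=["dose", "status", "objective", *tracked_reactions]
    )
    return DoseResponse(
        prebiotic=prebiotic.name, doses=list(doses), records=records, control=control
    )


# ---------------------------------------------------------------------------
# secretion/absorption profile


def profile_secretion_absorption(
    solution: FluxSolution,
    co: CoMetabolismModel,
    metabolites: tuple[str, ...] = ACID_BASES,
) -> pd.DataFrame:
    """Per lumen metabolite: net microbe secretion and host absorption
    (both signed to positive-secretes / positive-absorbs), diet inflow and
    lumen efflux, plus the lumen mass-balance residual."""
    if not solution.optimal:
        raise ValueError("profile requires an optimal solution")
    rows = []
    for base in metabolites:
        m_sec = solution.flux(co.secretion_id("microbe", base))
        m_upt = solution.flux(co.uptake_id("microbe", base))
        h_sec = solution.flux(co.secretion_id("host", base))
        h_upt = solution.flux(co.uptake_id("host", base))
        transported = any(
            rid in co.model.reactions
            for rid in (
                co.secretion_id("microbe", base),
                co.uptake_id("microbe", base),
                co.secretion_id("host", base),
                co.uptake_id("host", base),
            )
        )
        ex_flux = solution.flux(co.diet_exchange_id(base))
        diet_in = max(-ex_flux, 0.0)
        efflux = max(ex_flux, 0.0)
        secretion = m_sec - m_upt
        absorption = h_upt - h_sec
        residual = diet_in + secretion - absorption - efflux
        rows.append(
            {
                "metabolite": base,
                "microbe_secretion": secretion,
                "host_absorption": absorption,
                "diet_inflow": diet_in,
                "lumen_efflux": efflux,
                "balance_residual": residual,
                "transported": transported,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# knock-off scan


@dataclass
class KnockoffResult:
    reaction_id: str
    objective_before: float
    objective_after: float
    status_after: str
    flux_deltas: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def percent_reduction(self) -> float:
        if self.objective_before <= 0:
            return 0.0
        return 100.0 * (self.objective_before - self.objective_after) / self.objective_before


def run_knockoff_scan(
    co: CoMetabolismModel,
    candidate_reactions: list[str] | None,
    prebiotic: PrebioticSpec,
    dose: float,
    objective: str | dict[str, float] | None = None,
    tracked_exchanges: list[str] | None = None,
) -> list[KnockoffResult]:
    """One knock-off + re-solve per candidate, against a single baseline.

    Candidates default to the host uptake transports (the routes carrying
    microbial metabolites into the host); tracked exchanges default to all
    host uptake and microbe secretion transports, recording how the other
    routes readjust.  An infeasible knock-off records objective 0 with its
    status.
    """
    dosed = apply_prebiotic(co, prebiotic, dose)
    if candidate_reactions is None:
        candidate_reactions = sorted(co.host_uptake)
    for rid in candidate_reactions:
        if rid not in dosed.model.reactions:
            raise KeyError(f"knock-off candidate {rid!r} not in co-model")
    if tracked_exchanges is None:
        tracked_exchanges = sorted(co.host_uptake | co.microbe_secretion)
    baseline = solve_pfba(dosed.model, objective)
    if not baseline.optimal:
        raise ValueError(f"baseline not optimal: {baseline.status}")
    results = []
    for rid in candidate_reactions:
        knocked = knock_off(dosed.model, rid)
        sol = solve_pfba(knocked, objective)
        after = sol.objective_value if sol.optimal else 0.0
        deltas = {
            t: (baseline.flux(t), sol.flux(t) if sol.optimal else float("nan"))
            for t in tracked_exchanges
        }
        results.append(
            KnockoffResult(
                reaction_id=rid,
                objective_before=baseline.objective_value,
                objective_after=after,
                status_after=sol.status,
                flux_deltas=deltas,
            )
        )
    return results


def knockoff_table(results: list[KnockoffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "objective_before": r.objective_before,
                "objective_after": r.objective_after,
                "percent_reduction": r.percent_reduction,
                "status_after": r.status_after,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# collection screen


@dataclass
class ScreenResult:
    """Per (organism, prebiotic) utilization and per-metabolite maximum
    secretion over the dose grid, plus the full dose profiles."""

    summary: pd.DataFrame
    profiles: pd.DataFrame  # organism, prebiotic, metabolite, dose, flux
    dose_grid: list[float]
    mode: str

    def to_heatmap_tsv(self, path: str | Path) -> None:
        wide = self.summary.pivot_table(
            index="organism",
            columns="prebiotic",
            values=[c for c in self.summary.columns if c.startswith("max_")],
            sort=True,
        )
        wide.columns = [f"{p}:{m[4:]}" for m, p in wide.columns]
        wide = wide.reindex(sorted(wide.columns), axis=1).sort_index()
        wide.to_csv(path, sep="\t", float_format=_FLOAT_FMT)

    def to_tsv(self, path: str | Path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def screen_collection(
    models: list[str | Path | MetabolicModel],
    prebiotics: list[PrebioticSpec],
    dose_grid: list[float],
    metabolites: tuple[str, ...] = ACID_BASES,
    mode: str = "potential",
    diet: DietSpec | None = None,
    utilization_rtol: float = 1e-6,
) -> ScreenResult:
    """Screen standalone organism models for prebiotic utilization and
    acid secretion.

    ``utilizes`` means the organism has an exchange for at least one
    prebiotic component *and* its maximum growth improves (relative
    tolerance ``utilization_rtol``) at the top dose.  Secretion per dose is
    measured either as the direct maximum of the metabolite's secretion
    exchange (``mode="potential"``, matching a max-flux-in-range heatmap)
    or as the pFBA secretion at maximum growth (``mode="growth-coupled"``).
    Models are processed one at a time (constant memory in collection
    size); unreadable models get a flagged row and screening continues.
    """
    if not dose_grid:
        raise ValueError("dose grid must be non-empty")
    if mode not in ("potential", "growth-coupled"):
        raise ValueError(f"unknown screen mode {mode!r}")
    doses = sorted(dose_grid)
    top_dose = doses[-1]
    summary_rows = []
    profile_rows = []
    for entry in models:
        if isinstance(entry, MetabolicModel):
            organism, model, error = entry.id, entry, ""
        else:
            organism = Path(entry).name
            try:
                model = read_model(entry)
                organism, error = model.id or organism, ""
            except Exception as exc:  # noqa: BLE001 - row-level isolation
                summary_rows.extend(
                    {
                        "organism": organism,
                        "prebiotic": p.name,
                        "utilizes": False,
                        "error": str(exc)[:200],
                        **{f"max_{m}": float("nan") for m in metabolites},
                    }
                    for p in prebiotics
                )
                continue
        if diet is not None:
            model = apply_diet_to_model(model, diet)
        for prebiotic in prebiotics:
            row = _screen_one(
                model, organism, prebiotic, doses, top_dose, metabolites,
                mode, utilization_rtol, profile_rows,
            )
            summary_rows.append(row)
    columns = ["organism", "prebiotic", "utilizes", "error"] + [
        f"max_{m}" for m in metabolites
    ]
    summary = pd.DataFrame(summary_rows, columns=columns)
    profiles = pd.DataFrame(
        profile_rows, columns=["organism", "prebiotic", "metabolite", "dose", "flux"]
    )
    return ScreenResult(summary=summary, profiles=profiles, dose_grid=doses, mode=mode)


def _max_growth(model: MetabolicModel) -> float:
    sol = solve_fba(model)
    return sol.objective_value if sol.optimal else 0.0


def _screen_one(
    model, organism, prebiotic, doses, top_dose, metabolites, mode,
    utilization_rtol, profile_rows,
) -> dict:
    base_growth = _max_growth(apply_prebiotic_to_model(model, prebiotic, 0.0)[0])
    top_model, found = apply_prebiotic_to_model(model, prebiotic, top_dose)
    top_growth = _max_growth(top_model) if found else base_growth
    utilizes = bool(
        found and top_growth - base_growth > utilization_rtol * max(1.0, base_growth)
    )
    maxima = {m: 0.0 for m in metabolites}
    for dose in doses:
        dosed, _ = apply_prebiotic_to_model(model, prebiotic, dose)
        if mode == "growth-coupled":
            sol = solve_pfba(dosed)
        for met in metabolites:
            ex = resolve_exchange(dosed, met, {r.id for r in dosed.exchanges})
            if ex is None:
                flux = 0.0
            elif mode == "potential":
                s = solve_fba(dosed, objective=ex)
                flux = max(s.objective_value, 0.0) if s.optimal else 0.0
            else:
                flux = max(sol.flux(ex), 0.0) if sol.optimal else 0.0
            profile_rows.append(
                {
                    "organism": organism,
                    "prebiotic": prebiotic.name,
                    "metabolite": met,
                    "dose": dose,
                    "flux": flux,
                }
            )
            maxima[met] = max(maxima[met], flux)
    return {
        "organism": organism,
        "prebiotic": prebiotic.name,
        "utilizes": utilizes,
        "error": "",
        **{f"max_{m}": maxima[m] for m in metabolites},
    }


# ---------------------------------------------------------------------------
# flux modes


@dataclass
class FluxMode:
    dose: float
    fluxes: dict[str, float]
    active: dict[str, bool]
    absent: list[str] = field(default_factory=list)
    activity_tolerance: float = 1e-6


def extract_flux_modes(
    co: CoMetabolismModel,
    prebiotic: PrebioticSpec,
    doses: list[float],
    pathway_def: list[str],
    objective: str | dict[str, float] | None = None,
    activity_tolerance: float = 1e-6,
) -> list[FluxMode]:
    """Parsimonious fluxes through a named pathway at each dose, with an
    active flag per reaction (``|v| >= activity_tolerance``).  Pathway ids
    missing from the co-model are listed as absent, not fatal."""
    modes = []
    present = [rid for rid in pathway_def if rid in co.model.reactions]
    absent = [rid for rid in pathway_def if rid not in co.model.reactions]
    for dose in doses:
        dosed = apply_prebiotic(co, prebiotic, dose)
        sol = solve_pfba(dosed.model, objective)
        fluxes = {rid: sol.flux(rid) if sol.optimal else float("nan") for rid in present}
        active = {
            rid: bool(sol.optimal and abs(fluxes[rid]) >= activity_tolerance)
            for rid in present
        }
        modes.append(
            FluxMode(
                dose=dose,
                fluxes=fluxes,
                active=active,
                absent=list(absent),
                activity_tolerance=activity_tolerance,
            )
        )
    return modes


def flux_modes_table(modes: list[FluxMode]) -> pd.DataFrame:
    rows = []
    for mode in modes:
        for rid, v in mode.fluxes.items():
            rows.append(
                {"dose": mode.dose, "reaction_id": rid, "flux": v,
                 "active": mode.active[rid]}
            )
    return pd.DataFrame(rows, columns=["dose", "reaction_id", "flux", "active"])


# ---------------------------------------------------------------------------
# subsystem flux-change fractions


@dataclass
class SubsystemReport:
    table: pd.DataFrame  # subsystem, n_changed, n_total, fraction
    dose: float
    percentile_cut: float
    eps: float
    selected: list[str] = field(default_factory=list)

    def fraction(self, subsystem: str) -> float:
        hit = self.table[self.table["subsystem"] == subsystem]
        return float(hit["fraction"].iloc[0]) if len(hit) else 0.0

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def subsystem_flux_change(
    co: CoMetabolismModel,
    prebiotic: PrebioticSpec,
    dose: float,
    objective: str | dict[str, float] | None = None,
    percentile_cut: float = 0.9,
    eps: float = 1e-9,
    change_tolerance: float = 1e-6,
) -> SubsystemReport:
    """Fraction of each host subsystem's reactions whose flux changes
    under supplementation.

    Per internal host reaction the percent relative change is
    ``100 * |v_supp - v_base| / max(|v_base|, eps)``; reactions going from
    zero to nonzero rank above every finite change.  Changed reactions
    (absolute change above ``change_tolerance``) are ranked by that
    statistic and the top ``percentile_cut`` share retained (count-based,
    ``ceil``); the subsystem fraction is retained-over-total within each
    subsystem.  A model without subsystem labels falls into a single
    "unlabelled" subsystem.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    base_sol = solve_pfba(apply_prebiotic(co, prebiotic, 0.0).model, objective)
    supp_sol = solve_pfba(apply_prebiotic(co, prebiotic, dose).model, objective)
    for name, sol in (("baseline", base_sol), ("supplemented", supp_sol)):
        if not sol.optimal:
            raise ValueError(f"{name} solution not optimal: {sol.status}")

    transports = co.host_uptake | co.host_secretion
    internal = [
        rid
        for rid, rxn in co.model.reactions.items()
        if rid.startswith(co.host_prefix)
        and rid not in transports
        and not rxn.is_exchange
    ]
    scored = []
    for rid in internal:
        vb, vs = base_sol.flux(rid), supp_sol.flux(rid)
        delta = abs(vs - vb)
        changed = delta > change_tolerance
        if abs(vb) <= eps:
            rel = math.inf if changed else 0.0
        else:
            rel = 100.0 * delta / max(abs(vb), eps)
        scored.append((rid, changed, rel))

    changed_ids = [(rid, rel) for rid, changed, rel in scored if changed]
    changed_ids.sort(key=lambda t: (-t[1], t[0]))
    keep = math.ceil(percentile_cut * len(changed_ids))
    selected = [rid for rid, _ in changed_ids[:keep]]
    selected_set = set(selected)

    subsystems: dict[str, list[str]] = {}
    for rid in internal:
        label = co.model.reactions[rid].subsystem or "unlabelled"
        subsystems.setdefault(label, []).append(rid)
    rows = []
    for label in sorted(subsystems):
        members = subsystems[label]
        n_changed = sum(rid in selected_set for rid in members)
        rows.append(
            {
                "subsystem": label,
                "n_changed": n_changed,
                "n_total": len(members),
                "fraction": n_changed / len(members),
            }
        )
    table = pd.DataFrame(rows, columns=["subsystem", "n_changed", "n_total", "fraction"])
    return SubsystemReport(
        table=table,
        dose=dose,
        percentile_cut=percentile_cut,
        eps=eps,
        selected=selected,
    )
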