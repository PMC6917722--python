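"""Flux balance analysis: the LP, its parsimonious refinement, knock-offs.

FBA solves ``max c.v`` subject to the steady-state constraint ``S.v = 0``
and flux bounds ``lb <= v <= ub``.  The LP is handed to HiGHS through
``scipy.optimize.linprog`` with fixed settings, so results are deterministic
for a given model — there is no randomness anywhere in this module.

Plain FBA optima are unique, but the optimal flux *vector* generally is not
(alternate optima share the objective value).  Whenever individual reaction
fluxes are reported downstream, the parsimonious refinement
(:func:`solve_pfba`) is used: a second LP minimizing total absolute flux
``sum |v|`` while holding the stage-1 objective fixed, which resolves the
degeneracy reproducibly.  ``sum |v|`` is linearized by splitting every flux
into non-negative forward and reverse parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, require_valid

__all__ = [
    "FluxSolution",
    "solve_fba",
    "solve_pfba",
    "knock_off",
    "check_feasible",
    "SolverError",
]

#: feasibility/optimality tolerance used when verifying solutions
DEFAULT_TOLERANCE = 1e-9

#: relative tolerance on the stage-1 optimum during the pFBA stage 2
PFBA_RELATIVE_TOLERANCE = 1e-9

_LINPROG_OPTIONS = {"presolve": True}


class SolverError(RuntimeError):
    """The LP backend failed for a numerical (not infeasibility) reason."""


@dataclass
class FluxSolution:
    """Solver status, optimum and full flux vector of one FBA problem."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_ids: dict[str, float] = field(default_factory=dict)
    feasibility_tolerance: float = DEFAULT_TOLERANCE
    is_parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes.get(reaction_id, 0.0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v:.10g}\n")


def _objective_map(
    model: MetabolicModel, objective: str | dict[str, float] | None
) -> dict[str, float]:
    if objective is None:
        obj = dict(model.objective)
    elif isinstance(objective, str):
        obj = {objective: 1.0}
    else:
        obj = dict(objective)
    missing = [rid for rid in obj if rid not in model.reactions]
    if missing:
        raise KeyError(f"objective reactions not in model: {missing}")
    if not obj:
        raise ValueError("no objective reaction given and model has none")
    return obj


_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded"}


def solve_fba(
    model: MetabolicModel,
    objective: str | dict[str, float] | None = None,
    sense: str = "max",
    tolerance: float = DEFAULT_TOLERANCE,
) -> FluxSolution:
    """Solve the FBA linear program.

    Parameters
    ----------
    model:
        A validated metabolic model.
    objective:
        Reaction id, coefficient map, or ``None`` for the model objective.
    sense:
        ``"max"`` (default, e.g. 25-hydroxyvitamin-D3 secretion
        maximization) or ``"min"``.
    """
    require_valid(model)
    obj = _objective_map(model, objective)
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        if rid in obj:
            c[j] = obj[rid]
    sign = -1.0 if sense == "max" else 1.0

    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    status = _STATUS.get(res.status, "error")
    if status in ("error", "iteration-limit"):
        raise SolverError(f"LP backend failure ({res.status}): {res.message}")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None, objective_ids=obj,
                            feasibility_tolerance=tolerance)
    fluxes = dict(zip(rxn_ids, res.x))
    value = float(c @ res.x)
    return FluxSolution(
        status="optimal",
        objective_value=value,
        fluxes=fluxes,
        objective_ids=obj,
        feasibility_tolerance=tolerance,
    )


def solve_pfba(
    model: MetabolicModel,
    objective: str | dict[str, float] | None = None,
    sense: str = "max",
    tolerance: float = DEFAULT_TOLERANCE,
    relative_tolerance: float = PFBA_RELATIVE_TOLERANCE,
) -> FluxSolution:
    """Parsimonious FBA: minimize ``sum |v|`` at the stage-1 optimum.

    The stage-1 objective is held within ``relative_tolerance`` of its
    optimum; the returned solution reports the stage-1 objective value and
    ``is_parsimonious=True``.
    """
    stage1 = solve_fba(model, objective, sense=sense, tolerance=tolerance)
    if not stage1.optimal:
        return stage1
    opt = stage1.objective_value

    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(rxn_ids)
    c = np.zeros(n)
    for j, rid in enumerate(rxn_ids):
        c[j] = stage1.objective_ids.get(rid, 0.0)

    # v = f - r with f, r >= 0; bounds chosen so that f - r spans [lb, ub]
    f_lo, f_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    r_lo, r_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    A_eq = sparse.hstack([S, -S], format="csr")
    b_eq = np.zeros(S.shape[0])

    slack = relative_tolerance * max(1.0, abs(opt))
    if sense == "max":
        # c.v >= opt - slack  <=>  -c.(f - r) <= -(opt - slack)
        A_ub = sparse.hstack([-sparse.csr_matrix(c), sparse.csr_matrix(c)])
        b_ub = np.array([-(opt - slack)])
    else:
        A_ub = sparse.hstack([sparse.csr_matrix(c), -sparse.csr_matrix(c)])
        b_ub = np.array([opt + slack])

    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack(
            [np.concatenate([f_lo, r_lo]), np.concatenate([f_hi, r_hi])]
        ),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    if res.status == 2:
        raise SolverError(
            "pFBA stage 2 infeasible at relative tolerance "
            f"{relative_tolerance}; loosen the tolerance"
        )
    if res.status != 0:
        raise SolverError(f"pFBA stage-2 backend failure: {res.message}")
    v = res.x[:n] - res.x[n:]
    return FluxSolution(
        status="optimal",
        objective_value=opt,
        fluxes=dict(zip(rxn_ids, v)),
        objective_ids=stage1.objective_ids,
        feasibility_tolerance=tolerance,
        is_parsimonious=True,
    )


def knock_off(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Copy of the model with the reaction's bounds constrained to zero.

    All other constraints and the objective are kept unchanged, matching
    the knock-off protocol used for secretion reactions.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    knocked = model.copy()
    knocked.reactions[reaction_id].bounds = (0.0, 0.0)
    return knocked


def check_feasible(
    model: MetabolicModel,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> bool:
    """True iff the flux polytope (with optional bound overrides) is
    non-empty.  Deterministic; never raises for infeasibility."""
    probe = model
    if extra_bounds:
        probe = model.copy()
        for rid, (lo, hi) in extra_bounds.items():
            if rid not in probe.reactions:
                raise KeyError(f"unknown reaction {rid!r}")
            probe.reactions[rid].bounds = (lo, hi)
    S, _, _ = probe.stoichiometric_matrix()
    lb, ub = probe.bounds_arrays()
    res = linprog(
        np.zeros(S.shape[1]),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    return res.status == 0


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """``max |S.v|`` over metabolites for a stored solution (diagnostics)."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.flux(rid) for rid in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
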