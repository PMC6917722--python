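"""The LP engine against the brute-force vertex oracle and cobrapy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lumenfba as lf
from lumenfba.fba import steady_state_residual
from lumenfba.model import Metabolite, Reaction, build_model

from .conftest import to_cobra
from .oracle import oracle_optimum

ORACLE_TOL = 1e-9


def _parallel_paths_model():
    """A -> B through a direct reaction or a two-step detour: the optimum
    is degenerate, the parsimonious solution is not."""
    mets = [Metabolite(m, "c") for m in ("a_c", "x_c", "b_c")]
    rxns = [
        Reaction("SRC_a", {"a_c": 1}, 0, 5),
        Reaction("DIRECT", {"a_c": -1, "b_c": 1}, 0, 10),
        Reaction("DETOUR1", {"a_c": -1, "x_c": 1}, 0, 10),
        Reaction("DETOUR2", {"x_c": -1, "b_c": 1}, 0, 10),
        Reaction("SINK_b", {"b_c": -1}, 0, 10),
    ]
    return build_model("parallel", {"c": "c"}, mets, rxns, {"SINK_b": 1.0})


def _reversible_loop_model():
    """Small network with a reversible internal reaction and two exchanges."""
    mets = [Metabolite(m, "c") for m in ("a_c", "b_c")]
    rxns = [
        Reaction("EX_a", {"a_c": -1}, -4, 2),
        Reaction("AB", {"a_c": -1, "b_c": 1}, -10, 10),
        Reaction("EX_b", {"b_c": -1}, -1, 7),
    ]
    return build_model("revloop", {"c": "c"}, mets, rxns, {"EX_b": 1.0})


def _small_fixtures():
    return [
        lf.make_toy_host(),
        lf.make_toy_microbe(lf.FP_LIKE),
        lf.make_toy_microbe(lf.BT_LIKE),
        lf.make_toy_microbe(lf.NULL_SECRETOR),
        _parallel_paths_model(),
        _reversible_loop_model(),
    ]


@pytest.mark.parametrize("model", _small_fixtures(), ids=lambda m: m.id)
def test_fba_matches_vertex_enumeration(model):
    expected = oracle_optimum(model)
    sol = lf.solve_fba(model)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(expected, abs=ORACLE_TOL)


@pytest.mark.parametrize("model", _small_fixtures()[:4], ids=lambda m: m.id)
def test_minimization_matches_vertex_enumeration(model):
    expected = oracle_optimum(model, sense="min")
    sol = lf.solve_fba(model, sense="min")
    assert sol.objective_value == pytest.approx(expected, abs=ORACLE_TOL)


def test_toy_host_baseline_is_two(toy_host):
    # glucose bound 3 -> 6 acetyl-CoA -> 2 x 25-OH-D3
    assert lf.solve_fba(toy_host).objective_value == pytest.approx(2.0)


def test_all_bounds_zero_forces_zero_flux(toy_host):
    frozen = toy_host.copy()
    for rxn in frozen.reactions.values():
        rxn.bounds = (0.0, 0.0)
    sol = lf.solve_fba(frozen)
    assert sol.objective_value == pytest.approx(0.0)
    assert all(abs(v) <= ORACLE_TOL for v in sol.fluxes.values())


def test_steady_state_residual_within_tolerance(fp_comodel, fructan):
    dosed = lf.apply_prebiotic(fp_comodel, fructan, 1.0)
    for solver in (lf.solve_fba, lf.solve_pfba):
        sol = solver(dosed.model)
        assert steady_state_residual(dosed.model, sol) < 1e-6


# ---------------------------------------------------------------------------
# pFBA


def test_pfba_resolves_parallel_path_degeneracy():
    model = _parallel_paths_model()
    plain = lf.solve_fba(model)
    pars = lf.solve_pfba(model)
    assert pars.is_parsimonious
    assert pars.objective_value == pytest.approx(plain.objective_value)
    # both vertex optima: all-direct (sum |v| = 15) vs all-detour (20)
    assert sum(abs(v) for v in pars.fluxes.values()) == pytest.approx(15.0)
    assert pars.flux("DIRECT") == pytest.approx(5.0)
    assert pars.flux("DETOUR1") == pytest.approx(0.0)


def test_pfba_identity_on_unique_optimum(toy_host):
    plain = lf.solve_fba(toy_host)
    pars = lf.solve_pfba(toy_host)
    for rid in toy_host.reactions:
        assert pars.flux(rid) == pytest.approx(plain.flux(rid), abs=1e-7)


def test_pfba_zero_model_gives_zero_vector(toy_host):
    frozen = toy_host.copy()
    for rxn in frozen.reactions.values():
        rxn.bounds = (0.0, 0.0)
    sol = lf.solve_pfba(frozen)
    assert all(abs(v) <= 1e-9 for v in sol.fluxes.values())


def test_pfba_never_exceeds_fba_total_flux(fp_comodel, fructan):
    dosed = lf.apply_prebiotic(fp_comodel, fructan, 1.0)
    plain = lf.solve_fba(dosed.model)
    pars = lf.solve_pfba(dosed.model)
    assert sum(map(abs, pars.fluxes.values())) <= sum(
        map(abs, plain.fluxes.values())
    ) + 1e-6


# ---------------------------------------------------------------------------
# knock-off


def test_knock_off_zeroes_bounds_and_copies(toy_host):
    knocked = lf.knock_off(toy_host, "ACS")
    assert knocked.reactions["ACS"].bounds == (0.0, 0.0)
    assert toy_host.reactions["ACS"].bounds != (0.0, 0.0)


def test_knock_off_unknown_reaction_raises(toy_host):
    with pytest.raises(KeyError):
        lf.knock_off(toy_host, "NOPE")


def test_knock_off_objective_reaction_kills_objective(toy_host):
    sol = lf.solve_fba(lf.knock_off(toy_host, "EX_d25_s"))
    assert sol.objective_value == pytest.approx(0.0)


def test_knock_off_of_inactive_reaction_is_neutral(toy_host):
    already_zero = toy_host.copy()
    already_zero.reactions["LDH"].bounds = (0.0, 0.0)
    before = lf.solve_fba(already_zero).objective_value
    after = lf.solve_fba(lf.knock_off(already_zero, "LDH")).objective_value
    assert after == pytest.approx(before)


# ---------------------------------------------------------------------------
# feasibility


def test_host_on_glucose_is_feasible(toy_host):
    assert lf.check_feasible(toy_host)


def test_forced_uptake_without_consumer_is_infeasible(toy_host):
    model = toy_host.copy()
    # force 7-DHC "uptake" through its serum exchange: nothing consumes it
    assert not lf.check_feasible(model, {"EX_d25_s": (-1.0, -1.0)})


def test_minimum_growth_without_carbon_is_infeasible(fp_microbe):
    starved = fp_microbe.copy()
    for rxn in starved.exchanges:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    assert not lf.check_feasible(starved, {"BIOMASS": (0.01, 1000.0)})
    assert lf.check_feasible(starved)  # zero flux is still allowed


# ---------------------------------------------------------------------------
# monotonicity property


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    widen=st.floats(0.0, 5.0),
    rxn_index=st.integers(0, 11),
)
def test_relaxing_any_bound_never_decreases_the_optimum(widen, rxn_index):
    model = lf.make_toy_host()
    base = lf.solve_fba(model).objective_value
    rid = list(model.reactions)[rxn_index]
    relaxed = model.copy()
    rxn = relaxed.reactions[rid]
    rxn.bounds = (rxn.lower_bound - widen, rxn.upper_bound + widen)
    assert lf.solve_fba(relaxed).objective_value >= base - 1e-9


# ---------------------------------------------------------------------------
# independent solver cross-check (cobrapy/GLPK)


@pytest.mark.parametrize("dose", [0.0, 0.5, 1.0])
def test_comodel_optimum_matches_cobra(fp_comodel, fructan, dose, tmp_path):
    dosed = lf.apply_prebiotic(fp_comodel, fructan, dose)
    ours = lf.solve_fba(dosed.model).objective_value
    theirs = to_cobra(dosed.model, tmp_path).optimize().objective_value
    assert ours == pytest.approx(theirs, abs=1e-6)


def test_bt_comodel_optimum_matches_cobra(bt_comodel, fructan, tmp_path):
    dosed = lf.apply_prebiotic(bt_comodel, fructan, 1.0)
    ours = lf.solve_fba(dosed.model).objective_value
    theirs = to_cobra(dosed.model, tmp_path).optimize().objective_value
    assert ours == pytest.approx(theirs, abs=1e-6)
    assert ours == pytest.approx(11.0 / 3.0)
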