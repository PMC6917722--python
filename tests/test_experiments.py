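"""Dose response, profiling, knock-off scan, screening, flux modes,
subsystem fractions."""

import numpy as np
import pytest

import lumenfba as lf
from lumenfba.experiments import (
    extract_flux_modes,
    flux_modes_table,
    knockoff_table,
    profile_secretion_absorption,
    run_dose_response,
    run_knockoff_scan,
    screen_collection,
    subsystem_flux_change,
)

from .conftest import TOY_DOSES, to_cobra

COFACTOR_PATHWAY = ["H_LDH", "H_PDH", "H_PFL", "H_ACS", "H_TCA", "H_OXPHOS"]


# ---------------------------------------------------------------------------
# dose response


def test_fp_dose_response_doubles_at_top_dose(fp_comodel, fructan):
    result = run_dose_response(fp_comodel, fructan, TOY_DOSES)
    assert result.records["objective"].tolist() == pytest.approx([2.0, 3.0, 4.0])
    assert result.fold_change() == pytest.approx(2.0)


def test_capped_control_is_flat(fp_comodel, fructan):
    control = run_dose_response(fp_comodel, fructan, TOY_DOSES, control=True)
    assert control.records["objective"].tolist() == pytest.approx([2.0, 2.0, 2.0])
    assert control.control


def test_empty_dose_list_gives_empty_result(fp_comodel, fructan):
    result = run_dose_response(fp_comodel, fructan, [])
    assert len(result.records) == 0


def test_non_increasing_doses_rejected(fp_comodel, fructan):
    with pytest.raises(ValueError, match="increasing"):
        run_dose_response(fp_comodel, fructan, [0.0, 1.0, 1.0])


def test_unknown_tracked_reaction_rejected(fp_comodel, fructan):
    with pytest.raises(KeyError):
        run_dose_response(fp_comodel, fructan, TOY_DOSES,
                          tracked_reactions=("NOPE",))


def test_tracked_fluxes_follow_the_7dhc_chain(fp_comodel, fructan):
    result = run_dose_response(
        fp_comodel, fructan, TOY_DOSES, tracked_reactions=("H_DHCS", "H_D25H")
    )
    # 7-DHC synthesis and 25-OH-D3 secretion move together
    assert result.records["H_DHCS"].tolist() == pytest.approx([2.0, 3.0, 4.0])
    assert result.records["H_D25H"].tolist() == pytest.approx([2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# secretion/absorption profile


def _profile(co, fructan, dose):
    sol = lf.solve_pfba(lf.apply_prebiotic(co, fructan, dose).model)
    return profile_secretion_absorption(sol, co).set_index("metabolite")


def test_fp_profile_lactate_dominates(fp_comodel, fructan):
    prof = _profile(fp_comodel, fructan, 1.0)
    assert prof.loc["lac", "microbe_secretion"] == pytest.approx(4.0)
    assert prof.loc["ac", "microbe_secretion"] == pytest.approx(2.0)
    assert prof.loc["pyr", "microbe_secretion"] == pytest.approx(0.0)
    # absorption equals secretion: no efflux incentive
    np.testing.assert_allclose(
        prof["host_absorption"], prof["microbe_secretion"], atol=1e-7
    )
    assert prof["balance_residual"].abs().max() < 1e-7


def test_bt_profile_swaps_lactate_for_pyruvate(bt_comodel, fructan):
    prof = _profile(bt_comodel, fructan, 1.0)
    assert prof.loc["pyr", "microbe_secretion"] == pytest.approx(3.0)
    assert prof.loc["lac", "microbe_secretion"] == pytest.approx(0.0)


def test_zero_dose_profile_is_all_zero(fp_comodel, fructan):
    prof = _profile(fp_comodel, fructan, 0.0)
    np.testing.assert_allclose(prof["microbe_secretion"], 0.0, atol=1e-9)
    np.testing.assert_allclose(prof["host_absorption"], 0.0, atol=1e-9)


def test_profile_requires_optimal_solution(fp_comodel):
    from lumenfba.fba import FluxSolution

    with pytest.raises(ValueError, match="optimal"):
        profile_secretion_absorption(
            FluxSolution(status="infeasible", objective_value=None), fp_comodel
        )


# ---------------------------------------------------------------------------
# knock-off scan


def test_lactate_knockoff_reduction(fp_comodel, fructan):
    results = run_knockoff_scan(fp_comodel, ["H_UPT_lac"], fructan, 1.0)
    (res,) = results
    assert res.objective_before == pytest.approx(4.0)
    assert res.objective_after == pytest.approx(8.0 / 3.0)
    assert res.percent_reduction == pytest.approx(100 * (4 - 8 / 3) / 4)
    # the remaining acetate route readjusts, it does not vanish
    before, after = res.flux_deltas["H_UPT_ac"]
    assert before == pytest.approx(2.0) and after == pytest.approx(2.0)


def test_knocking_zero_flux_route_changes_nothing(fp_comodel, fructan):
    (res,) = run_knockoff_scan(fp_comodel, ["H_UPT_pyr"], fructan, 1.0)
    assert res.percent_reduction == pytest.approx(0.0)


def test_knocking_all_acid_routes_restores_baseline(fp_comodel, fructan):
    dosed = lf.apply_prebiotic(fp_comodel, fructan, 1.0)
    model = dosed.model
    for rid in ("H_UPT_lac", "H_UPT_ac", "H_UPT_pyr"):
        model = lf.knock_off(model, rid)
    assert lf.solve_fba(model).objective_value == pytest.approx(2.0)


def test_knockoff_never_increases_objective(fp_comodel, fructan):
    results = run_knockoff_scan(fp_comodel, None, fructan, 1.0)
    table = knockoff_table(results)
    assert (table["objective_after"] <= table["objective_before"] + 1e-9).all()


# ---------------------------------------------------------------------------
# collection screen


def _screen(models, fructan, western_diet, **kw):
    return screen_collection(models, [fructan], TOY_DOSES, diet=western_diet, **kw)


def test_screen_recovers_organism_specific_secretion(
    fp_microbe, bt_microbe, null_microbe, fructan, western_diet
):
    result = _screen([fp_microbe, bt_microbe, null_microbe], fructan, western_diet)
    s = result.summary.set_index("organism")
    fp, bt, null = (s.loc[m.id] for m in (fp_microbe, bt_microbe, null_microbe))
    assert fp["utilizes"] and bt["utilizes"] and not null["utilizes"]
    top = TOY_DOSES[-1]
    assert fp["max_lac"] == pytest.approx(4.0 * top)
    assert fp["max_pyr"] == pytest.approx(0.0)
    assert bt["max_pyr"] == pytest.approx(3.0 * top)
    assert bt["max_lac"] == pytest.approx(0.0)
    assert null[["max_ac", "max_lac", "max_pyr"]].tolist() == pytest.approx([0, 0, 0])


def test_screen_profiles_are_monotone_in_dose(fp_microbe, fructan, western_diet):
    result = _screen([fp_microbe], fructan, western_diet)
    lac = result.profiles.query("metabolite == 'lac'").sort_values("dose")
    assert lac["flux"].is_monotonic_increasing


def test_empty_dose_grid_rejected(fp_microbe, fructan, western_diet):
    with pytest.raises(ValueError, match="non-empty"):
        screen_collection([fp_microbe], [fructan], [], diet=western_diet)


def test_organism_without_prebiotic_exchange_is_non_utilizer(
    fp_microbe, fructan, western_diet
):
    no_fru = fp_microbe.copy()
    del no_fru.reactions["EX_fru_e"]
    del no_fru.reactions["FERM"]
    del no_fru.reactions["ANA_FRU"]
    del no_fru.metabolites["fru_e"]
    no_fru.id = "no_fructan_exchange"
    result = _screen([no_fru], fructan, western_diet)
    row = result.summary.iloc[0]
    assert not row["utilizes"]
    flat = result.profiles.groupby("metabolite")["flux"].nunique()
    assert (flat == 1).all()  # profile constant over doses


def test_unreadable_model_flags_row_and_continues(
    fp_microbe, fructan, western_diet, tmp_path
):
    bad = tmp_path / "broken.json"
    bad.write_text("{not json")
    result = _screen([bad, fp_microbe], fructan, western_diet)
    assert len(result.summary) == 2
    assert result.summary.iloc[0]["error"] != ""
    assert result.summary.iloc[1]["utilizes"]


def test_screen_rerun_is_byte_identical(fructan, western_diet, tmp_path):
    models = lf.make_toy_collection(6, seed=5)
    paths = []
    for a, b in zip(
        (tmp_path / "a.tsv", tmp_path / "a_heat.tsv"),
        (tmp_path / "b.tsv", tmp_path / "b_heat.tsv"),
    ):
        paths.append((a, b))
    r1 = _screen(models, fructan, western_diet)
    r2 = _screen(lf.make_toy_collection(6, seed=5), fructan, western_diet)
    r1.to_tsv(paths[0][0]); r2.to_tsv(paths[0][1])
    r1.to_heatmap_tsv(paths[1][0]); r2.to_heatmap_tsv(paths[1][1])
    for a, b in paths:
        assert a.read_bytes() == b.read_bytes()


def test_growth_coupled_mode_reports_fermentation_products(
    fp_microbe, fructan, western_diet
):
    result = _screen([fp_microbe], fructan, western_diet, mode="growth-coupled")
    row = result.summary.iloc[0]
    # at max growth the fructan feeds biomass, not fermentation, so the
    # growth-coupled secretion stays below the secretion potential
    assert row["max_lac"] <= 4.0 * TOY_DOSES[-1] + 1e-9


# ---------------------------------------------------------------------------
# flux modes


def test_flux_modes_activity_flags(fp_comodel, fructan):
    modes = extract_flux_modes(
        fp_comodel, fructan, [0.0, 1.0], ["H_LDH", "H_ACS", "H_PDHe", "MISSING"]
    )
    low, high = modes
    assert low.absent == ["MISSING"] and high.absent == ["MISSING"]
    assert not any(low.active.values())  # nothing prebiotic-fed at dose 0
    assert high.active["H_LDH"] and high.active["H_ACS"]
    assert not high.active["H_PDHe"]  # FP-like secretes no pyruvate


def test_huge_activity_tolerance_marks_everything_inactive(fp_comodel, fructan):
    (mode,) = extract_flux_modes(
        fp_comodel, fructan, [1.0], ["H_LDH", "H_ACS"], activity_tolerance=1e6
    )
    assert not any(mode.active.values())


def test_bt_lactate_route_is_never_active(bt_comodel, fructan):
    modes = extract_flux_modes(bt_comodel, fructan, [0.0, 0.5, 1.0], ["H_LDH"])
    assert not any(m.active["H_LDH"] for m in modes)


def test_cofactor_family_switches_acetylcoa_route_with_dose(
    cofactor_comodel, fructan
):
    """Low dose: the NADH-yielding decarboxylase carries pyruvate flux and
    the formate route is off.  High dose: respiration saturates, flux
    reroutes through the formate-releasing route plus ATP-consuming
    acetate activation."""
    low, high = extract_flux_modes(
        cofactor_comodel, fructan, [0.25, 2.5], COFACTOR_PATHWAY
    )
    assert low.active["H_PDH"] and not low.active["H_PFL"]
    assert high.active["H_PFL"] and not high.active["H_PDH"]
    assert high.active["H_ACS"]
    # respiration pinned at its capacity at the high dose
    assert high.fluxes["H_OXPHOS"] == pytest.approx(10.0)


def test_cofactor_modes_match_cobra_pfba(cofactor_comodel, fructan, tmp_path):
    """Independent pFBA route: cobrapy/GLPK agrees on the optimum and the
    parsimonious total flux at each dose."""
    cobra = pytest.importorskip("cobra")
    for dose in (0.25, 2.5):
        dosed = lf.apply_prebiotic(cofactor_comodel, fructan, dose)
        ours = lf.solve_pfba(dosed.model)
        cm = to_cobra(dosed.model, tmp_path)
        theirs = cobra.flux_analysis.pfba(cm)
        objective = sum(
            coeff * theirs.fluxes[rid] for rid, coeff in dosed.model.objective.items()
        )
        assert ours.objective_value == pytest.approx(objective, abs=1e-6)
        assert sum(map(abs, ours.fluxes.values())) == pytest.approx(
            theirs.fluxes.abs().sum(), abs=1e-5
        )


# ---------------------------------------------------------------------------
# subsystem flux-change fractions


def test_toy_subsystem_fractions(fp_comodel, fructan):
    report = subsystem_flux_change(fp_comodel, fructan, 1.0)
    assert report.fraction("Glycolysis") == pytest.approx(0.0)
    assert report.fraction("Acetyl-CoA synthesis") == pytest.approx(2.0 / 3.0)
    assert ((report.table["fraction"] >= 0) & (report.table["fraction"] <= 1)).all()
    assert (report.table["n_changed"] <= report.table["n_total"]).all()


def test_zero_dose_changes_nothing(fp_comodel, fructan):
    report = subsystem_flux_change(fp_comodel, fructan, 0.0)
    assert report.selected == []
    assert (report.table["fraction"] == 0.0).all()


def test_fully_changed_subsystem_reaches_one(fp_comodel, fructan):
    report = subsystem_flux_change(fp_comodel, fructan, 1.0)
    assert report.fraction("Cholesterol biosynthesis") == pytest.approx(1.0)


def test_unlabelled_reactions_fall_into_one_bucket(western_diet, fructan):
    co = lf.make_toy_comodel()
    for rid, rxn in co.model.reactions.items():
        if rid.startswith("H_"):
            rxn.subsystem = ""
    co = lf.apply_diet(co, western_diet)
    report = subsystem_flux_change(co, fructan, 1.0)
    assert report.table["subsystem"].tolist() == ["unlabelled"]
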