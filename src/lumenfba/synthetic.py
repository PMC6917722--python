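"""Fully specified toy fixtures carrying the structure the analysis assumes.

The toy host condenses the route from absorbed microbial fermentation
products to 25-hydroxyvitamin-D3 secretion: glucose and the three organic
acids (acetate, lactate, pyruvate) feed a cytosolic acetyl-CoA pool, three
acetyl-CoA lump into one 7-dehydrocholesterol (7-DHC, standing in for the
acetoacetyl-CoA/HMG-CoA chain), and 7-DHC is hydroxylated and secreted to
serum, which is the maximized objective.  Toy microbes ferment a fructan to
an organism-specific acid mix and grow on either the fructan or a peptone
(amino-acid) substrate, so a minimum-growth requirement stays satisfiable
even without supplementation.

Two fixture families exist.  The default family omits cofactors so every
expected optimum is hand-derivable (glucose bound 3 gives a baseline
objective of 2.0; a fructan bound of 1 with the FP-like fermenter gives
4.0).  The cofactor-aware family threads ATP and NADH through the same
routes (acetate activation costs ATP, the pyruvate decarboxylase route
yields NADH, respiration is capacity-bounded), which makes the optimal
acetyl-CoA route switch with prebiotic dose; its expected flux modes are
derived by an independent solver in the tests, not by hand.

All generation is deterministic; the collection generator is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comodel import CoMetabolismModel, JoinPolicy, merge_into_comodel
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, build_model

__all__ = [
    "ToyMicrobeProfile",
    "FP_LIKE",
    "BT_LIKE",
    "NULL_SECRETOR",
    "make_toy_host",
    "make_cofactor_host",
    "make_toy_microbe",
    "make_toy_comodel",
    "make_toy_collection",
    "TOY_JOIN_POLICY",
]


@dataclass(frozen=True)
class ToyMicrobeProfile:
    """Fermentation stoichiometry fructan -> a*acetate + l*lactate +
    p*pyruvate, plus a biomass yield per fructan."""

    name: str
    acetate: float
    lactate: float
    pyruvate: float
    biomass_yield: float = 0.1

    def __post_init__(self) -> None:
        for v in (self.acetate, self.lactate, self.pyruvate, self.biomass_yield):
            if v < 0:
                raise ValueError(f"profile {self.name!r}: coefficients must be >= 0")


#: F. prausnitzii-like archetype: lactate-dominant fermentation
FP_LIKE = ToyMicrobeProfile("fp-like", acetate=2.0, lactate=4.0, pyruvate=0.0)
#: B. thetaiotamicron-like archetype: pyruvate instead of lactate
BT_LIKE = ToyMicrobeProfile("bt-like", acetate=2.0, lactate=0.0, pyruvate=3.0)
#: ferments nothing, grows on peptone only
NULL_SECRETOR = ToyMicrobeProfile(
    "null-secretor", acetate=0.0, lactate=0.0, pyruvate=0.0, biomass_yield=0.0
)

_ARCHETYPES = (FP_LIKE, BT_LIKE, NULL_SECRETOR)

#: join policy used by every toy co-model: the host epithelium absorbs the
#: three fermentation acids from the lumen even though the standalone host
#: model keeps those exchanges closed to uptake.
TOY_JOIN_POLICY = JoinPolicy(host_open_uptake=frozenset({"lac", "ac", "pyr"}))


def make_toy_host(glucose_bound: float = 3.0) -> MetabolicModel:
    """12-reaction host: glucose -> 2 acetyl-CoA, acid salvage routes,
    3 acetyl-CoA -> 7-DHC -> 25-OH-D3 -> serum sink (the objective)."""
    mets = [
        Metabolite("glc_e", "e", "glucose"),
        Metabolite("lac_e", "e", "lactate"),
        Metabolite("ac_e", "e", "acetate"),
        Metabolite("pyr_e", "e", "pyruvate"),
        Metabolite("pyr_c", "c", "pyruvate (cytosol)"),
        Metabolite("accoa_c", "c", "acetyl-CoA"),
        Metabolite("dhc_c", "c", "7-dehydrocholesterol"),
        Metabolite("d25_s", "s", "25-hydroxyvitamin D3"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1}, -glucose_bound, 0, subsystem="Exchange"),
        Reaction("GLY", {"glc_e": -1, "accoa_c": 2}, 0, DEFAULT_BOUND,
                 name="glycolysis (lumped)", subsystem="Glycolysis"),
        Reaction("EX_lac_e", {"lac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("LDH", {"lac_e": -1, "pyr_c": 1}, 0, DEFAULT_BOUND,
                 name="lactate dehydrogenase", subsystem="Pyruvate metabolism"),
        Reaction("EX_ac_e", {"ac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("ACS", {"ac_e": -1, "accoa_c": 1}, 0, DEFAULT_BOUND,
                 name="acetyl-CoA synthetase", subsystem="Acetyl-CoA synthesis"),
        Reaction("EX_pyr_e", {"pyr_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("PDHe", {"pyr_e": -1, "accoa_c": 1}, 0, DEFAULT_BOUND,
                 name="pyruvate dehydrogenase (extracellular pool)",
                 subsystem="Acetyl-CoA synthesis"),
        Reaction("PDHc", {"pyr_c": -1, "accoa_c": 1}, 0, DEFAULT_BOUND,
                 name="pyruvate dehydrogenase (cytosolic pool)",
                 subsystem="Acetyl-CoA synthesis"),
        Reaction("DHCS", {"accoa_c": -3, "dhc_c": 1}, 0, DEFAULT_BOUND,
                 name="7-DHC synthesis (lumped HMG-CoA chain)",
                 subsystem="Cholesterol biosynthesis"),
        Reaction("D25H", {"dhc_c": -1, "d25_s": 1}, 0, DEFAULT_BOUND,
                 name="25-hydroxylation", subsystem="Vitamin D metabolism"),
        Reaction("EX_d25_s", {"d25_s": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
    ]
    return build_model(
        "toy_host",
        {"e": "extracellular", "c": "cytosol", "s": "serum"},
        mets,
        rxns,
        {"EX_d25_s": 1.0},
    )


def make_cofactor_host(
    glucose_bound: float = 3.0,
    glycolysis_atp_yield: float = 1.0,
    respiration_cap: float = 10.0,
) -> MetabolicModel:
    """Cofactor-aware host variant for dose-dependent flux-mode switching.

    Acetate activation costs ATP, the decarboxylase route to acetyl-CoA
    yields NADH, the lipoamide-style route dumps formate instead, and
    NADH re-oxidation (the only ATP source beyond glycolysis) is capped at
    ``respiration_cap``.  At low prebiotic dose ATP is scarce, so pyruvate
    flows through the NADH-yielding decarboxylase; at high dose NADH
    saturates respiration and flux reroutes through the formate-releasing
    route plus ATP-consuming acetate activation.
    """
    mets = [
        Metabolite("glc_e", "e", "glucose"),
        Metabolite("lac_e", "e", "lactate"),
        Metabolite("ac_e", "e", "acetate"),
        Metabolite("pyr_e", "e", "pyruvate"),
        Metabolite("pyr_c", "c", "pyruvate (cytosol)"),
        Metabolite("accoa_c", "c", "acetyl-CoA"),
        Metabolite("atp_c", "c", "ATP"),
        Metabolite("nadh_c", "c", "NADH"),
        Metabolite("for_c", "c", "formate"),
        Metabolite("dhc_c", "c", "7-dehydrocholesterol"),
        Metabolite("d25_s", "s", "25-hydroxyvitamin D3"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1}, -glucose_bound, 0, subsystem="Exchange"),
        Reaction("GLY", {"glc_e": -1, "accoa_c": 2, "atp_c": glycolysis_atp_yield},
                 0, DEFAULT_BOUND, name="glycolysis (lumped)",
                 subsystem="Glycolysis"),
        Reaction("EX_lac_e", {"lac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("LDH", {"lac_e": -1, "pyr_c": 1, "nadh_c": 1}, 0, DEFAULT_BOUND,
                 name="lactate dehydrogenase", subsystem="Pyruvate metabolism"),
        Reaction("EX_ac_e", {"ac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("ACS", {"ac_e": -1, "atp_c": -1, "accoa_c": 1}, 0, DEFAULT_BOUND,
                 name="acetyl-CoA synthetase (ATP-consuming)",
                 subsystem="Acetyl-CoA synthesis"),
        Reaction("EX_pyr_e", {"pyr_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("PYRt", {"pyr_e": -1, "pyr_c": 1}, 0, DEFAULT_BOUND,
                 name="pyruvate transport", subsystem="Transport"),
        Reaction("PDH", {"pyr_c": -1, "accoa_c": 1, "nadh_c": 1}, 0, DEFAULT_BOUND,
                 name="pyruvate decarboxylase route (NADH-yielding)",
                 subsystem="Acetyl-CoA synthesis"),
        Reaction("PFL", {"pyr_c": -1, "accoa_c": 1, "for_c": 1}, 0, DEFAULT_BOUND,
                 name="acetyldihydrolipoamide-style route (formate-releasing)",
                 subsystem="Acetyl-CoA synthesis"),
        Reaction("DM_for_c", {"for_c": -1}, 0, DEFAULT_BOUND,
                 name="formate drain", subsystem="Exchange"),
        Reaction("TCA", {"accoa_c": -1, "nadh_c": 2}, 0, DEFAULT_BOUND,
                 name="acetyl-CoA oxidation (lumped)",
                 subsystem="Citric acid cycle"),
        Reaction("OXPHOS", {"nadh_c": -1, "atp_c": 2}, 0, respiration_cap,
                 name="NADH re-oxidation", subsystem="Oxidative phosphorylation"),
        Reaction("ATPM", {"atp_c": -1}, 0, DEFAULT_BOUND,
                 name="ATP maintenance drain", subsystem="Energy maintenance"),
        Reaction("DHCS", {"accoa_c": -3, "atp_c": -3, "dhc_c": 1}, 0, DEFAULT_BOUND,
                 name="7-DHC synthesis (lumped, ATP-consuming)",
                 subsystem="Cholesterol biosynthesis"),
        Reaction("D25H", {"dhc_c": -1, "d25_s": 1}, 0, DEFAULT_BOUND,
                 name="25-hydroxylation", subsystem="Vitamin D metabolism"),
        Reaction("EX_d25_s", {"d25_s": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
    ]
    return build_model(
        "toy_host_cofactor",
        {"e": "extracellular", "c": "cytosol", "s": "serum"},
        mets,
        rxns,
        {"EX_d25_s": 1.0},
    )


def make_toy_microbe(profile: ToyMicrobeProfile) -> MetabolicModel:
    """Toy fermenter: fructan uptake, one fermentation reaction per the
    profile, secretion exchanges for the three acids, and a biomass drain
    fed by either fructan or a peptone substrate."""
    mets = [
        Metabolite("fru_e", "e", "fructan"),
        Metabolite("lac_e", "e", "lactate"),
        Metabolite("ac_e", "e", "acetate"),
        Metabolite("pyr_e", "e", "pyruvate"),
        Metabolite("aa_e", "e", "peptone (amino acids)"),
        Metabolite("biom_c", "c", "biomass precursor"),
    ]
    rxns = [
        Reaction("EX_fru_e", {"fru_e": -1}, -DEFAULT_BOUND, 0, subsystem="Exchange"),
        Reaction("EX_lac_e", {"lac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("EX_ac_e", {"ac_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("EX_pyr_e", {"pyr_e": -1}, 0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("EX_aa_e", {"aa_e": -1}, -DEFAULT_BOUND, 0, subsystem="Exchange"),
        Reaction("ANA_AA", {"aa_e": -1, "biom_c": 1}, 0, DEFAULT_BOUND,
                 name="anabolism from peptone", subsystem="Biomass"),
        Reaction("BIOMASS", {"biom_c": -1}, 0, DEFAULT_BOUND,
                 name="biomass", subsystem="Biomass"),
    ]
    products = {
        "ac_e": profile.acetate,
        "lac_e": profile.lactate,
        "pyr_e": profile.pyruvate,
    }
    products = {m: c for m, c in products.items() if c > 0}
    if products:
        rxns.insert(
            1,
            Reaction("FERM", {"fru_e": -1, **products}, 0, DEFAULT_BOUND,
                     name="fructan fermentation", subsystem="Fermentation"),
        )
    if profile.biomass_yield > 0:
        rxns.append(
            Reaction("ANA_FRU", {"fru_e": -1, "biom_c": profile.biomass_yield},
                     0, DEFAULT_BOUND, name="anabolism from fructan",
                     subsystem="Biomass"),
        )
    model = build_model(
        f"toy_microbe_{profile.name}",
        {"e": "extracellular", "c": "cytosol"},
        mets,
        rxns,
        {"BIOMASS": 1.0},
    )
    return model


def make_toy_comodel(
    host_params: dict | None = None,
    profile: ToyMicrobeProfile = FP_LIKE,
    cofactor: bool = False,
    policy: JoinPolicy | None = None,
) -> CoMetabolismModel:
    """Merged toy fixture with a lumen: host + one fermenter."""
    host_params = host_params or {}
    host = make_cofactor_host(**host_params) if cofactor else make_toy_host(**host_params)
    microbe = make_toy_microbe(profile)
    return merge_into_comodel(host, microbe, policy or TOY_JOIN_POLICY)


def make_toy_collection(n: int, seed: int) -> list[MetabolicModel]:
    """``n`` toy microbes with archetypes and growth yields drawn from a
    seeded generator; identical seed, identical collection."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        arche = _ARCHETYPES[rng.choice(len(_ARCHETYPES), p=[0.4, 0.4, 0.2])]
        yield_ = float(rng.uniform(0.02, 0.2)) if arche is not NULL_SECRETOR else 0.0
        profile = ToyMicrobeProfile(
            name=f"{arche.name}_{i:03d}",
            acetate=arche.acetate,
            lactate=arche.lactate,
            pyruvate=arche.pyruvate,
            biomass_yield=yield_,
        )
        models.append(make_toy_microbe(profile))
    return models
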