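# Methods

## The co-metabolism construction

A co-metabolism model couples one host and one microbial genome-scale
network through a shared lumen compartment.  Each source model is kept
intact under an id prefix (`H_`, `M_`); every boundary (exchange)
reaction whose metabolite sits in a shared compartment (default: the
extracellular compartment `e`, matched across organisms by the metabolite
id with its compartment suffix stripped) is rewritten into directed lumen
transports:

* uptake, lumen → organism, capacity equal to the organism's original
  uptake bound (`-lb` of the exchange);
* secretion, organism → lumen, capacity equal to the original secretion
  bound (`ub`).

Inheriting the source bounds preserves each organism's published uptake
limits; the directed split keeps the four transport classes disjoint, so
secretion caps and knock-offs are single-bound edits.  Every lumen
metabolite gets exactly one boundary exchange (diet inflow / lumen
efflux), and a structural validator checks mass-exchange closure: a lumen
metabolite can only be touched by registered transports and its own
exchange, so diet inflow can leave solely via host uptake, microbe
uptake, or efflux.

One deliberate asymmetry: a `JoinPolicy.host_open_uptake` list creates
host uptake transports (at default capacity) for metabolites whose
standalone host exchange is closed to uptake.  The standalone host
fixture absorbs no organic acids — its baseline is then fully determined
by its glucose supply — but epithelial absorption of microbial
fermentation acids is precisely the coupling the co-model exists to add,
so the toy co-model opens lactate, acetate and pyruvate on the host side.

## The FBA problem and its refinement

`solve_fba` maximizes `c·v` subject to `S·v = 0` and `lb ≤ v ≤ ub`,
via HiGHS (scipy.optimize.linprog) with fixed settings; there is no
randomness anywhere in the pipeline, hence no seeds outside the synthetic
collection generator.  The objective models vitamin-D3 deficiency:
a deficient system is assumed to direct its network toward synthesizing
what it lacks, so the host's 25-hydroxyvitamin-D3 secretion reaction is
maximized and 7-DHC synthesis tracked alongside.

Plain FBA optima are degenerate in the flux vector, so every reported
flux table uses parsimonious FBA: a second LP minimizing `Σ|v|`
(linearized by splitting each flux into non-negative forward/reverse
parts) with the stage-1 objective held within a relative tolerance of
1e-9.  Feasibility/optimality tolerance is 1e-9 throughout.  Knock-off
sets a reaction's bounds to `(0, 0)` and leaves everything else
untouched.

## Conditions: diet and prebiotic dose

A diet is a named map of diet-exchange bounds; applying it closes uptake
on every unlisted lumen exchange (secretion stays open), so re-application
is idempotent.  A prebiotic is a component list (exchange id, mass
fraction, molar mass in g/mmol) with a dose-amortization horizon.  A dose
of `d` grams becomes per-component bounds `b_i = d·w_i/M_i/T` scaled by a
per-gDW constant (default 1), applied as `(-b_i, 0)`: uptake *allowed up
to* the dose, never forced.  Forced uptake could make the system
infeasible and would destroy the monotone, saturating dose response this
reading guarantees (adding allowance never removes feasible points, so
the optimum is non-decreasing in dose).

Defaults that matter and why:

* scFOS composition: equal mass thirds of GF2/GF3/GF4 with average
  formula weights 0.50444/0.66658/0.82872 g/mmol (a GF(n) chain weighs
  180.156 + 162.141·n g/mol); inulin is treated as a DP-10 polymer.
  Composition and masses are preset-file overridable.
* Horizon 24 h, per-gDW scale 1.0.  These two constants dominate any
  absolute-flux comparison between model collections, which is why fold
  changes — not absolute fluxes — are the robust outputs.
* Minimum microbial growth 0.01 flux units, enforced as a lower bound on
  the microbe's biomass reaction after merging (whether the original
  analyses growth-coupled the microbe is not documented; this package
  makes the choice explicit and configurable, `min_biomass=0`
  disables it).
* Control condition: every microbe secretion transport capped at 0 (a
  `"viability"` policy instead picks the smallest feasible cap from a
  grid).  Under the toy diet the microbe stays viable at cap 0 because
  it can grow on the peptone substrate.

## Experiments

* **Dose response** — strictly increasing dose grid, pFBA per dose,
  objective plus tracked fluxes; infeasible points are recorded and
  skipped.  Default grid: 21 points over 0–10 g.
* **Secretion/absorption profile** — net microbe secretion and host
  absorption per lumen metabolite (signed positive), with the lumen
  balance residual reported per row.
* **Knock-off scan** — one knock-off and re-solve per candidate against
  a common baseline; candidates default to the host uptake transports
  (see "fixture families" for why), and flux readjustments of the other
  routes are recorded.
* **Collection screen** — per organism and prebiotic: `utilizes` =
  (component exchange present) AND (max growth at top dose exceeds
  baseline by rel. 1e-6); per metabolite and dose either the direct
  maximum of the secretion exchange (`potential`, the default — it
  matches a max-flux-over-range heatmap and needs no growth assumption)
  or the pFBA secretion at maximum growth (`growth-coupled`).  Both are
  implemented because the choice is genuinely open.  Rows stream one
  organism at a time; unreadable files flag their row and screening
  continues.
* **Flux modes** — pFBA fluxes through a named pathway per dose with an
  activity flag at |v| ≥ 1e-6.
* **Subsystem flux change** — per internal host reaction,
  Δ% = 100·|v_supp − v_base| / max(|v_base|, ε) with ε = 1e-9; reactions
  with absolute change above 1e-6 count as changed, zero-to-nonzero
  reactions rank above every finite Δ%.  The top 90% of changed reactions
  (count-based, `ceil`, deterministic (−Δ%, id) ordering) are retained
  and each subsystem scores retained/total.  "Top 90%" could also be read
  as a percentile threshold on Δ%; the count reading is used and the cut
  is configurable.

## Synthetic fixture families

The default toy family is built to be hand-solvable, which fixes its
study conditions: host glucose uptake 3 (baseline objective exactly 2.0:
3 glucose → 6 acetyl-CoA → 2 × 7-DHC → 25-OH-D3), fermentation
stoichiometries fructan → 2 acetate + 4 lactate (FP-like) and
fructan → 2 acetate + 3 pyruvate (BT-like), a null secretor, biomass
yield 0.1 per fructan, and a peptone growth channel (diet bound 1) that
keeps a 0.01 minimum growth satisfiable at dose 0 and under secretion
caps.  The toy prebiotic maps d grams to a fructan bound of d.  Cofactors
are deliberately omitted so every expected optimum is reproducible by
brute-force vertex enumeration of the flux polytope (the test-suite
oracle, exact for ≤15-reaction models).

Because the toy fermenter is a single fixed-stoichiometry reaction, it
has none of the internal rerouting flexibility of a genome-scale
reconstruction: blocking its lactate secretion transport stalls
fermentation entirely rather than diverting carbon.  Severing the
lactate route at the host uptake transport instead (lactate then leaves
via lumen efflux) reproduces the intended partial effect — objective
4.0 → 8/3 — which is why the knock-off scan defaults to host-side
candidates.  On genome-scale models, knocking the microbe's secretion
exchange is the natural equivalent.

The cofactor-aware family adds ATP/NADH/formate: glycolysis yields 1 ATP
per glucose, the decarboxylase route to acetyl-CoA yields NADH, an
alternative acetyldihydrolipoamide-style route releases formate, acetate
activation and 7-DHC synthesis cost ATP, acetyl-CoA can be burned to
NADH, and NADH re-oxidation (the only other ATP source) is capped at 10.
This produces the dose-dependent mode switch the family exists to
exercise: at low dose pyruvate flows through the NADH-yielding route; at
high dose respiration saturates, that route shuts off, and flux reroutes
through the formate-releasing route plus ATP-consuming acetate
activation, with the objective saturating at the respiratory cap.  Its
expected flux modes are asserted against an independent pFBA
implementation (cobrapy/GLPK), not hand values.

The seeded collection generator draws archetypes
(FP-like/BT-like/null, probabilities 0.4/0.4/0.2) and growth yields
(uniform 0.02–0.2) from `numpy.random.default_rng(seed)`; identical
seeds give byte-identical model files.

What passing on these fixtures does **not** show: realistic
gram-to-flux calibration, genome-scale degeneracy structure, multi-organism
communities, or regulatory/kinetic effects (plain FBA carries no
regulation, concentrations, or time scales).  Absolute numbers on real
VMH/AGORA-scale models additionally depend on the diet table and the
prebiotic calibration supplied by the user.

## Numerical choices and degenerate inputs

LP tolerances 1e-9; pFBA stage-2 relative tolerance 1e-9; lumen balance
and steady state verified at 1e-6 in tests (solver feasibility is far
tighter, the slack absorbs accumulation over summed transports).
Knock-off of an already-zero reaction is a no-op; percent reduction is
defined as 0 when the baseline objective is ≤ 0; models without
subsystem labels report a single "unlabelled" subsystem; a prebiotic
component absent from a model is created as a closed lumen exchange
(co-models, with a warning) or skipped (standalone screening, reflected
in `utilizes`).

## Problem sizes

All bundled analyses run on 12–35-reaction networks and a 50-model
collection over 3–21-point dose grids — the scales at which every
expected value is independently checkable (vertex enumeration, hand LP
arithmetic, or a second solver stack).  The same code paths take
genome-scale SBML-FBC/COBRA-JSON input unchanged.
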