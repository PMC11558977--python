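# Methods

## The enzyme-constrained model

The core object is a stoichiometric model to which one linear row is added.
Construction has three structural steps, applied in order:

1. **Direction splitting.** Every reaction with a negative lower bound is
   replaced by a forward copy (bounds `[0, ub]`) and a reverse copy
   `<id>_reverse` with negated stoichiometry and bounds `[0, -lb]`. Each
   direction can then carry its own enzyme cost, and net fluxes are
   recovered as forward minus reverse.
2. **Isozyme expansion.** A gene rule is parsed into disjunctive normal
   form (case-insensitive `and`/`or`, parentheses honoured, expansion capped
   at 64 conjuncts); a reaction with k conjuncts becomes copies
   `<id>_num1 … <id>_numk`, each with a single `and`-complex, identical
   stoichiometry and bounds. Both transforms are idempotent and preserve
   FBA optima; a `SplitMap` records the composition of the two.
3. **Pool attachment.** Each catalysed reaction gets an enzyme entry —
   complex composition (gene, subunit count, subunit MW), assembled MW
   = Σ count·MW, kcat (s⁻¹) and saturation σ — and contributes
   `v·MW/(σ·kcat·3600)` to a single row bounded by `ptot·f`. kcat is stored
   in s⁻¹ and converted to h⁻¹ inside the coefficient so that
   flux (mmol/gDW/h) × MW (g/mmol) / kcat (h⁻¹) is g enzyme per gDW.
   Reactions without enzyme data (or with an empty gene rule) simply carry
   coefficient zero, so missing coverage relaxes rather than corrupts the
   model. kcat records are keyed by post-split id with a fallback to the
   original id, so forward/reverse and isozyme copies are independently
   parameterizable but a single record covers all copies by default.

Key parameters and defaults: `ptot = 0.4653` g protein/gDW, `f = 0.55`
(enzyme mass fraction, estimated from proteomics as the abundance-weighted
MW ratio of model proteins to the whole proteome; exposed as a required
parameter with this documented default), `σ = 0.5` uniform. The pool bound
is their product, 0.255915 g enzyme/gDW. Source priority when merging kcat
tables is calibrated > database > TurNuP-predicted > DLKcat-predicted >
imputed; median imputation over kept values is available for uncovered
reactions.

## Solvers

All LPs (FBA, pFBA, minimum-enzyme, FVA, phase planes) are solved with
scipy's HiGHS backend with feasibility/optimality tolerances of 1e-9
requested and 1e-6 asserted on solutions; variable order is the model's
reaction order, making runs deterministic. pFBA is a lexicographic
two-stage LP: the objective is fixed at its optimum (relaxed by 1e-9 to
absorb stage-1 solver noise), then Σ|v| is minimized via auxiliary
variables t ≥ |v|, which leaves the original bounds untouched.
Infeasibility and unboundedness are reported in the solution status rather
than raised.

FVA solves two LPs per reaction at ≥ `fraction_of_optimum` × optimum
(default 1.0) and aggregates split copies: within a direction, the maximal
range over isozyme copies; across directions, forward range minus reverse
range. A negative difference is clamped to zero and logged — a variability
measure cannot be negative. When a reversible reaction also has isozymes the
within-direction rule applies first. A net-flux variant (`method="net"`,
optimizing Σ forward copies − Σ reverse copies directly) is exposed because
the subtraction rule understates the variability of genuinely bidirectional
reactions; the subtraction rule stays the default.

Phase planes run pFBA (not plain FBA) per grid cell over two exchange-bound
ranges; infeasible cells are recorded as growth 0.

## Calibration

Predicted kcats can over-constrain the pool; two relax-only loops raise
them. The enzyme-usage method: while pFBA growth < target·(1−tol), multiply
the kcat of the reaction with the largest enzyme-usage share by a factor
(default 2, ties broken lexicographically, per-reaction cap 10⁶ s⁻¹,
source retagged `calibrated`). The ¹³C-consistency method: compare pFBA
*net* fluxes (measurements are net quantities) with the table; every
measured reaction that is under-predicted beyond its relative tolerance has
the kcat of its enzyme-cost-dominant split copy multiplied by the factor;
over-predictions are deliberately left alone — the pool row is an upper
bound, so an over-prediction signals network structure or the objective,
not a slow enzyme. Both loops terminate on convergence, an iteration cap,
or stagnation (no progress over three consecutive rounds), and return a
complete step log; non-convergence is flagged in the log, not raised.
Neither loop ever decreases a kcat, so growth is monotone across the usage
loop by LP monotonicity.

A practical note encoded in the tests: the ¹³C method corrects a flux only
when that flux is limited by its own enzyme's kcat. Its clean use case is a
flux map measured under substrate-limited conditions (the chemostat-style
regime ¹³C studies typically use), where the flux distribution is unique
and kcat-independent; calibration then relaxes kcats until the pool stops
binding and recovery is exact. Deviations measured in pool-bound regimes
can be collateral (demand-driven) and are not fixable by raising the
measured reaction's own kcat.

## Analyses

**Uptake sweep.** Per uptake rate: pFBA growth; biomass yield
v_biomass/(v_substrate·MW_substrate) (recorded 0 with a flag at zero
uptake); enzyme efficiency ε_biomass = v_biomass/E_min with E_min from a
minimum-enzyme LP at the pFBA biomass flux (total minimized enzyme, not a
pathway subset); energy cost Σ_i E_i/v_ATP,i over ATP-producing reactions
(positive ATP stoichiometry in the carried direction, net ATP per reaction
= coefficient × flux); oxphos ratio = ATP made by the user-designated
oxidative-phosphorylation reactions over total ATP (explicit designation
avoids fragile pathway auto-detection; ratio 0 when no ATP is made).
Stage labels use pool slack (> 1e-6 ⇒ substrate-limited) and overflow
secretion (> 1e-6 ⇒ overflow), not dual values, for robustness across LP
backends. The default sweep is 0–6 mmol/gDW/h in 61 steps.

**Substrate hierarchy.** For each substrate the uptake bound is
carbon_uptake/carbon_count with carbon_uptake = 15 mmol C/gDW/h (glucose
2.5, cellobiose 1.25, xylose 3.0, galactose 2.5, arabinose 3.0). For each
of the 12 precursors (G6P, F6P, G3P, 3PG, PEP, PYR, AcCoA, OAA, AKG, SUCC,
E4P, R5P) a temporary unit-stoichiometry, enzyme-free drain is added, its
flux maximized, E_min computed at that flux, and ε = v/E_min recorded
(0 with a flag if unreachable). Substrate a is preferred over b iff
ε(a,p) > ε(b,p) strictly for every precursor p; any tie or mixed comparison
means co-utilization. Tiers are extracted by repeatedly removing the set of
substrates not strictly dominated by any remaining one.

**Targets.** Method 1: pFBA at maximal product secretion under the given
uptake conditions (maximal product, not maximal growth — the engineering
question is product capacity); each reaction's enzyme demand is split among
its complex's genes by subunit mass share and summed per gene; the top 15
genes are enhancement candidates. Method 2: biomass is pinned at 100% of
its maximum (HGLP, high growth / low product) and at 10% (LGHP), the
product maximized in each state; reactions with net flux > 1 mmol/gDW/h in
either state are candidates, labelled enhance when enzyme cost and flux are
higher in the LGHP state, weaken when lower, none when mixed. The
HGLP/LGHP naming follows the acronym expansion (high-growth state = 100%
biomass); scores are LGHP−HGLP enzyme-cost differences.

## The synthetic fixture

The minicore is a fixed ~45-reaction lumped central-carbon network (36
enzymatic reactions after splitting/expansion, 37 metabolites) built from
abstract reactions ("upper glycolysis", "oxidative PPP") rather than full
biochemistry: LPs stay under 100 variables while the structural contrasts
that matter are kept —

* five sugars with designed carbon counts; cellobiose has a hydrolytic and
  a phosphorolytic cleavage (the latter routes one hexose through
  glucose-1-phosphate and saves one ATP per cellobiose); arabinose is the
  xylose route plus two extra slow enzymes; galactose enters through a
  two-enzyme Leloir-style lump;
* two respiratory modes and fermentation with a designed enzyme-cost
  ordering *per mmol ATP*: high-yield oxidative phosphorylation (P/O 2.5,
  1000 kDa complex, ≈0.0076 g·h/mmol ATP) > alternative-oxidase route
  (P/O 1.5, ≈0.0062) > ethanol fermentation (substrate-level only,
  ≈0.0046), while ATP yield per glucose orders the opposite way
  (34 > 22 > 2). The low-yield route lies on the lower convex hull of
  (carbon per ATP, enzyme per ATP), which is what produces a genuine
  three-stage sweep: carbon-limited high-yield respiration, then a
  pool-bound adjustment stage shifting to the cheaper oxidase, then
  ethanol overflow from a critical uptake near 3.9 mmol/gDW/h;
* a hexokinase isozyme pair ("hxk1 or glk1", different kcat/MW per copy),
  two `and`-complexes (the 2-oxoglutarate dehydrogenase lump and the
  respiratory chain) and three reversible enzymatic reactions, so the
  splitting, expansion and aggregation rules are all exercised;
* a biomass reaction drawing all 12 precursors plus 60 ATP per unit growth.

These choices plant an exact ground truth that the analyses must recover:
utilization tiers [{glucose, cellobiose}, {xylose, galactose}, {arabinose}]
with mixed-dominance co-utilization inside the first two tiers (cellobiose
beats glucose on the ATP-consuming precursors through the phosphorolytic
route but loses on pyruvate, where ATP is not limiting and its extra
cleavage enzyme counts against it; xylose beats galactose only on R5P,
where it enters the pentose pool directly); fermentation-branch enhance
targets (pdc, adh) and respiratory weaken targets for ethanol; and the
overflow staging above.

Supporting generators: random feasible toy models (substrate-to-biomass
chain plus random conversions, positive optimum by construction); synthetic
proteomes with an exactly planted enzyme mass fraction (background protein
mass scaled analytically, so recovery is exact to machine precision); kcat
perturbations that record the pre-perturbation values; and ¹³C-style flux
tables (pFBA net fluxes of the active interior reactions × unit-mean
lognormal noise with chosen CV; relative tolerance max(2·CV, 0.05)). All
generators are pure functions of their arguments with explicitly seeded
local RNGs; repeated calls are byte-identical.

What the fixture does *not* emulate: genome-scale flux magnitudes or a real
organism's parameter values (growth rates here are ~0.2–0.7 h⁻¹ on a toy
biomass unit), thermodynamics, kinetic regulation, condition-dependent
proteome remodelling, or measurement structure beyond lognormal noise.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative enzyme-economics phenomena, not quantitative agreement with any
real dataset.

## Numerical choices and edge cases

* LP tolerances 1e-9 requested / 1e-6 asserted; pool feasibility asserted
  as Σ E ≤ bound + 1e-6.
* Objective-holding rows are relaxed by 1e-9 when a second-stage LP refines
  a first-stage optimum.
* Relative flux errors divide by max(|measured|, 1e-6 mmol/gDW/h).
* Zero uptake: yield recorded as 0 with an explicit flag; oxphos ratio 0
  when total ATP production is below tolerance.
* Exchange reactions are identified structurally (single-metabolite
  stoichiometry); uptake is a negative exchange flux in the original
  orientation and the reverse copy's upper bound after splitting — the
  `set_uptake`/`with_conditions` helpers handle both forms.
* Ties: kcat-source merging keeps the higher-priority source; calibration
  argmax ties break lexicographically by reaction id; hierarchy ties on any
  precursor mean co-utilization (no strict dominance).
* Problem sizes used in the shipped tests and acceptance script (31-point
  sweeps, 21×21 phase-plane grids, 20 proteome seeds, 20 alternative
  optima) keep the whole suite under a minute on one CPU while leaving
  every phenomenon well resolved.

## Known limitations

* One shared pool; no compartment-specific or secretory proteome budgets.
* σ is uniform and never calibrated (only kcat is).
* The ¹³C loop cannot correct over-predictions or collateral deviations
  (see above); this is a property of the method, surfaced honestly by the
  step log's stagnation flag.
* SBML round-trips preserve stoichiometry, bounds and gene rules but not
  the package's enzyme annotations; COBRA-style JSON is the lossless
  format.
* The isozyme expansion copies bounds verbatim, so the summed capacity of
  the copies can exceed the original bound when that bound is finite and
  binding; with the customary large default bounds this does not affect
  optima, and optima preservation is asserted in the tests.
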