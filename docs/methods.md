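# Methods

## Overview

`agefba` connects the choice of the objective function in enzyme-constrained
flux balance analysis (ecFBA) to replicative-ageing observables of
budding-yeast-like cells. A miniature central-carbon network is optimised
with a lexicographic two-stage strategy (with flexibilities ε₁, ε₂ and an
optional parsimonious post-optimisation), a Boolean signalling stand-in
converts the optimal fluxes into enzyme-usage constraints, and a
damage-accumulation model closes the loop: reactive oxygen species (ROS)
left unneutralised by antioxidant reactions damage the protein pool, which
shrinks the usable enzyme capacity and raises the maintenance requirement
until the optimisation becomes infeasible — the cell's death.

## The enzyme-constrained LP

Variables are fluxes **v** [mmol gDW⁻¹ h⁻¹], enzyme usages **e**
[mmol gDW⁻¹] and the pool usage e_pool [g gDW⁻¹]:

    max/min  z₁ = cᵀv
    s.t.     S v = 0
             v_min ≤ v ≤ v_max
             e_i = Σ_j (n_ij / kcat_ij) v_j          (per enzyme i)
             e_pool = Σ_i MW_i e_i
             e_min ≤ e ≤ e_max,  0 ≤ e_pool ≤ σ f P_tot

σ is the average enzyme saturation, f the modelled mass fraction of the
proteome and P_tot the total protein content [g gDW⁻¹]. Models are stored
and solved in irreversible (split) form so that "reactions producing X" is
well defined per column. The LP backend is HiGHS dual simplex through
SciPy, with primal/dual feasibility tolerances of 1e-9; the dual simplex
with a fixed variable ordering makes the selected vertex — and therefore
the *non-parsimonious* solution, which is compared against the parsimonious
one — reproducible across runs.

## Lexicographic optimisation, ε-flexibility and parsimony

A strategy is an ordered pair of objectives from {max growth, min glucose
uptake, max/min ATP production, min NADH production, max NGAM}. After
optimising the first objective to z₁, the constraint

    cᵀv ≥ z₁(1 − ε₁)   (after a maximisation; ≤ z₁(1 + ε₁) after a minimisation)

is appended before optimising the second objective. The parsimonious
solution additionally minimises Σ_j v_j + Σ_i e_i with the preceding stage
locked at solver precision (ε = 1e-9). Production-sum objectives (ATP,
NADH) weight each reaction by its stoichiometric coefficient of the
metabolite, so they are true production rates invariant to reaction
scaling; an unweighted variant exists as a sensitivity flag, as does a
molecular-weight-weighted parsimony variant.

The regulation step afterwards tightens enzyme bounds around the current
optimum; the final re-optimisation re-solves the last stage objective with
every earlier stage lock relaxed by the additional flexibility ε₂
(multiplicatively compounded with ε₁ for stage 1). Without this slack the
regulated problem would often be infeasible. If the regulated re-solve is
still infeasible, the simulator keeps the unregulated solution and logs a
warning rather than killing the cell — infeasibility of the *unregulated*
stage-1 problem is the only death signal.

## The regulation stand-in

Five Boolean pathway nodes (Snf1, PKA, TOR, Yap1, Sln1) are updated
synchronously from three inputs read off the optimal fluxes: glucose
uptake above a threshold, respiratory ATP share above a threshold, and
unneutralised ROS flux above a threshold (all strict comparisons;
defaults 0.05 mmol gDW⁻¹ h⁻¹, 0.4 and 1e-4 mmol gDW⁻¹ h⁻¹). The default
wiring is deliberately minimal: glucose activates PKA (which
down-regulates the glucose-repressed carbon-entry steps of the TCA cycle)
and TOR, represses Snf1; high ROS activates Yap1 (which up-regulates
antioxidant enzymes); respiration flags Sln1. PKA additionally requires
the cell *not* to be substantially respiring: once maintenance demand
forces respiratory ATP production, repression is lifted. This
derepression clause is what keeps the regulated re-optimisation feasible
in late life, when cutting respiratory capacity by the regulation factor
would conflict with the hard maintenance bound; in the terminal sliver of
life no repression is applied at all. Down-regulation of an active
target sets e_max := e*(1 − ρ), up-regulation e_min := e*(1 + ρ) capped at
the pool-feasible level, with regulation factor ρ = 0.04 by default. Rule
tables, thresholds and targets are all config-replaceable so a published
Boolean wiring can be dropped in; the shipped rules are a structural
stand-in, not reverse-engineered content.

## Damage dynamics

Between optimisations the damaged protein fraction D (intact P = 1 − D)
evolves by

    dD/dt = f_m · J_ROS · P + f₀ · P − r₀ · D

where J_ROS is the unneutralised ROS flux (production by the respiratory
chain minus antioxidant consumption, floored at zero), f_m the metabolic
damage formation rate per unit ROS flux, f₀ = 1e-4 h⁻¹ the non-metabolic
damage formation rate and r₀ = 5e-4 h⁻¹ the repair rate (reference
values). These right-hand sides are the simplest forms consistent with
the modelled biology (ROS-proportional plus baseline formation,
first-order repair) and sit behind a narrow interface so a more detailed
model can replace them. Integration is forward Euler at dt = 0.01 h by
default — the standard choice in dynamic FBA where each step requires an
LP solve anyway; the one-step error is verified to be second order.

Damage feeds back twice: the usable pool is σ f P_tot · P, and the
non-growth associated maintenance (NGAM) lower bound is
ngam₀ + slope · D. Division occurs when the accumulated biomass reaches a
threshold; the mother keeps a fraction `retention` of the damage mass
while intact protein splits evenly, and her fractions are renormalised
(retention 0.5 leaves D unchanged; higher retention concentrates damage
in the mother, the multiplicative amplification that dominates ageing in
the calibrated cell). Daughters are counted (that is what replicative
lifespan means) but not simulated.

Phases: phase I is the initial maximal-growth plateau (mean growth over
the first 5 % of life); phase II starts when growth first drops below
95 % of that plateau. Mean generation time is the arithmetic mean over
completed divisions, with the first division timed from birth.

## The synthetic network

The packaged network (20 reactions / 12 metabolites / 15 enzymes before
splitting) contains glucose uptake through a transporter, a three-step
glycolysis with an isoenzyme pair on the first step, a redox-neutral
fermentation branch, a reversible mitochondrial pyruvate carrier, a lumped
TCA chain whose second intermediate (α-ketoglutarate) is a biomass
precursor, a lumped respiratory chain producing ATP and ROS, an
ATP-costly anaplerotic bypass, catalase-like and glutathione-like ROS
neutralisation with bounded capacity, an uncatalysed ROS sink
(representing ROS free to damage proteins), a biomass reaction and an
NGAM reaction. Three numbers shape the physiology:

* fermentation is enzyme-cheaper per ATP (≈ 0.03 g h mmol⁻¹ per ATP) than
  respiration (≈ 0.06) while respiration yields more ATP per glucose
  (22 vs 2) — so a growth-maximising cell ferments (Crabtree-like
  overflow) but must respire in proportion to growth for the TCA-derived
  precursor, which ties ROS to the metabolism;
* the fermentation branch has a capacity bound (0.5 mmol gDW⁻¹ h⁻¹), so
  the rising maintenance demand of an ageing cell is increasingly met by
  respiration — growth drops and the metabolism shifts respiratory
  (phase II), and the damage rate stays high near death, which makes death
  crisp instead of asymptotic;
* the antioxidant reactions cost enzyme pool, so a cell at its growth
  optimum cannot afford them; only when the growth requirement is relaxed
  (ε₁ ≳ 0.3) does the parsimonious solution buy catalase (which also
  halves the disposal flux: 2 ROS per unit), cutting unneutralised ROS by
  roughly half — the mechanism by which parsimony extends lifespan.

Randomness only jitters kcat and MW within ±20 % of the preset means
(seeded); topology is fixed, so pathway-level behaviour is stable across
seeds. Glucose uptake is unbounded; finiteness comes from the enzyme pool.

What the generator does *not* emulate: real yeast kinetics (kcat/MW are
order-of-magnitude plausible, not literature values), galactose
metabolism, compartmentalised redox cofactors (one shared NADH pool),
NADPH, and the published Boolean wiring. Passing tests therefore
demonstrate the *mechanisms* — objective choice shaping lifespan through
flux allocation — not quantitative yeast physiology.

## Calibration of the reference cell

The reference cell must divide 20–30 times with a mean generation time of
1.5–2.3 h under the parsimonious maximal-growth objective (ε₁ = 0,
ε₂ = 0.05, regulation factor 0.04, f₀ = 1e-4, r₀ = 5e-4). The free
parameters are the metabolic damage rate f_m, the retention coefficient,
the division biomass and the NGAM slope. The starting point came from
design arithmetic: the NGAM slope (10 per unit damage) sets the
infeasibility frontier near D ≈ 0.13 while growth is still usable;
retention 0.55 makes the damage trajectory convex (multiplicative
amplification ≈ ×1.1 per division) so death is reached while divisions
are still frequent; f_m = 0.05 gDW mmol⁻¹ then places the division count
in the window (metabolic damage dominates the pinned non-metabolic rate
f₀ roughly tenfold, so the strategy-dependent ROS differences actually
matter for lifespan), and division biomass 0.45 sets the early
generation time near 1.5 h. `calibrate_wildtype` refines this by
coordinate search (generation-time window first via the biomass
threshold, division count second via f_m) and accepted the design point
unchanged; the calibrated bundle is committed as package data and
regression-tested. The packaged cell divides 25 times with a mean
generation time of ≈ 1.76 h and dies at ≈ 53 h.

Through the ε₂ slack of the regulation step, the parsimonious reference
runs its catalase at capacity from birth; the non-parsimonious solution
never does (antioxidants cannot increase growth). Net unneutralised ROS
is therefore what separates strategies: plain maximal growth leaks all
ROS and lives shorter, parsimonious solutions neutralise up to the
antioxidant capacity, and NGAM maximisation drives extra respiration
whose ROS outruns the capacity.

## Numerical choices and degenerate inputs

* LP tolerances 1e-9 (primal and dual); parsimony lock at 1e-9; stage
  locks use max(ε, 1e-9) so an ε = 0 lock is never numerically binding at
  exactly the optimum.
* Relative-change ties: |Δ| ≤ 1e-6 counts as "unchanged". A flux switched
  off is "decreased" with Δ = 1; a flux switched on from zero is undefined
  under the relative-change formula and reported as a separate
  "switched on" class rather than given an arbitrary value.
* Zero glucose uptake makes normalised fluxes undefined for that time
  point; such rows are excluded from phase averages. Phase averages are
  time-weighted by default (an unweighted per-step variant exists).
* Fractions are clamped to [0, 1] after each Euler step; division with
  zero total protein mass leaves fractions untouched.
* Lifespan simulations stop at a guard time (default 200 h, ≈ 10× the
  reference lifespan) and flag the result truncated.

## Problem sizes

All shipped analyses run on the miniature network: a lifespan is ~4 800 LP
solves of a 36-variable LP (≈ 1 min); the sweep scripts use reduced grids
(ε₁ ∈ {0, 0.15, 0.3, 0.45}, one ε₂) rather than a dense Fig-1-style grid.
Vertex-enumeration oracles in the tests are restricted to fixtures with at
most six flux variables.

## Known limitations

* The Boolean rule content and the damage ODE right-hand sides of the
  published multi-scale yeast model are not public in printed form; this
  package ships structural stand-ins behind replaceable interfaces.
* Death and growth both draw on the same enzyme pool, so a cell's growth
  tends to zero as it approaches infeasibility; the fermentation capacity
  bound keeps the terminal decline short but a final long generation can
  still raise the mean generation time by a few percent.
* Wildtype *counts* over a sweep grid (how many configurations fall in
  the window) are sensitive to the miniature network's parameters and are
  reported but not asserted; the directional claims (growth objective
  required for replication, parsimony extending lifespan at ε₁ ≥ 0.3,
  NGAM maximisation lengthening generation times) are asserted.
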