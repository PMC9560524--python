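# agefba

**Enzyme-constrained FBA meets replicative ageing: what the objective
function does to a yeast cell's lifespan.**

Flux balance analysis predicts metabolic fluxes by optimising an objective
— but which objective? This package studies that question not against flux
data but against *ageing*: a budding-yeast-like cell is simulated from
birth to death, with its metabolism re-optimised every time step, protein
damage accumulating from unneutralised reactive oxygen species (ROS), and
damage feeding back on the metabolism until the optimisation turns
infeasible (death). The observables are evolutionarily meaningful ones:
the replicative lifespan (RLS, number of divisions) and the generation
time. It is aimed at systems biologists who work with constraint-based
models and want a mechanistic testbed for objective-function choices.

## The model in brief

The metabolism is an enzyme-constrained LP: fluxes **v** obey steady-state
mass balance `S v = 0` and bounds, each enzyme usage is coupled to its
reactions through `e_i = Σ_j (n_ij/kcat_ij) v_j`, and the total enzyme
mass is capped by the pool `σ f P_tot`. Optimisation strategies are
lexicographic: optimise a first objective to `z₁`, lock
`cᵀv ≥ z₁(1−ε₁)` (or `≤ z₁(1+ε₁)` for minimisations), optionally optimise
a second objective, and optionally take the **parsimonious** solution
(minimal `Σv + Σe` at the locked optima). A Boolean signalling stand-in
(Snf1/PKA/TOR/Yap1/Sln1) converts the optimal fluxes into enzyme-bound
constraints before a final ε₂-relaxed re-optimisation.

Between optimisations the damaged protein fraction D follows

    dD/dt = f_m·J_ROS·P + f₀·P − r₀·D,        P = 1 − D,

the usable pool scales with P, the maintenance requirement (NGAM) grows
with D, division occurs at a biomass threshold with asymmetric damage
retention by the mother, and death is LP infeasibility. A packaged
miniature central-carbon network (glycolysis, fermentation, TCA,
oxidative phosphorylation, oxidative stress, anaplerosis) is calibrated
so that parsimonious maximal growth yields a wildtype cell: 20–30
divisions with a mean generation time of 1.5–2.3 h. See
`docs/methods.md` for the full model description.

## Worked example

```python
from agefba import load_reference, simulate_lifespan, OptimizationStrategy

model, strategy, regulation, ageing = load_reference()
result = simulate_lifespan(model, strategy, ageing,
                           regulation_config=regulation)
print(result.rls, round(result.mean_generation_time, 2),
      round(result.death_time, 1))
```

prints

```
25 1.76 53.5
```

— the reference cell divides 25 times with a mean generation time of
1.76 h and dies at 53.5 h: a wildtype by the operational definition.
Dropping the growth objective is fatal to replication:

```python
res = simulate_lifespan(model, OptimizationStrategy(first="min_glucose_uptake"),
                        ageing, regulation_config=regulation, max_time=20.0)
print(res.rls)   # 0 — the cell only covers maintenance, never divides
```

The numbered scripts under `analysis/` run the full study on the packaged
network and write tables under `results/`:

1. `01_reference_lifespan.py` — the reference cell's life history
   (trajectory, generation times, phase boundary).
2. `02_objective_sweep.py` — objectives × flexibilities × parsimony, with
   wildtype counts per strategy.
3. `03_flux_rewiring.py` — per-pathway relative flux changes between the
   non-parsimonious and parsimonious solutions, per metabolic phase
   (glucose-normalised, reversible splits and isoenzymes collapsed).
4. `04_phase_comparison.py` — time, divisions and damage per metabolic
   phase for wildtype-producing strategies.

A small CLI wraps the same functionality
(`agefba generate | simulate | sweep | analyze`); try
`agefba simulate --out run.tsv`.

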