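"""Replicative-lifespan simulation loop and the objective sweep.

One simulated life iterates: solve the optimisation strategy on the
damage-adjusted enzyme-constrained LP -> derive regulation inputs and
tighten enzyme bounds -> epsilon2-relaxed re-optimisation -> integrate the
damage/growth dynamics for one step -> divide if enough biomass was made ->
repeat until the LP turns infeasible (death) or a guard time is reached.

Phases: phase I is the initial maximal-growth (fermentation-dominated)
plateau; phase II starts when the growth flux first drops below a fraction
(1 - delta) of that plateau.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ageing import (
    CellState,
    DamageParameters,
    apply_state_bounds,
    damage_step,
    effective_pool,
    maybe_divide,
)
from .model import FluxSolution, MetabolicModel, build_lp, solve_lp
from .optimize import (
    PARSIMONY_LABEL,
    OptimizationStrategy,
    make_objective,
    parsimony_objective,
    run_stages,
)
from .regulation import RegulationConfig, RegulationState, constrain_enzymes
from .regulation import derive_inputs as _derive_inputs
from .regulation import update_state as _update_state

logger = logging.getLogger(__name__)

#: wildtype acceptance windows: 20-30 divisions, 1.5-2.3 h generation time
WILDTYPE_RLS = (20, 30)
WILDTYPE_GENERATION_TIME = (1.5, 2.3)

DEFAULT_MAX_TIME = 200.0  # h, ~10x a reference lifespan (non-termination guard)


@dataclass
class LifespanResult:
    rls: int
    generation_times: list[float]
    mean_generation_time: float
    death_time: float
    phase_boundary: float
    divisions_per_phase: tuple[int, int]
    damage_at_phase_end: tuple[float, float]
    trajectory: pd.DataFrame
    truncated: bool = False
    status: str = "ok"

    @property
    def wildtype(self) -> bool:
        return classify_wildtype(self)


@dataclass
class SweepRecord:
    first: str
    second: str | None
    epsilon1: float
    epsilon2: float
    parsimonious: bool
    rls: int
    mean_generation_time: float
    wildtype: bool
    status: str


def classify_wildtype(result: LifespanResult,
                      rls_window: tuple[int, int] = WILDTYPE_RLS,
                      gt_window: tuple[float, float] = WILDTYPE_GENERATION_TIME
                      ) -> bool:
    """Inclusive wildtype windows on divisions and mean generation time."""
    if not result.generation_times:
        return False
    return (rls_window[0] <= result.rls <= rls_window[1]
            and gt_window[0] <= result.mean_generation_time <= gt_window[1])


def detect_phases(trajectory: pd.DataFrame, delta: float = 0.05,
                  plateau_fraction: float = 0.05) -> float:
    """First time the growth flux falls below (1 - delta) of its initial
    plateau (mean growth over the first ``plateau_fraction`` of the
    lifetime). Returns the final time when growth never drops."""
    if trajectory.empty:
        raise ValueError("empty trajectory")
    t = trajectory["t"].to_numpy()
    growth = trajectory["growth"].to_numpy()
    t_end = t[-1]
    window = t <= t[0] + plateau_fraction * max(t_end - t[0], 0.0)
    plateau = float(growth[window].mean()) if window.any() else float(growth[0])
    below = growth < (1.0 - delta) * plateau
    if not below.any():
        return float(t_end)
    return float(t[int(np.argmax(below))])


def _relock(problem, objective, z: float, relax: float) -> None:
    """Append a stage lock with a combined multiplicative relaxation.

    ``relax`` is the total allowed fractional violation (may exceed 1 when
    epsilon1 and epsilon2 compound)."""
    if objective.direction == "max":
        bound = z * (1.0 - relax)
        problem.add_inequality(
            {k: -w for k, w in objective.coefficients.items()}, -bound)
    else:
        bound = z * (1.0 + relax)
        problem.add_inequality(dict(objective.coefficients), bound)


def _regulated_resolve(base_problem, model: MetabolicModel, state: CellState,
                       params: DamageParameters,
                       strategy: OptimizationStrategy,
                       solution: FluxSolution,
                       adjustments: dict[str, tuple[float, float]],
                       weighted_sums: bool = True) -> FluxSolution:
    """Re-optimise the final stage under regulated enzyme bounds.

    Every earlier stage lock is carried over, relaxed by the additional
    flexibility epsilon2; the final-stage objective is re-optimised.
    """
    problem = base_problem.copy()
    apply_state_bounds(problem, state, model, params)
    for eid, (lo, hi) in adjustments.items():
        problem.set_bounds(eid, lower=lo, upper=hi)

    labels = solution.objective_labels
    values = solution.stage_values
    eps1, eps2 = strategy.epsilon1, strategy.epsilon2
    objectives = []
    for label in labels:
        if label == PARSIMONY_LABEL:
            objectives.append(parsimony_objective(problem, model))
        else:
            objectives.append(make_objective(model, label, weighted=weighted_sums))
    # locks for all but the final stage
    for k in range(len(labels) - 1):
        if k == 0:
            relax = (1.0 - (1.0 - eps1) * (1.0 - eps2)
                     if objectives[0].direction == "max"
                     else (1.0 + eps1) * (1.0 + eps2) - 1.0)
        else:
            relax = eps2
        _relock(problem, objectives[k], values[k], relax)
    return solve_lp(problem, objectives[-1])


def simulate_lifespan(model: MetabolicModel, strategy: OptimizationStrategy,
                      ageing_params: DamageParameters,
                      regulation_config: RegulationConfig | None = None,
                      max_time: float = DEFAULT_MAX_TIME,
                      weighted_sums: bool = True) -> LifespanResult:
    """Simulate one mother cell from birth to death (or the guard time)."""
    base = build_lp(model)
    state = CellState()
    reg_state = RegulationState()
    rows: list[dict] = []
    dt = ageing_params.dt
    dead = False
    n_steps = int(np.ceil(max_time / dt))
    rxn_ids = [r.id for r in model.reactions]
    enz_ids = [e.id for e in model.enzymes]
    biomass_id = model.named("biomass")

    for _ in range(n_steps):
        problem = base.copy()
        apply_state_bounds(problem, state, model, ageing_params)
        sol, _ = run_stages(problem, model, strategy, weighted_sums=weighted_sums)
        if not sol.optimal:
            logger.debug("LP %s at t=%.3f h: cell dead", sol.status, state.t)
            dead = True
            break
        if regulation_config is not None and regulation_config.regulation_factor > 0:
            inputs = _derive_inputs(model, sol, regulation_config.thresholds)
            reg_state = _update_state(reg_state, inputs, regulation_config)
            adjustments = constrain_enzymes(
                model, reg_state, regulation_config, sol,
                pool_bound=effective_pool(state, model))
            if adjustments:
                sol_reg = _regulated_resolve(
                    base, model, state, ageing_params, strategy, sol,
                    adjustments, weighted_sums=weighted_sums)
                if sol_reg.optimal:
                    sol_reg.stage_values = sol.stage_values
                    sol_reg.objective_labels = sol.objective_labels
                    sol = sol_reg
                else:
                    logger.warning(
                        "regulated re-optimisation %s at t=%.3f h; keeping the "
                        "unregulated solution", sol_reg.status, state.t)

        row = {"t": state.t, "D": state.damaged,
               "growth": sol.v.get(biomass_id, 0.0), "e_pool": sol.e_pool}
        for rid in rxn_ids:
            row[f"v_{rid}"] = sol.v.get(rid, 0.0)
        for eid in enz_ids:
            row[f"e_{eid}"] = sol.e.get(eid, 0.0)
        rows.append(row)

        state = damage_step(state, sol, model, ageing_params)
        before = state.divisions
        state = maybe_divide(state, ageing_params)
        if state.divisions > before:
            logger.debug("division %d at t=%.3f h (D=%.4f)",
                         state.divisions, state.t, state.damaged)

    truncated = not dead
    death_time = state.t
    trajectory = pd.DataFrame(rows)
    division_times = list(state.division_times)
    generation_times = (list(np.diff([0.0] + division_times))
                        if division_times else [])
    mean_gt = float(np.mean(generation_times)) if generation_times else float("nan")

    if trajectory.empty:
        return LifespanResult(
            rls=0, generation_times=[], mean_generation_time=float("nan"),
            death_time=0.0, phase_boundary=0.0, divisions_per_phase=(0, 0),
            damage_at_phase_end=(0.0, 0.0), trajectory=trajectory,
            truncated=False, status="dead_at_birth")

    boundary = detect_phases(trajectory)
    d1 = sum(t <= boundary for t in division_times)
    phase_mask = trajectory["t"] <= boundary
    damage_phase1 = float(trajectory.loc[phase_mask, "D"].iloc[-1]) \
        if phase_mask.any() else 0.0
    return LifespanResult(
        rls=state.divisions,
        generation_times=generation_times,
        mean_generation_time=mean_gt,
        death_time=death_time,
        phase_boundary=boundary,
        divisions_per_phase=(d1, state.divisions - d1),
        damage_at_phase_end=(damage_phase1, float(state.damaged)),
        trajectory=trajectory,
        truncated=truncated,
        status="truncated" if truncated else "ok",
    )


def sweep(model: MetabolicModel, objective_pairs, epsilon1_values,
          epsilon2_values, parsimony_options, ageing_params: DamageParameters,
          regulation_config: RegulationConfig | None = None,
          max_time: float = DEFAULT_MAX_TIME) -> pd.DataFrame:
    """Grid of lifespan simulations over objectives x epsilons x parsimony.

    Returns one row per configuration with the columns
    (first, second, epsilon1, epsilon2, parsimonious, rls,
    mean_generation_time, wildtype, status). Individual failures are
    recorded in ``status`` and do not abort the sweep.
    """
    records = []
    for first, second in objective_pairs:
        for eps1 in epsilon1_values:
            for eps2 in epsilon2_values:
                for parsimonious in parsimony_options:
                    strategy = OptimizationStrategy(
                        first=first, second=second, epsilon1=eps1,
                        epsilon2=eps2, parsimonious=parsimonious)
                    try:
                        res = simulate_lifespan(
                            model, strategy, ageing_params,
                            regulation_config=regulation_config,
                            max_time=max_time)
                        rec = SweepRecord(
                            first=first, second=second, epsilon1=eps1,
                            epsilon2=eps2, parsimonious=parsimonious,
                            rls=res.rls,
                            mean_generation_time=res.mean_generation_time,
                            wildtype=classify_wildtype(res), status=res.status)
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("sweep point failed: %s", exc)
                        rec = SweepRecord(
                            first=first, second=second, epsilon1=eps1,
                            epsilon2=eps2, parsimonious=parsimonious,
                            rls=0, mean_generation_time=float("nan"),
                            wildtype=False, status=f"error: {exc}")
                    records.append(rec.__dict__)
    return pd.DataFrame(records)
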