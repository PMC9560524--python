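"""Protein damage accumulation and growth dynamics between optimisations.

Between LP solves the cell state evolves by a simple damage model: the
damaged protein fraction D grows with metabolic damage formation (rate f_m
per unit of unneutralised ROS flux, acting on the intact fraction P), with
non-metabolic damage formation (rate f0) and shrinks with first-order repair
(rate r0):

    dD/dt = f_m * J_ROS * P + f0 * P - r0 * D,      P = 1 - D

Damage feeds back on the metabolism in two ways: the usable enzyme pool
scales with the intact fraction, and the non-growth associated maintenance
(NGAM) requirement grows linearly with damage. Cell division occurs once
enough biomass has been produced; protein damage is segregated
asymmetrically at division (the mother retains a fraction ``retention`` of
the damage mass while intact protein is split evenly, and the mother's
fractions are renormalised). Death is the LP turning infeasible.

The right-hand sides are deliberately the simplest forms consistent with the
modelled biology and are isolated behind this module's interface so a more
detailed damage model can replace them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .fluxes import net_ros_flux
from .model import FluxSolution, MetabolicModel, build_lp, solve_lp
from .optimize import OptimizationStrategy, make_objective


@dataclass
class DamageParameters:
    """Rates in 1/h unless noted; reference non-metabolic damage formation
    f0 = 0.0001 and repair r0 = 0.0005."""

    f_m: float = 0.0  # metabolic damage per unit ROS flux [gDW/mmol]
    f0: float = 0.0001
    r0: float = 0.0005
    retention: float = 0.5  # damage fraction kept by the mother at division
    division_biomass: float = 1.0  # biomass units required per division
    ngam0: float = 0.0  # baseline NGAM flux [mmol/gDW/h]
    ngam_slope: float = 0.0  # NGAM increase per unit damage fraction
    dt: float = 0.01  # integrator step [h]

    def __post_init__(self) -> None:
        for name in ("f_m", "f0", "r0", "division_biomass", "ngam0",
                     "ngam_slope", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")


@dataclass
class CellState:
    intact: float = 1.0
    damaged: float = 0.0
    biomass_progress: float = 0.0
    divisions: int = 0
    t: float = 0.0
    division_times: list[float] = field(default_factory=list)

    def copy(self) -> "CellState":
        return replace(self, division_times=list(self.division_times))


def damage_step(state: CellState, solution: FluxSolution,
                model: MetabolicModel, params: DamageParameters,
                dt: float | None = None) -> CellState:
    """One forward-Euler step of the damage/growth dynamics.

    Damage fractions are clamped to [0, 1]; biomass progress integrates the
    growth flux of the solution.
    """
    dt = params.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not solution.optimal:
        raise ValueError("damage step requires an optimal solution")
    j_ros = net_ros_flux(model, solution)
    P, D = state.intact, state.damaged
    dD = (params.f_m * j_ros * P + params.f0 * P - params.r0 * D) * dt
    D_new = min(max(D + dD, 0.0), 1.0)
    growth = solution.v.get(model.named("biomass"), 0.0)
    new = state.copy()
    new.damaged = D_new
    new.intact = 1.0 - D_new
    new.biomass_progress = state.biomass_progress + growth * dt
    new.t = state.t + dt
    return new


def maybe_divide(state: CellState, params: DamageParameters) -> CellState:
    """Division event with asymmetric damage segregation.

    When the biomass threshold is reached, the damage mass is split so the
    mother keeps fraction ``retention`` while intact protein is split
    evenly; the mother's fractions are renormalised to sum to one. With
    retention = 0.5 the damage fraction is unchanged at division.
    """
    if state.biomass_progress < params.division_biomass:
        return state
    damage_kept = params.retention * state.damaged
    intact_kept = state.intact / 2.0
    total = damage_kept + intact_kept
    new = state.copy()
    if total > 0:
        new.damaged = damage_kept / total
        new.intact = intact_kept / total
    new.divisions = state.divisions + 1
    new.division_times = state.division_times + [state.t]
    new.biomass_progress = state.biomass_progress - params.division_biomass
    return new


def ngam_bound(state: CellState, params: DamageParameters) -> float:
    """Damage-dependent lower bound for the NGAM reaction flux."""
    return params.ngam0 + params.ngam_slope * state.damaged


def effective_pool(state: CellState, model: MetabolicModel) -> float:
    """Pool bound scaled by the intact protein fraction."""
    return model.pool_bound * state.intact


def apply_state_bounds(problem, state: CellState, model: MetabolicModel,
                       params: DamageParameters) -> None:
    """Install the damage-adjusted pool and NGAM bounds on a problem."""
    problem.set_bounds("e_pool", upper=effective_pool(state, model))
    problem.set_bounds(model.named("ngam"), lower=ngam_bound(state, params))


def is_dead(model: MetabolicModel, state: CellState,
            strategy: OptimizationStrategy, params: DamageParameters) -> bool:
    """True iff the stage-1 LP with damage-adjusted bounds is infeasible."""
    problem = build_lp(model)
    apply_state_bounds(problem, state, model, params)
    sol = solve_lp(problem, make_objective(model, strategy.first))
    return not sol.optimal
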