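"""Lexicographic two-stage optimisation with epsilon-flexibility and the
parsimonious post-optimisation.

A strategy consists of an ordered pair of objectives. The first objective is
optimised over the enzyme-constrained LP; its achieved value ``z1`` is then
locked as a constraint that may be violated by a fraction ``epsilon1``
(``c^T v >= z1 (1 - eps)`` after a maximisation, ``<= z1 (1 + eps)`` after a
minimisation) before the second objective is optimised. The parsimonious
solution additionally minimises the sum of all fluxes and enzyme usages with
the last stage locked at solver precision only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import (
    FluxSolution,
    LinearProblem,
    MetabolicModel,
    ModelIntegrityError,
    build_lp,
    solve_lp,
)

#: flexibility granted to the stage preceding the parsimonious minimisation
#: ("according to the solver precision")
PRECISION_EPS = 1e-9

OBJECTIVE_LABELS = {
    "max_growth": "max",
    "min_glucose_uptake": "min",
    "max_atp_production": "max",
    "min_atp_production": "min",
    "min_nadh_production": "min",
    "max_ngam": "max",
}

PARSIMONY_LABEL = "parsimony"


class ConfigurationError(ValueError):
    """Strategy or objective configuration is inconsistent with the model."""


@dataclass
class Objective:
    label: str
    direction: str  # "max" | "min"
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if self.direction not in ("max", "min"):
            raise ConfigurationError(f"bad direction {self.direction!r}")
        if not self.coefficients:
            raise ConfigurationError(f"objective {self.label!r} has no coefficients")


@dataclass
class LockedConstraint:
    coefficients: dict[str, float]
    bound: float
    sense: str  # ">=" | "<="


@dataclass
class OptimizationStrategy:
    first: str
    second: str | None = None
    epsilon1: float = 0.0
    epsilon2: float = 0.0
    parsimonious: bool = False

    def __post_init__(self) -> None:
        for eps in (self.epsilon1, self.epsilon2):
            if not 0.0 <= eps <= 1.0:
                raise ConfigurationError("epsilon must lie in [0, 1]")
        for label in (self.first, self.second):
            if label is not None and label not in OBJECTIVE_LABELS:
                raise ConfigurationError(f"unknown objective label {label!r}")

    @property
    def key(self) -> str:
        second = self.second or "-"
        return (f"{self.first}|{second}|e1={self.epsilon1}|e2={self.epsilon2}"
                f"|{'p' if self.parsimonious else 'np'}")


def make_objective(model: MetabolicModel, label: str, weighted: bool = True,
                   atp_id: str = "atp", nadh_id: str = "nadh") -> Objective:
    """Translate an objective label into LP coefficients.

    Production objectives (ATP, NADH) weight each reaction in the
    corresponding reaction set by its positive stoichiometric coefficient of
    the metabolite (``weighted=False`` uses unit weights instead).
    """
    direction = OBJECTIVE_LABELS.get(label)
    if direction is None:
        raise ConfigurationError(f"unknown objective label {label!r}")
    if label == "max_growth":
        coeffs = {model.named("biomass"): 1.0}
    elif label == "min_glucose_uptake":
        coeffs = {model.named("glucose_uptake"): 1.0}
    elif label == "max_ngam":
        coeffs = {model.named("ngam"): 1.0}
    else:
        set_name, met = (
            ("atp_producing", atp_id)
            if "atp" in label
            else ("nadh_producing", nadh_id)
        )
        rids = model.reaction_sets.get(set_name)
        if not rids:
            raise ConfigurationError(f"model lacks reaction set {set_name!r}")
        coeffs = {}
        for rid in rids:
            coef = model.reaction(rid).stoich.get(met, 0.0)
            if coef > 0:
                coeffs[rid] = coef if weighted else 1.0
        if not coeffs:
            raise ConfigurationError(
                f"no reaction in set {set_name!r} produces {met!r}"
            )
    return Objective(label=label, direction=direction, coefficients=coeffs)


def parsimony_objective(problem: LinearProblem, model: MetabolicModel | None = None,
                        weight_by_mw: bool = False) -> Objective:
    """Sum of all fluxes plus all enzyme usages (equal unit weights).

    ``weight_by_mw`` is a sensitivity variant that weights each enzyme usage
    by its molecular weight (i.e. minimises flux plus enzyme mass).
    """
    coeffs = {name: 1.0 for name in problem.var_names[: problem.n_reactions]}
    for name in problem.var_names[problem.n_reactions:-1]:
        w = model.enzyme(name).MW if (weight_by_mw and model is not None) else 1.0
        coeffs[name] = w
    return Objective(label=PARSIMONY_LABEL, direction="min", coefficients=coeffs)


def lock_stage(problem: LinearProblem, objective: Objective, z: float,
               epsilon: float) -> LockedConstraint:
    """Append the locked-stage constraint for an achieved optimum ``z``."""
    if not 0.0 <= epsilon <= 1.0:
        raise ConfigurationError("epsilon must lie in [0, 1]")
    if z < 0:
        warnings.warn(
            "locking a negative objective value: the multiplicative relaxation "
            "direction inverts", stacklevel=2,
        )
    if objective.direction == "max":
        bound = z * (1.0 - epsilon)
        problem.add_inequality({k: -w for k, w in objective.coefficients.items()}, -bound)
        locked = LockedConstraint(dict(objective.coefficients), bound, ">=")
    else:
        bound = z * (1.0 + epsilon)
        problem.add_inequality(dict(objective.coefficients), bound)
        locked = LockedConstraint(dict(objective.coefficients), bound, "<=")
    return locked


def parsimonious_solve(problem: LinearProblem, model: MetabolicModel | None = None,
                       weight_by_mw: bool = False) -> FluxSolution:
    """Minimise total flux + enzyme usage over the locked polytope."""
    return solve_lp(problem, parsimony_objective(problem, model, weight_by_mw))


def run_stages(problem: LinearProblem, model: MetabolicModel,
               strategy: OptimizationStrategy, weighted_sums: bool = True):
    """Run all optimisation stages on a prepared problem.

    Returns ``(solution, problem)`` where ``problem`` carries the locked
    constraints of every completed stage (the ageing loop re-solves over it
    after the regulation step). ``solution.stage_values`` records one achieved
    value per optimisation performed.
    """
    obj1 = make_objective(model, strategy.first, weighted=weighted_sums)
    sol = solve_lp(problem, obj1)
    if not sol.optimal:
        return sol, problem
    stage_values = [sol.stage_values[0]]
    labels = [strategy.first]
    lock_stage(problem, obj1, stage_values[0], max(strategy.epsilon1, PRECISION_EPS))

    if strategy.second is not None:
        obj2 = make_objective(model, strategy.second, weighted=weighted_sums)
        sol2 = solve_lp(problem, obj2)
        if not sol2.optimal:  # cannot happen if lock_stage is correct
            raise RuntimeError(
                f"stage 2 became {sol2.status} after locking stage 1"
            )
        sol = sol2
        stage_values.append(sol2.stage_values[0])
        labels.append(strategy.second)

    if strategy.parsimonious:
        if strategy.second is not None:
            obj2 = make_objective(model, strategy.second, weighted=weighted_sums)
            lock_stage(problem, obj2, stage_values[-1], PRECISION_EPS)
        sol_p = parsimonious_solve(problem, model)
        if not sol_p.optimal:
            raise RuntimeError(
                f"parsimonious stage became {sol_p.status} after locking"
            )
        sol = sol_p
        stage_values.append(sol_p.stage_values[0])
        labels.append(PARSIMONY_LABEL)

    sol.stage_values = stage_values
    sol.objective_labels = labels
    return sol, problem


def lexicographic_solve(model: MetabolicModel, strategy: OptimizationStrategy,
                        problem: LinearProblem | None = None,
                        weighted_sums: bool = True) -> FluxSolution:
    """Solve the full optimisation strategy on a model.

    Stage 1 is the enzyme-constrained LP under the first objective; stage 2
    (if any) runs with stage 1 locked at flexibility ``epsilon1``; the
    parsimonious stage (if requested) runs with the preceding stage locked at
    solver precision. Stage-1 infeasibility is propagated (the ageing module
    interprets it as cell death).
    """
    if problem is None:
        problem = build_lp(model)
    sol, _ = run_stages(problem, model, strategy, weighted_sums=weighted_sums)
    return sol
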