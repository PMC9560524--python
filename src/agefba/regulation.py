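"""Simplified pluggable stand-in for the nutrient/stress signalling layer.

Five canonical yeast signalling pathways (Snf1, PKA, TOR, Yap1, Sln1) are
represented as Booleans updated synchronously from inputs derived from the
current optimal flux distribution (glucose uptake, respiratory ATP share,
unneutralised ROS). Active pathways then tighten the usage bounds of their
target enzymes around the current optimum by a multiplicative regulation
factor, before the final epsilon2-relaxed re-optimisation.

The default rule table is a deliberately minimal stand-in (glucose represses
Snf1 and activates PKA/TOR; oxidative stress activates Yap1; respiration
flags Sln1); arbitrary rule tables, thresholds and enzyme targets can be
supplied through the config so a published wiring can be dropped in.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .fluxes import net_ros_flux, respiratory_atp_share
from .model import FluxSolution, MetabolicModel
from .optimize import ConfigurationError

PATHWAYS = ("Snf1", "PKA", "TOR", "Yap1", "Sln1")

#: glucose represses respiration through PKA only while the cell is not
#: already substantially respiring: once maintenance demand forces
#: respiratory ATP production, repression is lifted (derepression under
#: energy stress), which keeps the regulated re-optimisation feasible
DEFAULT_RULES = {
    "Snf1": "not glucose_high",
    "PKA": "glucose_high and not respiring",
    "TOR": "glucose_high",
    "Yap1": "ros_high",
    "Sln1": "respiring",
}

#: strict (>) comparisons; boundary values evaluate to False
DEFAULT_THRESHOLDS = {"glucose_high": 0.05, "respiring": 0.4, "ros_high": 1e-4}


@dataclass
class RegulationState:
    pathway_activity: dict[str, bool] = field(
        default_factory=lambda: {p: False for p in PATHWAYS}
    )
    inputs: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in PATHWAYS:
            self.pathway_activity.setdefault(p, False)


@dataclass
class RegulationConfig:
    regulation_factor: float = 0.04  # reference value
    rules: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RULES))
    targets: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.regulation_factor <= 1.0:
            raise ConfigurationError("regulation_factor must lie in [0, 1]")
        for p in PATHWAYS:
            if p not in self.rules:
                raise ConfigurationError(f"missing rule for pathway {p!r}")


def default_targets(model: MetabolicModel) -> dict[str, list[tuple[str, str]]]:
    """Enzyme targets for the default rule set, inferred from pathway labels.

    PKA (glucose signalling) down-regulates the glucose-repressed reactions'
    enzymes (carbon entry into the TCA cycle when the model declares a
    ``glucose_repressed`` reaction set, all respiratory enzymes otherwise),
    Snf1 up-regulates the same set under glucose limitation and Yap1
    up-regulates antioxidant enzymes. TOR and Sln1 carry no metabolic
    targets here: forcing a minimum usage of the biomass machinery while
    glucose repression caps respiration would make the re-optimisation
    structurally infeasible (TOR's growth promotion is already implicit in
    the growth objective), and Sln1 is osmotic signalling.
    """
    repressed_rxns = set(model.reaction_sets.get("glucose_repressed", []))
    repressed, antioxidant = [], []
    for enz in model.enzymes:
        pathways = {model.reaction(rid).pathway for rid in enz.kcat}
        if repressed_rxns:
            if repressed_rxns & set(enz.kcat):
                repressed.append(enz.id)
        elif pathways & {"tca", "oxidative phosphorylation"}:
            repressed.append(enz.id)
        if pathways & {"oxidative stress"}:
            antioxidant.append(enz.id)
    return {
        "PKA": [(eid, "down") for eid in repressed],
        "Snf1": [(eid, "up") for eid in repressed],
        "Yap1": [(eid, "up") for eid in antioxidant],
        "TOR": [],
        "Sln1": [],
    }


def derive_inputs(model: MetabolicModel, solution: FluxSolution,
                  thresholds: dict[str, float] | None = None) -> dict[str, bool]:
    """Boolean inputs for the rule layer, read off the optimal fluxes."""
    if not solution.optimal:
        raise ValueError("inputs require an optimal solution")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    glucose = solution.v.get(model.named("glucose_uptake"), 0.0)
    share = respiratory_atp_share(model, solution)
    ros = net_ros_flux(model, solution)
    return {
        "glucose_high": glucose > thr["glucose_high"],
        "respiring": share > thr["respiring"],
        "ros_high": ros > thr["ros_high"],
    }


def update_state(state: RegulationState, inputs: dict[str, bool],
                 config: RegulationConfig) -> RegulationState:
    """Synchronous Boolean update of all five pathways from the rule table."""
    env = dict(inputs)
    activity = {}
    for pathway in PATHWAYS:
        rule = config.rules.get(pathway)
        if rule is None:
            raise ConfigurationError(f"undefined rule for pathway {pathway!r}")
        try:
            activity[pathway] = bool(eval(rule, {"__builtins__": {}}, env))  # noqa: S307
        except NameError as exc:
            raise ConfigurationError(
                f"rule for {pathway!r} references an undeclared input: {exc}"
            ) from exc
    return RegulationState(pathway_activity=activity, inputs=dict(inputs))


def constrain_enzymes(model: MetabolicModel, state: RegulationState,
                      config: RegulationConfig, solution: FluxSolution,
                      pool_bound: float | None = None
                      ) -> dict[str, tuple[float, float]]:
    """Adjusted (e_min, e_max) per targeted enzyme of an active pathway.

    down: ``e_max := e* (1 - factor)``; up: ``e_min := e* (1 + factor)``
    capped at the feasible level (the pool and, because usage is coupled to
    flux, the usage attainable under the reactions' flux bounds — without
    the latter, up-regulating an enzyme whose reaction runs at capacity
    would force an unsatisfiable minimum usage). With
    ``regulation_factor == 0`` or no active pathway, no bounds are touched
    (identity).
    """
    factor = config.regulation_factor
    if factor == 0.0:
        return {}
    cap_pool = model.pool_bound if pool_bound is None else pool_bound
    adjustments: dict[str, tuple[float, float]] = {}
    for pathway, active in state.pathway_activity.items():
        if not active:
            continue
        for eid, direction in config.targets.get(pathway, []):
            e_star = solution.e.get(eid, 0.0)
            enz = model.enzyme(eid)
            lo, hi = adjustments.get(eid, (enz.lower_bound, enz.upper_bound))
            if direction == "down":
                hi = min(hi, e_star * (1.0 - factor))
            elif direction == "up":
                cap_flux = sum(
                    enz.subunits(rid) / kcat
                    * model.reaction(rid).upper_bound
                    for rid, kcat in enz.kcat.items())
                lo = max(lo, min(e_star * (1.0 + factor),
                                 cap_pool / enz.MW, cap_flux))
            else:
                raise ConfigurationError(f"bad regulation direction {direction!r}")
            if lo > hi:
                warnings.warn(
                    f"inconsistent regulated bounds for enzyme {eid}; clamping",
                    stacklevel=2,
                )
                lo = hi
            adjustments[eid] = (lo, hi)
    return adjustments
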