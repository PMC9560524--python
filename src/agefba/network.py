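"""Generator of miniature enzyme-constrained central-carbon networks.

The generated network is a deliberately small stand-in for a yeast central
carbon metabolism with the features that matter for replicative-ageing
simulations: a glucose exchange with a transporter, a glycolysis chain to
pyruvate (with an isoenzyme pair on the first step), a redox-neutral
fermentation branch (cheap enzymes, low ATP yield), a respiration branch
(mitochondrial pyruvate transport + lumped TCA + oxidative phosphorylation;
expensive enzymes, high ATP yield, ROS formation proportional to
respiratory flux), an anaplerotic bypass, an oxidative-stress pathway
(catalase-like and glutathione-like neutralisation with bounded capacity,
plus an uncatalysed sink representing ROS left free to damage proteins), a
biomass reaction drawing precursors from glycolysis and the TCA cycle, and
an NGAM reaction.

Because fermentation is the enzyme-cheaper way to make ATP while the TCA
cycle is the only source of a biomass precursor, a growth-maximising cell
ferments (Crabtree-like overflow) yet necessarily respires in proportion to
growth, which ties ROS formation - and hence ageing - to the metabolism.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ageing import DamageParameters
from .model import MetabolicModel, validate_model
from .optimize import OptimizationStrategy
from .simulate import (
    WILDTYPE_GENERATION_TIME,
    WILDTYPE_RLS,
    simulate_lifespan,
)


class GenerationError(ValueError):
    """The preset produced an invalid model."""


class CalibrationError(RuntimeError):
    """The calibration search exhausted its budget."""


@dataclass
class NetworkPreset:
    """Parameters of the miniature network.

    Enzyme costs are per-flux enzyme mass demands (MW/kcat, g h/mmol);
    respiration must be less enzyme-efficient per ATP than fermentation
    while yielding more ATP per glucose, which is what makes fermentative
    overflow emerge under a growth objective.
    """

    name: str = "wildtype"
    n_glycolysis_steps: int = 3
    n_tca_steps: int = 3
    fermentation_atp_yield: float = 2.0  # net ATP per glucose
    respiration_atp_yield: float = 22.0  # ATP per fully oxidised glucose
    ros_per_respiration: float = 0.2  # ROS per unit oxidative-phosphorylation flux
    antioxidant_capacity: float = 0.025  # flux bound per antioxidant reaction
    fermentation_capacity: float = 0.5  # flux bound on the fermentation branch
    enzyme_cost_fermentation: float = 0.010  # g h/mmol per glycolytic step
    enzyme_cost_respiration: float = 0.080  # g h/mmol per respiratory step
    # biomass composition (per unit of growth flux)
    biomass_g6p: float = 0.3
    biomass_pyr: float = 0.3
    biomass_akg: float = 0.15
    biomass_atp: float = 2.0
    biomass_enzyme_cost: float = 0.12
    sigma: float = 0.5
    f: float = 0.5
    P_tot: float = 0.4  # g/gDW
    kcat_jitter: float = 0.2  # +-20 % perturbation of kcat and MW
    seed: int = 42

    def __post_init__(self) -> None:
        if self.respiration_atp_yield <= self.fermentation_atp_yield:
            raise GenerationError(
                "respiration must yield more ATP per glucose than fermentation")
        if self.enzyme_cost_respiration <= self.enzyme_cost_fermentation:
            raise GenerationError(
                "respiration must be less enzyme-efficient than fermentation")
        if self.n_glycolysis_steps < 2 or self.n_tca_steps < 3:
            raise GenerationError("need >=2 glycolysis and >=3 TCA steps")


def _enzyme_entry(rng, name, mw, cost, rxns, n=1.0, jitter=0.2):
    """Enzyme dict with kcat = n*MW/cost, jittered around the nominal mean."""
    mw_eff = mw * (1.0 + jitter * (2.0 * rng.random() - 1.0))
    kcat_nominal = n * mw_eff / cost
    kcat_eff = kcat_nominal * (1.0 + jitter * (2.0 * rng.random() - 1.0))
    return {
        "id": name,
        "MW": round(mw_eff, 6),
        "kcat": {rid: round(kcat_eff, 6) for rid in rxns},
        "n": {rid: n for rid in rxns} if n != 1.0 else {},
        "lower_bound": 0.0,
        "upper_bound": None,
    }


def generate(preset: NetworkPreset) -> MetabolicModel:
    """Build the model; deterministic for a given preset (incl. seed)."""
    rng = np.random.default_rng(preset.seed)
    jit = preset.kcat_jitter
    k_glyc = preset.n_glycolysis_steps
    k_tca = preset.n_tca_steps
    cf = preset.enzyme_cost_fermentation
    cr = preset.enzyme_cost_respiration

    mets = [
        {"id": "glc", "name": "glucose", "compartment": "c"},
        *({"id": f"gly{i}", "name": f"glycolytic intermediate {i}",
           "compartment": "c"} for i in range(1, k_glyc)),
        {"id": "pyr", "name": "pyruvate", "compartment": "c"},
        {"id": "pyr_m", "name": "mitochondrial pyruvate", "compartment": "m"},
        *({"id": f"tca{i}", "name": f"TCA intermediate {i}",
           "compartment": "m"} for i in range(1, k_tca - 1)),
        {"id": "akg", "name": "alpha-ketoglutarate", "compartment": "m"},
        {"id": "etoh", "name": "ethanol", "compartment": "c"},
        {"id": "atp", "name": "ATP", "compartment": "c"},
        {"id": "nadh", "name": "NADH", "compartment": "c"},
        {"id": "o2", "name": "oxygen", "compartment": "c"},
        {"id": "ros", "name": "reactive oxygen species", "compartment": "c"},
    ]

    rxns: list[dict] = []
    enzymes: list[dict] = []

    def rxn(id, stoich, pathway, lb=0.0, ub=None, name="", parent=None, group=None):
        rxns.append({
            "id": id, "name": name, "stoich": stoich, "lower_bound": lb,
            "upper_bound": ub, "pathway": pathway,
            "reversible_parent": parent, "isoenzyme_group": group,
        })

    # exchanges -------------------------------------------------------------
    rxn("EX_glc", {"glc": 1.0}, "exchange", name="glucose uptake")
    enzymes.append(_enzyme_entry(rng, "E_hxt", 60.0, 1.5 * cf, ["EX_glc"], jitter=jit))
    rxn("EX_o2", {"o2": 1.0}, "exchange", name="oxygen uptake")
    rxn("EX_etoh", {"etoh": -1.0}, "exchange", name="ethanol export")

    # glycolysis ------------------------------------------------------------
    # two ATP-investment steps (one when the chain is minimal), then a payoff
    # step producing 2 pyruvate + 2 NADH; net ATP equals the fermentation yield
    invest = 2.0 if k_glyc >= 3 else 1.0
    step_mets = ["glc"] + [f"gly{i}" for i in range(1, k_glyc)]
    for i in range(k_glyc - 1):
        stoich = {step_mets[i]: -1.0, step_mets[i + 1]: 1.0}
        if i < invest:
            stoich["atp"] = -1.0
        rid = f"GLY{i + 1}"
        if i == 0:  # isoenzyme pair on the first (hexokinase-like) step
            for iso, cost in (("a", cf), ("b", 0.9 * cf)):
                rxn(f"{rid}{iso}", dict(stoich), "glycolysis", group=rid,
                    name=f"glycolysis step {i + 1} isoenzyme {iso}")
                enzymes.append(_enzyme_entry(
                    rng, f"E_gly{i + 1}{iso}", 55.0, cost,
                    [f"{rid}{iso}"], jitter=jit))
        else:
            rxn(rid, stoich, "glycolysis", name=f"glycolysis step {i + 1}")
            enzymes.append(_enzyme_entry(
                rng, f"E_gly{i + 1}", 60.0, cf, [rid], jitter=jit))
    payoff_atp = preset.fermentation_atp_yield + invest
    rxn("PYK", {step_mets[-1]: -1.0, "pyr": 2.0, "atp": payoff_atp, "nadh": 2.0},
        "glycolysis", name="lower glycolysis payoff")
    enzymes.append(_enzyme_entry(rng, "E_pyk", 120.0, 2.0 * cf, ["PYK"], jitter=jit))

    # fermentation (redox-neutral: consumes the glycolytic NADH) ------------
    # the bounded capacity is what pushes the ageing cell, whose maintenance
    # demand keeps rising, toward respiration late in life
    rxn("PDC_ADH", {"pyr": -1.0, "nadh": -1.0, "etoh": 1.0}, "fermentation",
        ub=preset.fermentation_capacity,
        name="pyruvate decarboxylase + alcohol dehydrogenase")
    enzymes.append(_enzyme_entry(rng, "E_adh", 90.0, 1.2 * cf, ["PDC_ADH"], jitter=jit))

    # mitochondrial transport (reversible; split at load time) --------------
    rxn("MPC", {"pyr": -1.0, "pyr_m": 1.0}, "mitochondrial transport",
        lb=-1000.0, ub=1000.0, name="mitochondrial pyruvate carrier")
    enzymes.append(_enzyme_entry(rng, "E_mpc", 40.0, 0.4 * cf, ["MPC"], jitter=jit))

    # TCA chain: PDH -> CIT(-> akg) -> ... -> terminal oxidation ------------
    tca_mets = (["pyr_m"] + [f"tca{i}" for i in range(1, k_tca - 1)] + ["akg"])
    tca_ids = []
    for i in range(k_tca - 1):
        rid = "PDH" if i == 0 else f"TCA{i + 1}"
        rxn(rid, {tca_mets[i]: -1.0, tca_mets[i + 1]: 1.0, "nadh": 1.0}, "tca",
            name="pyruvate dehydrogenase (lumped)" if i == 0 else f"TCA step {i + 1}")
        enzymes.append(_enzyme_entry(
            rng, f"E_{rid.lower()}", 200.0, cr, [rid], jitter=jit))
        tca_ids.append(rid)
    rxn("AKGOX", {"akg": -1.0, "nadh": 2.0, "atp": 1.0}, "tca",
        name="terminal oxidation of alpha-ketoglutarate (lumped)")
    enzymes.append(_enzyme_entry(rng, "E_akgox", 150.0, cr, ["AKGOX"], jitter=jit))
    tca_ids.append("AKGOX")

    # oxidative phosphorylation --------------------------------------------
    # P/O chosen so that full oxidation of glucose attains the preset yield:
    # yield = ferm_yield + 2 (substrate-level TCA) + p * NADH_per_glucose
    nadh_per_glc = 2.0 + 2.0 * (k_tca + 1.0)
    p_ratio = ((preset.respiration_atp_yield - preset.fermentation_atp_yield - 2.0)
               / nadh_per_glc)
    if p_ratio <= 0:
        raise GenerationError("respiration yield too low for a positive P/O ratio")
    rxn("ETC", {"nadh": -1.0, "o2": -0.5, "atp": p_ratio,
                "ros": preset.ros_per_respiration},
        "oxidative phosphorylation", name="electron transport chain (lumped)")
    enzymes.append(_enzyme_entry(rng, "E_etc", 200.0, cr, ["ETC"], n=2.0, jitter=jit))

    # anaplerotic bypass (ATP-costly AKG source, normally dormant) ----------
    rxn("PYC", {"pyr_m": -1.0, "atp": -3.0, "akg": 1.0}, "anaplerotic",
        name="anaplerotic alpha-ketoglutarate synthesis")
    enzymes.append(_enzyme_entry(rng, "E_pyc", 130.0, 2.0 * cr, ["PYC"], jitter=jit))

    # oxidative stress ------------------------------------------------------
    rxn("CTT1", {"ros": -2.0, "o2": 0.5}, "oxidative stress",
        ub=preset.antioxidant_capacity, name="catalase-like ROS dismutation")
    enzymes.append(_enzyme_entry(rng, "E_cat", 60.0, 0.15 * cf, ["CTT1"], jitter=jit))
    rxn("GPX", {"ros": -1.0, "nadh": -1.0}, "oxidative stress",
        ub=preset.antioxidant_capacity, name="glutathione-like ROS reduction")
    enzymes.append(_enzyme_entry(rng, "E_gpx", 50.0, 3.0 * cf, ["GPX"], jitter=jit))
    rxn("ROS_SINK", {"ros": -1.0}, "oxidative stress",
        name="unneutralised ROS (protein-damaging)")

    # biomass and maintenance ----------------------------------------------
    rxn("BIOMASS",
        {"gly1" if k_glyc >= 2 else "glc": -preset.biomass_g6p,
         "pyr": -preset.biomass_pyr, "akg": -preset.biomass_akg,
         "atp": -preset.biomass_atp},
        "biomass", name="biomass synthesis")
    enzymes.append(_enzyme_entry(
        rng, "E_rib", 2000.0, preset.biomass_enzyme_cost, ["BIOMASS"], jitter=jit))
    rxn("NGAM", {"atp": -1.0}, "maintenance",
        name="non-growth associated maintenance")

    atp_producing = ["PYK", "AKGOX", "ETC"]
    nadh_producing = ["PYK"] + tca_ids[:-1] + ["AKGOX"]
    data = {
        "metabolites": mets,
        "reactions": rxns,
        "enzymes": enzymes,
        "pool": {"sigma": preset.sigma, "f": preset.f, "P_tot": preset.P_tot},
        "named_reactions": {
            "biomass": "BIOMASS", "glucose_uptake": "EX_glc", "ngam": "NGAM",
        },
        "reaction_sets": {
            "atp_producing": atp_producing,
            "nadh_producing": nadh_producing,
            "ros_producing": ["ETC"],
            "antioxidant": ["CTT1", "GPX"],
            # carbon entry into the TCA cycle: the steps subject to glucose
            # repression (terminal oxidation and the respiratory chain are
            # exempt so that repression never conflicts with the hard
            # maintenance requirement)
            "glucose_repressed": tca_ids[:-1],
        },
    }
    model = MetabolicModel.from_dict(data)
    issues = validate_model(model)
    if issues:
        raise GenerationError("generated model is invalid: " + "; ".join(issues))
    return model


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_wildtype(preset: NetworkPreset, ageing_params: DamageParameters,
                       strategy: OptimizationStrategy,
                       regulation_config=None,
                       rls_window: tuple[int, int] = WILDTYPE_RLS,
                       gt_window: tuple[float, float] = WILDTYPE_GENERATION_TIME,
                       budget: int = 40, max_time: float = 200.0):
    """Search ageing parameters until the simulated cell is a wildtype.

    Coordinate search over (division_biomass, f_m): the generation-time
    window is centred first by scaling the biomass threshold against the
    observed mean generation time, then the division count is steered by
    scaling the metabolic damage rate (more damage -> fewer divisions).
    ``retention`` and ``ngam_slope`` are honoured as given. Returns the
    calibrated ``(preset, ageing_params)``; raises CalibrationError with the
    best attempt in the message if the budget is exhausted.
    """
    model = generate(preset)
    params = replace(ageing_params)
    best = None
    gt_target = 0.5 * (gt_window[0] + gt_window[1])
    rls_target = (0.5 * (rls_window[0] + rls_window[1])
                  if np.isfinite(rls_window[1]) else rls_window[0] + 5.0)
    for _ in range(budget):
        result = simulate_lifespan(model, strategy, params,
                                   regulation_config=regulation_config,
                                   max_time=max_time)
        ok_rls = rls_window[0] <= result.rls <= rls_window[1]
        ok_gt = (result.generation_times
                 and gt_window[0] <= result.mean_generation_time <= gt_window[1])
        score = abs(result.rls - rls_target)
        if best is None or score < best[0]:
            best = (score, result.rls, result.mean_generation_time,
                    replace(params))
        if ok_rls and ok_gt:
            return preset, params
        if result.generation_times and not ok_gt:
            # scale the division threshold toward the target generation time
            params = replace(
                params,
                division_biomass=params.division_biomass
                * gt_target / result.mean_generation_time)
            continue
        if not result.generation_times:
            params = replace(params, division_biomass=params.division_biomass * 0.5)
            continue
        # steer the division count through the metabolic damage rate
        ratio = result.rls / rls_target
        factor = min(max(ratio, 0.3), 3.0)
        params = replace(params, f_m=max(params.f_m, 1e-6) * factor)
    raise CalibrationError(
        f"calibration budget exhausted; best attempt rls={best[1]}, "
        f"mean generation time={best[2]:.3f} h with {best[3]}")
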