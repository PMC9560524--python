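"""Flux-distribution analytics: collapse of split/isoenzyme reactions,
glucose normalisation, phase averaging and the relative-change statistic
used to compare non-parsimonious against parsimonious solutions.

The relative change of flux ``i`` between a baseline ``v`` and an
alternative ``v_p`` is ``delta_i = |v_p_i - v_i| / |v_i|``. A flux that is
switched off (``v_i != 0``, ``v_p_i = 0``) is classified as decreased with
``delta = 1``; a flux switched on from zero is undefined under the formula
and reported in a separate class rather than given an arbitrary value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    FluxSolution,
    MetabolicModel,
    total_consumption_flux,
    total_production_flux,
)

#: relative tie tolerance below which a change counts as "unchanged"
TIE_TOL = 1e-6


@dataclass
class CollapsedFluxVector:
    """Signed fluxes after merging split directions and isoenzyme groups."""

    values: dict[str, float]
    pathway: dict[str, str] = field(default_factory=dict)

    def normalized(self, glucose_uptake: float) -> "CollapsedFluxVector":
        return normalize_by_glucose(self, glucose_uptake)


@dataclass
class FluxChange:
    delta: dict[str, float]  # defined entries only, all >= 0
    direction_class: dict[str, str]  # increased | unchanged | decreased | switched_on
    undefined: set[str] = field(default_factory=set)
    pathway: dict[str, str] = field(default_factory=dict)


def _collapsed_layout(model: MetabolicModel):
    """Mapping collapsed-id -> [(reaction id, sign)], plus pathway labels."""
    layout: dict[str, list[tuple[str, float]]] = {}
    pathway: dict[str, str] = {}
    for r in model.reactions:
        if r.reversible_parent is not None:
            cid = r.reversible_parent
            sign = -1.0 if r.id.endswith("__bwd") else 1.0
        elif r.isoenzyme_group is not None:
            cid, sign = r.isoenzyme_group, 1.0
        else:
            cid, sign = r.id, 1.0
        layout.setdefault(cid, []).append((r.id, sign))
        if cid in pathway and pathway[cid] != r.pathway:
            raise ValueError(
                f"inconsistent pathway labels within collapsed group {cid!r}"
            )
        pathway[cid] = r.pathway
    return layout, pathway


def collapse(model: MetabolicModel, solution) -> CollapsedFluxVector:
    """Merge forward/backward split pairs (fwd - bwd) and sum isoenzymes.

    ``solution`` may be a FluxSolution, a mapping reaction-id -> flux or an
    already-collapsed vector (the operation is idempotent).
    """
    if isinstance(solution, CollapsedFluxVector):
        fluxes = solution.values
    elif isinstance(solution, FluxSolution):
        fluxes = solution.v
    else:
        fluxes = dict(solution)
    layout, pathway = _collapsed_layout(model)
    values: dict[str, float] = {}
    for cid, members in layout.items():
        if all(rid not in fluxes for rid, _ in members) and cid in fluxes:
            values[cid] = float(fluxes[cid])  # already collapsed
        else:
            values[cid] = float(sum(sign * fluxes.get(rid, 0.0) for rid, sign in members))
    return CollapsedFluxVector(values=values, pathway=pathway)


def relative_change(v: CollapsedFluxVector, v_p: CollapsedFluxVector,
                    tie_tol: float = TIE_TOL) -> FluxChange:
    """Per-flux relative change between a baseline and an alternative."""
    if set(v.values) != set(v_p.values):
        raise ValueError("flux vectors cover different collapsed reactions")
    delta: dict[str, float] = {}
    direction: dict[str, str] = {}
    undefined: set[str] = set()
    for cid, base in v.values.items():
        alt = v_p.values[cid]
        if base == 0.0 and alt == 0.0:
            delta[cid], direction[cid] = 0.0, "unchanged"
        elif base == 0.0:
            undefined.add(cid)  # switched on: formula undefined
            direction[cid] = "switched_on"
        elif alt == 0.0:
            delta[cid], direction[cid] = 1.0, "decreased"
        else:
            d = abs(alt - base) / abs(base)
            delta[cid] = d
            if d <= tie_tol:
                direction[cid] = "unchanged"
            else:
                # direction on signed (normalised) fluxes
                direction[cid] = "increased" if alt > base else "decreased"
    return FluxChange(delta=delta, direction_class=direction,
                      undefined=undefined, pathway=dict(v.pathway))


def normalize_by_glucose(v: CollapsedFluxVector, glucose_uptake: float
                         ) -> CollapsedFluxVector:
    """Divide every flux by the glucose uptake rate.

    Zero uptake leaves every entry undefined (NaN) so downstream averages
    can exclude the time point.
    """
    if glucose_uptake < 0:
        raise ValueError("glucose uptake must be non-negative")
    if glucose_uptake == 0.0:
        values = {cid: math.nan for cid in v.values}
    else:
        values = {cid: x / glucose_uptake for cid, x in v.values.items()}
    return CollapsedFluxVector(values=values, pathway=dict(v.pathway))


def phase_average(trajectory: pd.DataFrame, phase_boundary: float,
                  model: MetabolicModel | None = None,
                  normalize: bool = False,
                  glucose_column: str | None = None,
                  time_column: str = "t",
                  time_weighted: bool = True):
    """Mean of each flux column within phase I / phase II.

    ``trajectory`` holds one row per time step with a time column and one
    column per reaction flux (``v_<rid>``). With ``normalize=True`` each row
    is first divided by its glucose uptake (rows with zero uptake are
    excluded). Averages are time-weighted by default (an unweighted per-step
    variant is available). Returns a pair of ``CollapsedFluxVector`` when a
    model is given, otherwise a pair of pandas Series.
    """
    t = trajectory[time_column].to_numpy()
    if not (t[0] <= phase_boundary <= t[-1]):
        raise ValueError("phase boundary outside trajectory span")
    flux_cols = [c for c in trajectory.columns if c.startswith("v_")]
    data = trajectory[flux_cols].copy()
    if normalize:
        if glucose_column is None:
            raise ValueError("normalize=True requires glucose_column")
        uptake = trajectory[glucose_column].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            data = data.div(pd.Series(uptake, index=data.index), axis=0)
        data[uptake == 0.0] = np.nan

    if time_weighted:
        dt = np.diff(t, append=t[-1] + (t[-1] - t[-2] if len(t) > 1 else 1.0))
        weights = pd.Series(dt, index=data.index)
    else:
        weights = pd.Series(1.0, index=data.index)

    def _mean(mask) -> pd.Series:
        if not mask.any():
            return pd.Series(np.nan, index=flux_cols)
        sub, w = data[mask], weights[mask]
        out = {}
        for col in flux_cols:
            vals = sub[col]
            ok = vals.notna()
            out[col] = (
                float((vals[ok] * w[ok]).sum() / w[ok].sum()) if ok.any() else np.nan
            )
        return pd.Series(out)

    phase1 = _mean(pd.Series(t <= phase_boundary, index=data.index))
    phase2 = _mean(pd.Series(t > phase_boundary, index=data.index))
    if model is None:
        return phase1, phase2
    out = []
    for series in (phase1, phase2):
        fluxes = {c[2:]: series[c] for c in flux_cols}
        out.append(collapse(model, fluxes))
    return tuple(out)


def classify_and_tabulate(changes: FluxChange,
                          pathways: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-pathway summary of a FluxChange.

    Columns: fractions of defined fluxes increased / unchanged / decreased,
    quartiles of the delta distribution, fraction with delta > 1 and the
    count of switched-on (undefined) fluxes.
    """
    pathways = pathways if pathways is not None else changes.pathway
    rows = []
    for pw in sorted(set(pathways.values())):
        ids = [cid for cid, p in pathways.items() if p == pw]
        defined = [cid for cid in ids if cid in changes.delta]
        deltas = np.array([changes.delta[cid] for cid in defined])
        n = len(defined)
        counts = {
            cls: sum(changes.direction_class.get(cid) == cls for cid in defined)
            for cls in ("increased", "unchanged", "decreased")
        }
        rows.append({
            "pathway": pw,
            "n": n,
            "frac_increased": counts["increased"] / n if n else np.nan,
            "frac_unchanged": counts["unchanged"] / n if n else np.nan,
            "frac_decreased": counts["decreased"] / n if n else np.nan,
            "delta_q1": float(np.percentile(deltas, 25)) if n else np.nan,
            "delta_median": float(np.percentile(deltas, 50)) if n else np.nan,
            "delta_q3": float(np.percentile(deltas, 75)) if n else np.nan,
            "frac_delta_gt_1": float(np.mean(deltas > 1.0)) if n else np.nan,
            "n_switched_on": sum(cid in changes.undefined for cid in ids),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers shared with the regulation and ageing layers
# ---------------------------------------------------------------------------

def ros_production(model: MetabolicModel, solution: FluxSolution,
                   ros_id: str = "ros") -> float:
    """Zero for models without an oxidative-stress pathway."""
    rids = model.reaction_sets.get("ros_producing", [])
    if not rids:
        return 0.0
    return total_production_flux(model, ros_id, solution, reactions=rids)


def antioxidant_neutralization(model: MetabolicModel, solution: FluxSolution,
                               ros_id: str = "ros") -> float:
    rids = model.reaction_sets.get("antioxidant", [])
    if not rids:
        return 0.0
    return total_consumption_flux(model, ros_id, solution, reactions=rids)


def net_ros_flux(model: MetabolicModel, solution: FluxSolution,
                 ros_id: str = "ros") -> float:
    """Unneutralised ROS flux: production minus antioxidant consumption,
    floored at zero (the quantity that drives metabolic protein damage)."""
    net = (ros_production(model, solution, ros_id)
           - antioxidant_neutralization(model, solution, ros_id))
    return max(net, 0.0)


RESPIRATORY_PATHWAYS = {"tca", "oxidative phosphorylation"}


def respiratory_atp_share(model: MetabolicModel, solution: FluxSolution,
                          atp_id: str = "atp") -> float:
    """Fraction of total ATP production carried by respiratory pathways
    (zero for models without an ATP metabolite)."""
    if atp_id not in model._met_index:
        return 0.0
    total = total_production_flux(model, atp_id, solution)
    if total <= 0:
        return 0.0
    resp_rids = [r.id for r in model.reactions if r.pathway in RESPIRATORY_PATHWAYS]
    resp = total_production_flux(model, atp_id, solution, reactions=resp_rids)
    return resp / total
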