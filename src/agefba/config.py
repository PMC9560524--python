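"""YAML config loading for strategies, regulation and ageing parameters.

A run config is a single YAML document with (any of) the blocks::

    strategy:
      first: max_growth
      second: max_ngam        # or null
      epsilon1: 0.3
      epsilon2: 0.05
      parsimonious: true
    regulation:
      regulation_factor: 0.04
      thresholds: {glucose_high: 0.05, respiring: 0.2, ros_high: 0.0001}
      rules: {Snf1: "not glucose_high", ...}
      targets: {PKA: [[E_pdh, down], ...], ...}
    ageing:
      f_m: 0.25
      f0: 0.0001
      r0: 0.0005
      retention: 0.52
      division_biomass: 0.6
      ngam0: 0.2
      ngam_slope: 2.5
      dt: 0.01
"""
from __future__ import annotations

import yaml

from .ageing import DamageParameters
from .optimize import OptimizationStrategy
from .regulation import DEFAULT_RULES, DEFAULT_THRESHOLDS, RegulationConfig


def strategy_from_dict(block: dict) -> OptimizationStrategy:
    return OptimizationStrategy(
        first=block["first"],
        second=block.get("second"),
        epsilon1=float(block.get("epsilon1", 0.0)),
        epsilon2=float(block.get("epsilon2", 0.0)),
        parsimonious=bool(block.get("parsimonious", False)),
    )


def regulation_from_dict(block: dict) -> RegulationConfig:
    rules = dict(DEFAULT_RULES)
    rules.update(block.get("rules", {}))
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(block.get("thresholds", {}))
    targets = {
        pathway: [(eid, direction) for eid, direction in entries]
        for pathway, entries in block.get("targets", {}).items()
    }
    return RegulationConfig(
        regulation_factor=float(block.get("regulation_factor", 0.04)),
        rules=rules,
        targets=targets,
        thresholds=thresholds,
    )


def ageing_from_dict(block: dict) -> DamageParameters:
    return DamageParameters(**{k: float(v) for k, v in block.items()})


def load_run_config(path):
    """Parse a run config file -> (strategy, regulation, ageing) tuple;
    missing blocks come back as None."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    strategy = strategy_from_dict(doc["strategy"]) if "strategy" in doc else None
    regulation = (regulation_from_dict(doc["regulation"])
                  if "regulation" in doc else None)
    ageing = ageing_from_dict(doc["ageing"]) if "ageing" in doc else None
    return strategy, regulation, ageing
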