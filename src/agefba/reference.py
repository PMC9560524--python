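"""The packaged calibrated reference cell.

``data/reference_model.json`` is a calibrated miniature central-carbon
network (see :mod:`agefba.network`) and ``data/reference_config.yaml`` the
matching strategy / regulation / ageing parameters. Simulated under the
parsimonious maximal-growth objective they yield a wildtype cell: 20-30
divisions with a mean generation time of 1.5-2.3 h.
"""
from __future__ import annotations

from importlib import resources

import yaml

from .ageing import DamageParameters
from .config import ageing_from_dict, regulation_from_dict, strategy_from_dict
from .model import MetabolicModel
from .optimize import OptimizationStrategy
from .regulation import RegulationConfig, default_targets

_DATA = resources.files("agefba") / "data"


def load_reference_model() -> MetabolicModel:
    return MetabolicModel.from_json((_DATA / "reference_model.json").read_text())


def load_reference() -> tuple[MetabolicModel, OptimizationStrategy,
                              RegulationConfig, DamageParameters]:
    """Load the calibrated reference bundle (model, strategy, regulation,
    ageing parameters)."""
    model = load_reference_model()
    doc = yaml.safe_load((_DATA / "reference_config.yaml").read_text())
    strategy = strategy_from_dict(doc["strategy"])
    regulation = regulation_from_dict(doc.get("regulation", {}))
    if not regulation.targets:
        regulation.targets = default_targets(model)
    ageing = ageing_from_dict(doc["ageing"])
    return model, strategy, regulation, ageing
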