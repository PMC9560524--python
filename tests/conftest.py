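"""Shared fixtures: hand-built toy models and the calibrated reference."""
from __future__ import annotations

import pytest

from agefba.model import Enzyme, MetabolicModel, Metabolite, Reaction
from agefba.reference import load_reference


def make_t1(pool: float = 5.0, kcat: float = 1.0) -> MetabolicModel:
    """Single metabolite X, uptake R_up in [0, 10], drain R_bio catalysed by
    E1 (kcat 1/h, MW 1 kDa), pool bound 5: pool-limited optimum v_bio = 5."""
    return MetabolicModel(
        metabolites=[Metabolite(id="X")],
        reactions=[
            Reaction(id="R_up", stoich={"X": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction(id="R_bio", stoich={"X": -1.0}),
        ],
        enzymes=[Enzyme(id="E1", MW=1.0, kcat={"R_bio": kcat})],
        sigma=1.0, f=1.0, P_tot=pool,
        named_reactions={"biomass": "R_bio", "glucose_uptake": "R_up"},
    )


def make_t2() -> MetabolicModel:
    """T1 plus a second drain R_ngam with a twice-as-fast enzyme; the two
    drains compete for the same pool of 5 g/gDW."""
    return MetabolicModel(
        metabolites=[Metabolite(id="X")],
        reactions=[
            Reaction(id="R_up", stoich={"X": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction(id="R_bio", stoich={"X": -1.0}),
            Reaction(id="R_ngam", stoich={"X": -1.0}),
        ],
        enzymes=[
            Enzyme(id="E_bio", MW=1.0, kcat={"R_bio": 1.0}),
            Enzyme(id="E_ngam", MW=1.0, kcat={"R_ngam": 2.0}),
        ],
        sigma=1.0, f=1.0, P_tot=5.0,
        named_reactions={"biomass": "R_bio", "glucose_uptake": "R_up",
                         "ngam": "R_ngam"},
    )


def make_parallel_routes() -> MetabolicModel:
    """Two redundant routes X -> Y; R_cheap needs half the enzyme of R_dear.
    Used to check that parsimony picks the enzyme-cheaper route."""
    return MetabolicModel(
        metabolites=[Metabolite(id="X"), Metabolite(id="Y")],
        reactions=[
            Reaction(id="R_up", stoich={"X": 1.0}, upper_bound=10.0),
            Reaction(id="R_cheap", stoich={"X": -1.0, "Y": 1.0}),
            Reaction(id="R_dear", stoich={"X": -1.0, "Y": 1.0}),
            Reaction(id="R_out", stoich={"Y": -1.0}),
        ],
        enzymes=[
            Enzyme(id="E_cheap", MW=1.0, kcat={"R_cheap": 2.0}),
            Enzyme(id="E_dear", MW=1.0, kcat={"R_dear": 1.0}),
            Enzyme(id="E_out", MW=1.0, kcat={"R_out": 4.0}),
        ],
        sigma=1.0, f=1.0, P_tot=5.0,
        named_reactions={"biomass": "R_out", "glucose_uptake": "R_up"},
    )


@pytest.fixture
def t1() -> MetabolicModel:
    return make_t1()


@pytest.fixture
def t2() -> MetabolicModel:
    return make_t2()


@pytest.fixture
def parallel_routes() -> MetabolicModel:
    return make_parallel_routes()


@pytest.fixture(scope="session")
def reference():
    """Calibrated reference bundle (model, strategy, regulation, ageing)."""
    return load_reference()


@pytest.fixture(scope="session")
def reference_lifespan(reference):
    """The reference cell's full lifespan simulation, shared across tests."""
    from agefba.simulate import simulate_lifespan

    model, strategy, regulation, ageing = reference
    return simulate_lifespan(model, strategy, ageing,
                             regulation_config=regulation)
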