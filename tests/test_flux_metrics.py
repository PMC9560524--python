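"""Collapse, relative change, glucose normalisation and phase averaging."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agefba.fluxes import (
    CollapsedFluxVector,
    classify_and_tabulate,
    collapse,
    normalize_by_glucose,
    phase_average,
    relative_change,
)
from agefba.model import Enzyme, MetabolicModel, Metabolite, Reaction


def make_collapsible_model() -> MetabolicModel:
    """A reversible transport (split on load) plus an isoenzyme pair."""
    data = MetabolicModel(
        metabolites=[Metabolite(id="X"), Metabolite(id="Y")],
        reactions=[
            Reaction(id="R_up", stoich={"X": 1.0}, upper_bound=10.0,
                     pathway="exchange"),
            Reaction(id="ISO1", stoich={"X": -1.0, "Y": 1.0},
                     isoenzyme_group="ISO", pathway="conversion"),
            Reaction(id="ISO2", stoich={"X": -1.0, "Y": 1.0},
                     isoenzyme_group="ISO", pathway="conversion"),
            Reaction(id="T", stoich={"Y": -1.0}, lower_bound=-5.0,
                     upper_bound=5.0, pathway="transport"),
        ],
        enzymes=[Enzyme(id="E", MW=1.0, kcat={"ISO1": 1.0, "ISO2": 1.0, "T": 1.0})],
        sigma=1.0, f=1.0, P_tot=100.0,
    ).to_dict()
    return MetabolicModel.from_dict(data)


class TestCollapse:
    def test_split_pair_merges_signed(self):
        model = make_collapsible_model()
        vec = collapse(model, {"T__fwd": 3.0, "T__bwd": 1.0, "R_up": 0.0,
                               "ISO1": 0.0, "ISO2": 0.0})
        assert vec.values["T"] == pytest.approx(2.0)
        assert vec.pathway["T"] == "transport"

    def test_isoenzymes_sum(self):
        model = make_collapsible_model()
        vec = collapse(model, {"ISO1": 1.0, "ISO2": 2.0, "R_up": 3.0,
                               "T__fwd": 3.0, "T__bwd": 0.0})
        assert vec.values["ISO"] == pytest.approx(3.0)

    def test_plain_model_identity(self, t2):
        vec = collapse(t2, {"R_up": 1.0, "R_bio": 0.5, "R_ngam": 0.5})
        assert vec.values == {"R_up": 1.0, "R_bio": 0.5, "R_ngam": 0.5}

    def test_idempotent(self):
        model = make_collapsible_model()
        raw = {"ISO1": 1.0, "ISO2": 2.0, "R_up": 3.0, "T__fwd": 3.0,
               "T__bwd": 0.5}
        once = collapse(model, raw)
        twice = collapse(model, once)
        assert twice.values == once.values


class TestRelativeChange:
    def _vec(self, **values):
        return CollapsedFluxVector(values=dict(values),
                                   pathway={k: "p" for k in values})

    def test_halving_gives_half(self):
        change = relative_change(self._vec(a=2.0), self._vec(a=1.0))
        assert change.delta["a"] == pytest.approx(0.5)
        assert change.direction_class["a"] == "decreased"

    def test_sign_flip_uses_absolute_values(self):
        change = relative_change(self._vec(a=-1.0), self._vec(a=1.0))
        assert change.delta["a"] == pytest.approx(2.0)
        assert change.direction_class["a"] == "increased"

    def test_identity_all_zero_and_unchanged(self):
        v = self._vec(a=2.0, b=-3.0, c=0.0)
        change = relative_change(v, v)
        assert all(d == 0.0 for d in change.delta.values())
        assert set(change.direction_class.values()) == {"unchanged"}

    def test_switched_off_is_decreased_with_delta_one(self):
        change = relative_change(self._vec(a=2.0), self._vec(a=0.0))
        assert change.delta["a"] == pytest.approx(1.0)
        assert change.direction_class["a"] == "decreased"

    def test_switched_on_is_flagged_undefined(self):
        change = relative_change(self._vec(a=0.0), self._vec(a=1.0))
        assert "a" not in change.delta
        assert "a" in change.undefined
        assert change.direction_class["a"] == "switched_on"

    def test_id_mismatch_raises(self):
        with pytest.raises(ValueError):
            relative_change(self._vec(a=1.0), self._vec(b=1.0))

    @given(base=st.floats(-10, 10), alt=st.floats(-10, 10))
    @settings(deadline=None, max_examples=100)
    def test_delta_non_negative_where_defined(self, base, alt):
        change = relative_change(self._vec(a=base), self._vec(a=alt))
        for d in change.delta.values():
            assert d >= 0.0


class TestNormalize:
    def test_division_by_uptake(self):
        vec = CollapsedFluxVector(values={"a": 4.0}, pathway={"a": "p"})
        assert normalize_by_glucose(vec, 2.0).values["a"] == pytest.approx(2.0)
        assert normalize_by_glucose(vec, 1.0).values["a"] == pytest.approx(4.0)

    def test_zero_uptake_flags_all(self):
        vec = CollapsedFluxVector(values={"a": 4.0, "b": 0.0},
                                  pathway={"a": "p", "b": "p"})
        out = normalize_by_glucose(vec, 0.0)
        assert all(math.isnan(x) for x in out.values.values())

    def test_normalise_denormalise_round_trip(self):
        vec = CollapsedFluxVector(values={"a": 4.0, "b": -1.0},
                                  pathway={"a": "p", "b": "p"})
        back = normalize_by_glucose(normalize_by_glucose(vec, 2.0), 0.5)
        for key in vec.values:
            assert back.values[key] == pytest.approx(vec.values[key])


class TestPhaseAverage:
    def _traj(self, t, flux, uptake=None):
        frame = pd.DataFrame({"t": t, "v_R": flux})
        if uptake is not None:
            frame["v_up"] = uptake
        return frame

    def test_constant_flux_equal_in_both_phases(self):
        traj = self._traj(np.arange(0, 4.0, 0.5), 2.0)
        p1, p2 = phase_average(traj, 2.0)
        assert p1["v_R"] == pytest.approx(2.0)
        assert p2["v_R"] == pytest.approx(2.0)

    def test_step_function_averages(self):
        t = np.arange(0, 4.0, 0.5)
        flux = np.where(t <= 2.0, 1.0, 3.0)
        p1, p2 = phase_average(self._traj(t, flux), 2.0)
        assert p1["v_R"] == pytest.approx(1.0)
        assert p2["v_R"] == pytest.approx(3.0)

    def test_linear_ramp_matches_closed_form(self):
        dt = 0.01
        t = np.arange(0.0, 1.0, dt)
        p1, _ = phase_average(self._traj(t, t), t[-1])
        # time average of a uniform ramp 0 -> 1 is 1/2 up to O(dt)
        assert p1["v_R"] == pytest.approx(0.5, abs=dt)

    def test_normalised_average_excludes_zero_uptake_rows(self):
        t = np.arange(0, 2.0, 0.5)
        traj = self._traj(t, [2.0, 2.0, 4.0, 4.0], uptake=[1.0, 1.0, 2.0, 0.0])
        p1, _ = phase_average(traj, t[-1], normalize=True, glucose_column="v_up")
        assert p1["v_R"] == pytest.approx(2.0)

    def test_boundary_outside_span_raises(self):
        with pytest.raises(ValueError):
            phase_average(self._traj([0.0, 1.0], [1.0, 1.0]), 5.0)


class TestClassifyAndTabulate:
    def _change(self, deltas, classes, pathway="p"):
        from agefba.fluxes import FluxChange
        return FluxChange(delta=deltas, direction_class=classes,
                          pathway={k: pathway for k in classes})

    def test_all_zero_is_all_unchanged(self):
        change = self._change({"a": 0.0, "b": 0.0},
                              {"a": "unchanged", "b": "unchanged"})
        table = classify_and_tabulate(change)
        assert table.loc[0, "frac_unchanged"] == pytest.approx(1.0)

    def test_fifty_fifty_split(self):
        change = self._change({"a": 0.5, "b": 0.0},
                              {"a": "increased", "b": "unchanged"})
        row = classify_and_tabulate(change).iloc[0]
        assert row["frac_increased"] == pytest.approx(0.5)
        assert row["frac_unchanged"] == pytest.approx(0.5)
        assert row["frac_decreased"] == pytest.approx(0.0)

    def test_fraction_above_one(self):
        change = self._change({"a": 2.0, "b": 0.5, "c": 0.0},
                              {"a": "increased", "b": "increased",
                               "c": "unchanged"})
        row = classify_and_tabulate(change).iloc[0]
        assert row["frac_delta_gt_1"] == pytest.approx(1.0 / 3.0)

    @given(st.lists(st.sampled_from(["increased", "unchanged", "decreased"]),
                    min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_fractions_sum_to_one(self, classes):
        deltas = {f"r{i}": (0.0 if c == "unchanged" else 0.5)
                  for i, c in enumerate(classes)}
        named = {f"r{i}": c for i, c in enumerate(classes)}
        row = classify_and_tabulate(self._change(deltas, named)).iloc[0]
        total = (row["frac_increased"] + row["frac_unchanged"]
                 + row["frac_decreased"])
        assert total == pytest.approx(1.0)
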