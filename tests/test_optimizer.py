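"""Lexicographic two-stage optimisation, stage locking and parsimony."""
import numpy as np
import pytest

from agefba.model import build_lp, solve_lp
from agefba.optimize import (
    ConfigurationError,
    Objective,
    OptimizationStrategy,
    lexicographic_solve,
    lock_stage,
    make_objective,
    parsimonious_solve,
)

from conftest import make_t2
from lp_oracle import enumerate_vertices


class TestMakeObjective:
    def test_growth_and_ngam_single_reaction(self, t2):
        growth = make_objective(t2, "max_growth")
        assert growth.direction == "max"
        assert growth.coefficients == {"R_bio": 1.0}
        ngam = make_objective(t2, "max_ngam")
        assert ngam.coefficients == {"R_ngam": 1.0}

    def test_atp_production_reads_stoichiometry(self):
        from agefba.model import Enzyme, MetabolicModel, Metabolite, Reaction
        model = MetabolicModel(
            metabolites=[Metabolite(id="atp")],
            reactions=[
                Reaction(id="r1", stoich={"atp": 2.0}),
                Reaction(id="r2", stoich={"atp": 1.0}),
                Reaction(id="use", stoich={"atp": -1.0}),
            ],
            enzymes=[Enzyme(id="E", MW=1.0, kcat={"r1": 1.0, "r2": 1.0, "use": 1.0})],
            sigma=1.0, f=1.0, P_tot=1.0,
            reaction_sets={"atp_producing": ["r1", "r2"]})
        obj = make_objective(model, "max_atp_production")
        assert obj.coefficients == {"r1": 2.0, "r2": 1.0}
        unweighted = make_objective(model, "max_atp_production", weighted=False)
        assert unweighted.coefficients == {"r1": 1.0, "r2": 1.0}

    def test_missing_set_raises(self, t2):
        with pytest.raises(ConfigurationError):
            make_objective(t2, "min_nadh_production")


class TestLockStage:
    @pytest.mark.parametrize("direction,z,eps,expected_rhs", [
        ("max", 5.0, 0.2, 4.0),   # c.v >= 4
        ("min", 0.0, 0.5, 0.0),   # c.v <= 0
        ("max", 5.0, 1.0, 0.0),   # vacuous for non-negative objectives
    ])
    def test_lock_arithmetic(self, t2, direction, z, eps, expected_rhs):
        lp = build_lp(t2)
        locked = lock_stage(lp, Objective("o", direction, {"R_bio": 1.0}), z, eps)
        assert locked.bound == pytest.approx(expected_rhs)
        assert locked.sense == (">=" if direction == "max" else "<=")
        # the appended inequality row encodes the same constraint
        assert lp.b_ub[-1] == pytest.approx(
            -expected_rhs if direction == "max" else expected_rhs)

    def test_epsilon_out_of_range_rejected(self, t2):
        lp = build_lp(t2)
        with pytest.raises(ConfigurationError):
            lock_stage(lp, Objective("o", "max", {"R_bio": 1.0}), 5.0, 1.5)

    def test_negative_optimum_warns(self, t2):
        lp = build_lp(t2)
        with pytest.warns(UserWarning):
            lock_stage(lp, Objective("o", "max", {"R_bio": 1.0}), -1.0, 0.1)


class TestLexicographic:
    def test_two_stage_relaxed_growth_frees_pool_for_ngam(self, t2):
        # z1 = 5; lock v_bio >= 3; remaining pool supports v_ngam = 4
        strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                        epsilon1=0.4)
        sol = lexicographic_solve(t2, strategy)
        assert sol.optimal
        assert sol.stage_values == pytest.approx([5.0, 4.0], abs=1e-7)
        assert sol.v["R_bio"] == pytest.approx(3.0, abs=1e-7)
        assert sol.v["R_ngam"] == pytest.approx(4.0, abs=1e-7)

    def test_zero_epsilon_keeps_stage1_optimum(self, t2):
        strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                        epsilon1=0.0)
        sol = lexicographic_solve(t2, strategy)
        assert sol.v["R_bio"] == pytest.approx(5.0, abs=1e-6)
        assert sol.v["R_ngam"] == pytest.approx(0.0, abs=1e-6)

    def test_min_first_objective_means_no_flux(self, t2):
        sol = lexicographic_solve(t2, OptimizationStrategy(first="min_glucose_uptake"))
        assert sol.stage_values[0] == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) < 1e-8 for v in sol.v.values())

    def test_stage1_values_respected_after_all_stages(self, t2):
        # locked stage-1 value holds after stage 2 and parsimony for every
        # (epsilon1) on the sweep grid
        for eps1 in [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]:
            strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                            epsilon1=eps1, parsimonious=True)
            sol = lexicographic_solve(t2, strategy)
            z1 = sol.stage_values[0]
            assert sol.v["R_bio"] >= z1 * (1 - eps1) - 1e-7

    def test_z2_monotone_in_epsilon1(self, t2):
        values = []
        for eps1 in [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]:
            sol = lexicographic_solve(t2, OptimizationStrategy(
                first="max_growth", second="max_ngam", epsilon1=eps1))
            values.append(sol.stage_values[1])
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_infeasible_stage1_propagates(self, t2):
        t2.reaction("R_bio").lower_bound = 100.0  # beyond the pool limit
        sol = lexicographic_solve(t2, OptimizationStrategy(first="max_growth"))
        assert sol.status == "infeasible"


class TestParsimony:
    def test_unique_point_after_two_locked_stages(self, t2):
        # locked at v_bio >= 3 and v_ngam >= 4 the parsimonious point is
        # unique: v_up = 7, sum v = 14, sum e = 5
        strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                        epsilon1=0.4, parsimonious=True)
        sol = lexicographic_solve(t2, strategy)
        assert sol.v["R_up"] == pytest.approx(7.0, abs=1e-6)
        assert sum(sol.v.values()) == pytest.approx(14.0, abs=1e-6)
        assert sum(sol.e.values()) == pytest.approx(5.0, abs=1e-6)
        assert sol.stage_values[-1] == pytest.approx(19.0, abs=1e-6)

    def test_single_feasible_point_t1(self, t1):
        t1.reaction("R_bio").lower_bound = 5.0
        sol = lexicographic_solve(t1, OptimizationStrategy(
            first="max_growth", parsimonious=True))
        assert sol.v["R_up"] == pytest.approx(5.0, abs=1e-6)
        assert sol.v["R_bio"] == pytest.approx(5.0, abs=1e-6)

    def test_parsimony_picks_enzyme_cheaper_route(self, parallel_routes):
        sol = lexicographic_solve(parallel_routes, OptimizationStrategy(
            first="max_growth", epsilon1=0.5, parsimonious=True))
        # both routes could carry the locked flux; the cheap one wins
        assert sol.v["R_dear"] == pytest.approx(0.0, abs=1e-8)
        assert sol.v["R_cheap"] > 0

    def test_parsimony_dominates_random_feasible_points(self, t2):
        rng = np.random.default_rng(0)
        strategy = OptimizationStrategy(first="max_growth", epsilon1=0.4,
                                        parsimonious=True)
        sol = lexicographic_solve(t2, strategy)
        best = sum(sol.v.values()) + sum(sol.e.values())
        # sample feasible points of the growth-locked polytope
        # {v_bio >= 3, e_bio + e_ngam <= 5, v_up = v_bio + v_ngam <= 10}
        for _ in range(100):
            v_bio = rng.uniform(3.0, 5.0)
            v_ngam = rng.uniform(0.0, 2.0 * (5.0 - v_bio))
            e_bio, e_ngam = v_bio, v_ngam / 2.0
            v_up = v_bio + v_ngam
            assert e_bio + e_ngam <= 5.0 + 1e-12 and v_up <= 10.0
            total = v_up + v_bio + v_ngam + e_bio + e_ngam
            assert total >= best - 1e-7

    def test_parsimony_idempotent(self, t2):
        from agefba.optimize import run_stages
        strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                        epsilon1=0.4, parsimonious=True)
        problem = build_lp(t2)
        sol, locked = run_stages(problem, t2, strategy)
        again = parsimonious_solve(locked, t2)
        first = sum(sol.v.values()) + sum(sol.e.values())
        second = sum(again.v.values()) + sum(again.e.values())
        assert second == pytest.approx(first, abs=1e-8)

    def test_lexicographic_optima_match_vertex_oracle(self, t2):
        # stage 2 optimum over the locked polytope equals the best vertex
        strategy = OptimizationStrategy(first="max_growth", second="max_ngam",
                                        epsilon1=0.4)
        problem = build_lp(t2)
        obj1 = make_objective(t2, "max_growth")
        z1 = solve_lp(problem, obj1).stage_values[0]
        lock_stage(problem, obj1, z1, 0.4)
        vertices = enumerate_vertices(problem)
        idx = problem.index["R_ngam"]
        expected = vertices[:, idx].max()
        sol = lexicographic_solve(t2, strategy)
        assert sol.stage_values[1] == pytest.approx(expected, rel=1e-6)
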