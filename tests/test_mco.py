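import numpy as np
import pytest
import scipy.sparse as sp

from protonarc._opt import InfeasibleProblemError
from protonarc.beamline import BeamConfig, DoseInfluence, Spot
from protonarc.fixtures import toy_lp, toy_problem
from protonarc.mco import (
    HardConstraint,
    Objective,
    Plan,
    WishList,
    build_surrogate,
    default_wishlist,
    parse_wishlist,
    per_field_max_dose,
    solve_lexicographic,
    surrogate_value,
)
from protonarc.phantom import GridSpec, Phantom
from protonarc.scenarios import Scenario, ScenarioSet


class TestWishListValidation:
    def test_three_priorities_parse_in_order(self):
        wl = parse_wishlist(
            """{"constraints": [], "objectives": [
                {"priority": 2, "structure": "b", "metric": "mean_dose", "goal": 1},
                {"priority": 1, "structure": "a", "metric": "mean_dose", "goal": 1},
                {"priority": 3, "structure": "c", "metric": "max_dose", "goal": 1}]}"""
        )
        assert [o.priority for o in wl.objectives] == [1, 2, 3]

    def test_duplicate_priority_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            WishList([], [Objective(2, "a", "mean_dose", 1), Objective(2, "b", "mean_dose", 1)])

    def test_non_contiguous_priorities_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            WishList([], [Objective(1, "a", "mean_dose", 1), Objective(3, "b", "mean_dose", 1)])

    def test_negative_bound_and_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            HardConstraint("a", "max_dose", -1.0)
        with pytest.raises(ValueError):
            HardConstraint("a", "median_dose", 1.0)
        with pytest.raises(ValueError):
            Objective(1, "a", "min_dose", 1.0)

    def test_default_wishlist_structure(self):
        wl = default_wishlist()
        robust_targets = [c for c in wl.constraints if c.robust and c.structure == "ctv70"]
        assert {c.metric for c in robust_targets} == {"min_dose", "max_dose"}
        assert any(c.metric == "per_field_max_dose" and c.bound == 47.0 for c in wl.constraints)
        oar_means = [o for o in wl.objectives if o.metric == "mean_dose" and not o.robust]
        assert oar_means, "nominal-scenario mean-dose OAR objectives expected"
        assert wl.digest() == default_wishlist().digest()


class TestLexicographicSolve:
    def test_single_spot_min_dose_constraint(self):
        wl = WishList(
            [HardConstraint("t", "min_dose", 60.0)],
            [Objective(1, "t", "mean_dose", 0.0)],
        )
        toy = toy_problem("one", np.array([[1.2]]), {"t": [0]}, wl)
        plan = solve_lexicographic(toy.dij, toy.phantom, wl)
        assert plan.weights[0] == pytest.approx(60.0 / 1.2, abs=1e-6)
        assert plan.achieved[1] == pytest.approx(60.0, abs=1e-6)

    def test_two_spot_lexicographic_matches_grid_search_oracle(self):
        toy = toy_lp("two_spot_lex")
        plan = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, delta=0.0)
        _, oracle_vec = toy.oracle_grid_search(w_max=70.0, n_grid=141)
        impl_vec = [plan.achieved[k] for k in sorted(plan.achieved)]
        assert np.allclose(impl_vec, oracle_vec, atol=0.5)

    def test_delta_zero_is_strict_lexicographic(self):
        toy = toy_lp("two_spot_lex")
        plan = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, delta=0.0)
        # re-minimizing priority 1 with the same constraints cannot beat it
        wl1 = WishList(toy.wishlist.constraints, [toy.wishlist.objectives[0]])
        best1 = solve_lexicographic(toy.dij, toy.phantom, wl1)
        assert plan.achieved[1] <= best1.achieved[1] + 1e-6

    def test_delta_relaxes_higher_priorities(self):
        toy = toy_lp("two_spot_lex")
        strict = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, delta=0.0)
        relaxed = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, delta=0.10)
        # the lower priority can only improve when the higher one is relaxed
        assert relaxed.achieved[2] <= strict.achieved[2] + 1e-6

    def test_infeasible_constraints_report_names_constraint(self):
        toy = toy_lp("infeasible_minmax")
        with pytest.raises(InfeasibleProblemError, match="min_dose|max_dose"):
            solve_lexicographic(toy.dij, toy.phantom, toy.wishlist)

    def test_sufficient_objective_stops_at_goal(self):
        wl = WishList(
            [HardConstraint("t", "min_dose", 60.0)],
            [
                Objective(1, "oar_a", "mean_dose", goal=20.0, sufficient=True),
                Objective(2, "oar_b", "mean_dose", goal=5.0),
            ],
        )
        toy = toy_lp("two_spot_lex")
        plan = solve_lexicographic(toy.dij, toy.phantom, wl, delta=0.0)
        # the unconstrained priority-1 minimum is 12 (< goal 20): recorded at goal,
        # which leaves slack that priority 2 may exploit
        assert plan.achieved[1] == pytest.approx(20.0)
        strict = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, delta=0.0)
        assert plan.achieved[2] <= strict.achieved[2] + 1e-6

    def test_goal_value_does_not_change_non_sufficient_solution(self):
        toy = toy_lp("two_spot_lex")
        wl2 = WishList(
            toy.wishlist.constraints,
            [
                Objective(1, "oar_a", "mean_dose", goal=50.0),
                Objective(2, "oar_b", "mean_dose", goal=5.0),
            ],
        )
        a = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist)
        b = solve_lexicographic(toy.dij, toy.phantom, wl2)
        assert a.achieved[1] == pytest.approx(b.achieved[1], abs=1e-9)

    def test_support_restriction(self):
        toy = toy_lp("two_spot_lex")
        plan = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, support=[1])
        assert plan.spot_ids == [1]
        assert plan.weights[0] == pytest.approx(60.0, abs=1e-6)


class TestExtraPenalty:
    def test_l1_penalty_sparsifies_every_stage(self):
        toy = toy_lp("five_spot_l1")
        plain = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist)
        pen = solve_lexicographic(
            toy.dij, toy.phantom, toy.wishlist,
            extra_penalty={"kind": "l1", "coefficient": 10.0},
        )
        assert (pen.weights > 1e-6).sum() <= (plain.weights > 1e-6).sum()
        # hard constraint still holds under the penalty
        t_idx = np.flatnonzero(toy.phantom.masks["t"].ravel())
        assert toy.dij.dose(pen.weights)[t_idx].min() >= 50.0 - 1e-3

    def test_group_penalty_collapses_el_groups(self):
        toy = toy_lp("three_el_ladder")
        pen = solve_lexicographic(
            toy.dij, toy.phantom, toy.wishlist,
            extra_penalty={"kind": "group", "coefficient": 50.0,
                           "groups": [np.array([0]), np.array([1]), np.array([2]), np.array([3])],
                           "group_weights": np.ones(4)},
        )
        plain = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist)
        assert (pen.weights > 1e-3 * pen.weights.max()).sum() <= \
               (plain.weights > 1e-3 * plain.weights.max()).sum()


class TestPlanSerialization:
    def test_plan_json_round_trip(self):
        toy = toy_lp("two_spot_lex")
        plan = solve_lexicographic(toy.dij, toy.phantom, toy.wishlist, mode="cs4")
        plan.meta["normalization_scale"] = 1.25
        again = Plan.from_json(plan.to_json())
        assert again.mode == "cs4"
        assert again.spots == plan.spots
        assert np.allclose(again.weights, plan.weights)
        assert again.achieved == plan.achieved
        assert again.meta["normalization_scale"] == 1.25


class TestRobustConstraints:
    def _two_scenario_toy(self):
        grid = GridSpec((2, 1, 1), (1.0, 1.0, 1.0))
        masks = {"body": np.ones(grid.shape, bool), "t": np.ones(grid.shape, bool)}
        ph = Phantom(grid, np.ones(grid.shape), masks, {"body": "body", "t": "target_high"})
        spots = [Spot(0, 0, 100.0, (0.0, 0.0), 0), Spot(0, 1, 100.0, (1.0, 0.0), 1)]
        scen = ScenarioSet((Scenario((0, 0, 0), 1.0, "nominal"), Scenario((3, 0, 0), 1.0, "shift")))
        m_nom = sp.csc_matrix(np.array([[1.0, 0.1], [0.1, 1.0]]))
        m_shift = sp.csc_matrix(np.array([[0.7, 0.2], [0.2, 0.7]]))
        dij = DoseInfluence(grid, [BeamConfig(0.0)], spots, scen, [m_nom, m_shift])
        return ph, dij

    def test_robust_min_dose_enforced_in_every_scenario(self):
        ph, dij = self._two_scenario_toy()
        wl = WishList(
            [HardConstraint("t", "min_dose", 60.0, robust=True)],
            [Objective(1, "body", "mean_dose", 0.0)],
        )
        plan = solve_lexicographic(dij, ph, wl)
        for i in range(2):
            assert dij.dose(plan.weights, i).min() >= 60.0 - 1e-3

    def test_nominal_only_constraint_ignores_error_scenarios(self):
        ph, dij = self._two_scenario_toy()
        wl = WishList(
            [HardConstraint("t", "min_dose", 60.0, robust=False)],
            [Objective(1, "body", "mean_dose", 0.0)],
        )
        plan = solve_lexicographic(dij, ph, wl)
        assert dij.dose(plan.weights, 0).min() >= 60.0 - 1e-3
        assert dij.dose(plan.weights, 1).min() < 60.0  # scenario dose may sag


class TestPerFieldMaxDose:
    def _two_field_toy(self):
        D = np.array([[1.0, 0.5], [0.2, 0.8]])
        wl = WishList([HardConstraint("t", "min_dose", 10.0)], [Objective(1, "t", "mean_dose", 0)])
        return toy_problem("2f", D, {"t": [0, 1]}, wl, el_of_spot=[(0, 0), (1, 0)])

    def test_zero_weights_give_zero(self):
        toy = self._two_field_toy()
        from protonarc.mco import Plan

        plan = Plan(np.zeros(2), toy.dij.spots)
        assert per_field_max_dose(plan, toy.dij, 0) == 0.0

    def test_single_field_plan_equals_whole_plan_max(self):
        toy = self._two_field_toy()
        from protonarc.mco import Plan

        plan = Plan(np.array([5.0, 0.0]), toy.dij.spots)
        whole = toy.dij.dose(np.array([5.0, 0.0])).max()
        assert per_field_max_dose(plan, toy.dij, 0) == pytest.approx(whole)

    def test_unknown_field_rejected(self):
        toy = self._two_field_toy()
        from protonarc.mco import Plan

        with pytest.raises(KeyError):
            per_field_max_dose(Plan(np.zeros(2), toy.dij.spots), toy.dij, 7)

    def test_cap_constraint_limits_each_field(self):
        D = np.array([[1.0, 1.0]])
        wl = WishList(
            [
                HardConstraint("t", "min_dose", 60.0),
                HardConstraint("body", "per_field_max_dose", 40.0),
            ],
            [Objective(1, "t", "mean_dose", 0.0)],
        )
        toy = toy_problem("cap", D, {"t": [0]}, wl, el_of_spot=[(0, 0), (1, 0)])
        plan = solve_lexicographic(toy.dij, toy.phantom, wl)
        for f in range(2):
            assert per_field_max_dose(plan, toy.dij, f) <= 40.0 + 1e-3
        assert toy.dij.dose(plan.weights).min() >= 60.0 - 1e-3


class TestSurrogate:
    def test_surrogate_value_matches_solution_cost(self):
        toy = toy_lp("two_spot_lex")
        prob = build_surrogate(toy.dij, toy.phantom, toy.wishlist)
        x, val = prob.solve()
        assert surrogate_value(prob, x[: prob.n_spots]) == pytest.approx(val, abs=1e-9)

    def test_surrogate_matches_independent_dense_assembly(self):
        toy = toy_lp("two_spot_lex")
        prob = build_surrogate(toy.dij, toy.phantom, toy.wishlist)
        _, val = prob.solve()
        _, oracle_val = toy.oracle_constrained_lp()
        assert val == pytest.approx(oracle_val, abs=1e-7)
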