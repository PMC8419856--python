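"""The four-term objective, representation costs, and single-flip deltas."""

import numpy as np
import pytest

from marprob import (
    BoundarySegment,
    ContractError,
    FeatureRecord,
    LandscapeSpec,
    Occurrence,
    PlanningUnit,
    Problem,
    ProblemMode,
    RunConfig,
    Solution,
    UnitStatus,
    boundary_term,
    cost_term,
    delta_evaluate,
    estimate_representation_cost,
    evaluate,
    probability_penalty_term,
    random_problem,
    representation_amounts,
    representation_penalty_term,
    toy_problem,
)


def grid3x3():
    """3x3 unit grid, rook adjacency, unit edge lengths, unit costs."""
    units = [PlanningUnit(id=i) for i in range(1, 10)]
    bounds = []
    for r in range(3):
        for c in range(3):
            i = r * 3 + c + 1
            if c < 2:
                bounds.append(BoundarySegment(i, i + 1, 1.0))
            if r < 2:
                bounds.append(BoundarySegment(i, i + 3, 1.0))
    return Problem(planning_units=units, features=[], occurrences=[],
                   boundaries=bounds)


class TestTerms:
    def test_cost_sums_selected_units(self):
        units = [PlanningUnit(id=i, cost=float(i)) for i in (1, 2, 3)]
        p = Problem(planning_units=units, features=[], occurrences=[])
        assert cost_term(p, Solution.empty(p)) == 0.0
        assert cost_term(p, Solution.from_ids(p, [1, 2, 3])) == 6.0

    def test_cost_matches_summation_oracle(self):
        rng = np.random.default_rng(1)
        costs = rng.uniform(0, 10, size=100)
        units = [PlanningUnit(id=i + 1, cost=float(c))
                 for i, c in enumerate(costs)]
        p = Problem(planning_units=units, features=[], occurrences=[])
        chosen = [i + 1 for i in range(100) if rng.random() < 0.5]
        assert cost_term(p, Solution.from_ids(p, chosen)) == \
            pytest.approx(sum(costs[i - 1] for i in chosen), abs=1e-9)

    def test_interior_edge_vanishes_when_both_selected(self):
        units = [PlanningUnit(id=1), PlanningUnit(id=2)]
        p = Problem(planning_units=units, features=[], occurrences=[],
                    boundaries=[BoundarySegment(1, 2, 1.0)])
        assert boundary_term(p, Solution.from_ids(p, [1, 2])) == 0.0
        assert boundary_term(p, Solution.from_ids(p, [1])) == 1.0

    def test_center_of_grid_has_four_open_edges(self):
        p = grid3x3()
        assert boundary_term(p, Solution.from_ids(p, [5])) == 4.0

    def test_self_segment_charges_when_selected(self):
        units = [PlanningUnit(id=1)]
        p = Problem(planning_units=units, features=[], occurrences=[],
                    boundaries=[BoundarySegment(1, 1, 2.5)])
        assert boundary_term(p, Solution.from_ids(p, [1])) == 2.5
        assert boundary_term(p, Solution.empty(p)) == 0.0

    def test_representation_amounts(self, toy2):
        held = representation_amounts(toy2, Solution.from_ids(toy2, [2, 3]))
        assert held == {1: 2.0}
        assert representation_amounts(toy2, Solution.empty(toy2)) == {1: 0.0}


def two_carrier_problem():
    units = [PlanningUnit(id=1, cost=1.0), PlanningUnit(id=2, cost=10.0)]
    occs = [Occurrence(1, 1, 1.0), Occurrence(1, 2, 1.0)]
    feats = [FeatureRecord(id=1, target=1.0)]
    return Problem(planning_units=units, features=feats, occurrences=occs)


class TestRepresentationCost:
    def test_single_carrier(self):
        units = [PlanningUnit(id=1, cost=5.0)]
        p = Problem(planning_units=units,
                    features=[FeatureRecord(id=1, target=1.0)],
                    occurrences=[Occurrence(1, 1, 1.0)])
        assert estimate_representation_cost(p, 1) == 5.0

    def test_greedy_picks_cheapest(self):
        assert estimate_representation_cost(two_carrier_problem(), 1) == 1.0

    def test_greedy_accumulates(self):
        p = two_carrier_problem()
        p.features[0].target = 2.0
        assert estimate_representation_cost(p, 1) == 11.0

    def test_unreachable_target_warns_and_uses_all(self):
        p = two_carrier_problem()
        p.features[0].target = 5.0
        with pytest.warns(UserWarning, match="below target"):
            assert estimate_representation_cost(p, 1) == 11.0


class TestRepresentationPenalty:
    def make(self, held_frac, style):
        units = [PlanningUnit(id=1, cost=1.0), PlanningUnit(id=2, cost=1.0)]
        occs = [Occurrence(1, 1, held_frac * 2), Occurrence(1, 2, 2.0)]
        feats = [FeatureRecord(id=1, target=2.0, representation_cost=1.0)]
        p = Problem(planning_units=units, features=feats, occurrences=occs)
        cfg = RunConfig(representation_penalty_style=style)
        return p, cfg

    def test_met_targets_cost_nothing(self):
        p, cfg = self.make(0.5, "step")
        assert representation_penalty_term(
            p, Solution.from_ids(p, [2]), cfg) == 0.0

    def test_proportional_half_target(self):
        p, cfg = self.make(0.5, "proportional")
        assert representation_penalty_term(
            p, Solution.from_ids(p, [1]), cfg) == pytest.approx(0.5)

    def test_step_indicator(self):
        p, cfg = self.make(0.5, "step")
        assert representation_penalty_term(
            p, Solution.from_ids(p, [1]), cfg) == pytest.approx(1.0)


class TestProbabilityPenalty:
    def test_worked_example_raw_shortfall(self, toy3, raw_exact_config):
        sol = Solution.from_ids(toy3, [2])
        # species 3 meets P=0.8 (p=0.9); species 4 misses P=0.9 by 0.3
        assert probability_penalty_term(toy3, sol, raw_exact_config) == \
            pytest.approx(0.3, abs=1e-12)

    def test_worked_example_normalized_shortfall(self, toy3):
        cfg = RunConfig(shortfall_style="normalized",
                        probability_engine="exact")
        sol = Solution.from_ids(toy3, [2])
        assert probability_penalty_term(toy3, sol, cfg) == \
            pytest.approx(0.3 / 0.9, abs=1e-9)

    def test_no_penalty_when_targets_met(self, toy3, raw_exact_config):
        sol = Solution.from_ids(toy3, [2, 3])
        assert probability_penalty_term(toy3, sol, raw_exact_config) == 0.0

    def test_zero_probability_target_contributes_nothing(self):
        p = two_carrier_problem()  # probability_target defaults to 0
        cfg = RunConfig(probability_engine="exact")
        assert probability_penalty_term(p, Solution.empty(p), cfg) == 0.0

    def test_adding_a_carrier_never_increases_penalty(self):
        rng = np.random.default_rng(11)
        spec = LandscapeSpec(grid_rows=2, grid_cols=4, n_features=2,
                             seed=19, occupancy_fraction=0.6)
        p = random_problem(spec)
        cfg = RunConfig(shortfall_style="raw", probability_engine="exact")
        for _ in range(10):
            ids = [u.id for u in p.planning_units]
            keep = [i for i in ids if rng.random() < 0.4]
            rest = [i for i in ids if i not in keep]
            if not rest:
                continue
            before = probability_penalty_term(
                p, Solution.from_ids(p, keep), cfg)
            after = probability_penalty_term(
                p, Solution.from_ids(p, keep + [rest[0]]), cfg)
            assert after <= before + 1e-12


class TestEvaluate:
    def test_empty_problem_scores_zero(self):
        p = Problem(planning_units=[PlanningUnit(id=1)], features=[],
                    occurrences=[])
        bd = evaluate(p, Solution.empty(p), RunConfig())
        assert bd.total == 0.0

    def test_worked_example_total(self, toy3, raw_exact_config):
        # both probability targets met -> only the two unit costs remain
        bd = evaluate(toy3, Solution.from_ids(toy3, [2, 3]),
                      raw_exact_config)
        assert bd.total == pytest.approx(2.0, abs=1e-9)
        assert bd.representation_penalty_term == 0.0
        assert bd.probability_penalty_term == 0.0

    @pytest.mark.parametrize("engine", ["normal_approx", "exact"])
    def test_decomposition_identity(self, engine):
        spec = LandscapeSpec(grid_rows=3, grid_cols=4, n_features=3, seed=5)
        p = random_problem(spec)
        cfg = RunConfig(boundary_multiplier=0.7, probability_weight=3.0,
                        probability_engine=engine,
                        representation_penalty_style="proportional")
        rng = np.random.default_rng(2)
        for _ in range(5):
            sol = Solution({u.id: bool(rng.random() < 0.5)
                            for u in p.planning_units})
            bd = evaluate(p, sol, cfg)
            assert bd.total == pytest.approx(
                bd.cost_term + 0.7 * bd.boundary_term
                + bd.representation_penalty_term
                + bd.probability_penalty_term, abs=1e-9)
            # terms agree with their standalone computations
            assert bd.cost_term == pytest.approx(cost_term(p, sol), abs=1e-9)
            assert bd.boundary_term == pytest.approx(
                boundary_term(p, sol), abs=1e-9)
            assert bd.representation_penalty_term == pytest.approx(
                representation_penalty_term(p, sol, cfg), abs=1e-9)
            assert bd.probability_penalty_term == pytest.approx(
                probability_penalty_term(p, sol, cfg), abs=1e-9)

    def test_reduces_to_classic_objective_when_certain(self):
        """With every probability 1 the chance term vanishes and the score
        is cost + b*boundary + representation penalty."""
        spec = LandscapeSpec(grid_rows=3, grid_cols=3, n_features=3, seed=9,
                             mode=ProblemMode.DETERMINISTIC)
        p = random_problem(spec)
        for f in p.features:
            f.probability_target = 0.95  # chance constraint present...
        cfg = RunConfig(boundary_multiplier=0.5, probability_weight=4.0,
                        probability_engine="exact")
        rng = np.random.default_rng(3)
        for _ in range(5):
            sol = Solution({u.id: bool(rng.random() < 0.5)
                            for u in p.planning_units})
            bd = evaluate(p, sol, cfg)
            held = representation_amounts(p, sol)
            classic = (cost_term(p, sol) + 0.5 * boundary_term(p, sol)
                       + representation_penalty_term(p, sol, cfg))
            if all(held[f.id] >= f.target for f in p.features):
                assert bd.probability_penalty_term == 0.0
                assert bd.total == pytest.approx(classic, abs=1e-9)


class TestDeltaEvaluate:
    def setup_problem(self):
        spec = LandscapeSpec(grid_rows=3, grid_cols=4, n_features=3, seed=21)
        p = random_problem(spec)
        cfg = RunConfig(boundary_multiplier=0.4, probability_weight=2.0)
        return p, cfg

    def test_isolated_costly_unit_delta_is_cost(self):
        units = [PlanningUnit(id=1, cost=3.5), PlanningUnit(id=2, cost=1.0)]
        p = Problem(planning_units=units, features=[], occurrences=[])
        cfg = RunConfig()
        sol = Solution.empty(p)
        bd = evaluate(p, sol, cfg)
        _, d = delta_evaluate(p, sol, bd, 1, cfg)
        assert d == pytest.approx(3.5, abs=1e-12)

    def test_matches_full_reevaluation(self):
        p, cfg = self.setup_problem()
        rng = np.random.default_rng(4)
        sol = Solution({u.id: bool(rng.random() < 0.5)
                        for u in p.planning_units})
        bd = evaluate(p, sol, cfg)
        for _ in range(200):
            uid = int(rng.choice([u.id for u in p.planning_units]))
            bd, d = delta_evaluate(p, sol, bd, uid, cfg)
            sol.selected[uid] = not sol.selected[uid]
            fresh = evaluate(p, sol, cfg)
            assert bd.total == pytest.approx(fresh.total, abs=1e-9)

    def test_flip_involution(self):
        p, cfg = self.setup_problem()
        sol = Solution.from_ids(p, [1, 5, 9])
        bd0 = evaluate(p, sol, cfg)
        bd1, d1 = delta_evaluate(p, sol, bd0, 5, cfg)
        sol2 = sol.copy()
        sol2.selected[5] = False
        bd2, d2 = delta_evaluate(p, sol2, bd1, 5, cfg)
        assert bd2.total == pytest.approx(bd0.total, abs=1e-9)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-9)

    def test_locked_unit_rejected(self):
        units = [PlanningUnit(id=1, status=UnitStatus.LOCKED_IN)]
        p = Problem(planning_units=units, features=[], occurrences=[])
        cfg = RunConfig()
        bd = evaluate(p, Solution.from_ids(p, [1]), cfg)
        with pytest.raises(ContractError):
            delta_evaluate(p, Solution.from_ids(p, [1]), bd, 1, cfg)
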