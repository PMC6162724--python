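"""Unit and property tests for the best-first engines."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nfsearch.errors import ConfigError, DomainError, NodeBudgetExceeded
from nfsearch.search_core import (
    BoundReport,
    SearchTrace,
    TraceRecord,
    WeightSchedule,
    astar,
    backtracking_score,
    evaluate,
    focal_search,
    weighted_astar,
)
from nfsearch.task_domains import (
    GOAL,
    GridMap,
    grid_problem,
    optimal_puzzle_cost,
    puzzle_problem,
)


class TestEvaluate:
    @pytest.mark.parametrize(
        "g,h,omega,expected",
        [(4, 6, 0.5, 5.0), (0, 0, 0.575, 0.0), (4, 6, 0.575, 5.15)],
    )
    def test_weighted_mean(self, g, h, omega, expected):
        assert evaluate(g, h, omega) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("omega", [-0.1, 1.1, 2.0])
    def test_rejects_weight_outside_unit_interval(self, omega):
        with pytest.raises(DomainError):
            evaluate(1.0, 1.0, omega)

    def test_rejects_negative_costs(self):
        with pytest.raises(DomainError):
            evaluate(-1.0, 1.0, 0.5)

    @given(
        g=st.floats(0, 1e6), h=st.floats(0, 1e6), omega=st.floats(0, 1)
    )
    def test_f_lies_between_g_and_h(self, g, h, omega):
        f = evaluate(g, h, omega)
        assert min(g, h) - 1e-6 <= f <= max(g, h) + 1e-6

    def test_endpoints_recover_g_and_h(self):
        assert evaluate(3.0, 7.0, 0.0) == 3.0
        assert evaluate(3.0, 7.0, 1.0) == 7.0


class TestWeightSchedule:
    def test_trivial_schedule_is_admissible_astar(self):
        sched = WeightSchedule()
        assert sched.initial_weight == 0.5 and sched.max_weight == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(initial_weight=0.4),
            dict(initial_weight=1.0),
            dict(triggers=((0.2, 0.6), (0.1, 0.65))),  # fractions not increasing
            dict(triggers=((0.2, 0.45),)),  # weight below 0.5
            dict(triggers=((1.5, 0.6),)),  # fraction outside [0, 1]
            dict(initial_weight=0.6, triggers=((0.1, 0.55),), monotone=True),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            WeightSchedule(**kwargs)

    def test_max_weight_spans_triggers(self):
        sched = WeightSchedule(0.5, ((0.1, 0.55), (0.3, 0.65)))
        assert sched.max_weight == 0.65


class TestAstar:
    def test_identity_instance(self):
        trace = astar(puzzle_problem(GOAL, GOAL))
        assert trace.solved
        assert trace.solution_path == [GOAL.tiles]
        assert trace.solution_cost == 0
        assert trace.nodes_expanded == 1

    def test_empty_grid_attains_manhattan_bound(self):
        gmap = GridMap(width=3, height=3, start=(0, 0), goal=(2, 2))
        trace = astar(grid_problem(gmap))
        assert trace.solution_cost == 4

    def test_optimal_on_oracle_batch(self, easy_instances):
        for start, goal in easy_instances:
            trace = astar(puzzle_problem(start, goal))
            assert trace.solution_cost == optimal_puzzle_cost(start, goal)

    def test_unsolvable_returns_unsolved_trace(self):
        gmap = GridMap.from_ascii("S.#.\n..#.\n..#G")
        trace = astar(grid_problem(gmap))
        assert not trace.solved
        assert trace.solution_cost is None
        assert trace.nodes_expanded == 6  # the reachable component

    def test_budget_exhaustion_signals(self, medium_instance):
        with pytest.raises(NodeBudgetExceeded):
            astar(puzzle_problem(*medium_instance), node_budget=5)

    def test_deterministic_trace(self, medium_instance):
        p = puzzle_problem(*medium_instance)
        t1, t2 = astar(p), astar(p)
        assert t1.expansions == t2.expansions
        assert t1.solution_path == t2.solution_path


class TestWeightedAstar:
    def test_half_weight_reproduces_astar_sequence(self, easy_instances):
        for start, goal in easy_instances[:6]:
            p = puzzle_problem(start, goal)
            ref = astar(p)
            trace, report = weighted_astar(
                p, WeightSchedule(), optimal_cost=ref.solution_cost
            )
            assert trace.expansion_states() == ref.expansion_states()
            assert report.suboptimality_bound == pytest.approx(1.0)
            assert report.bound_satisfied

    def test_fixed_weight_meets_suboptimality_bound(self, easy_instances):
        for start, goal in easy_instances:
            opt = optimal_puzzle_cost(start, goal)
            trace, report = weighted_astar(
                puzzle_problem(start, goal),
                WeightSchedule(initial_weight=0.6),
                optimal_cost=opt,
            )
            assert trace.solution_cost <= 1.5 * opt + 1e-9
            assert report.bound_satisfied

    def test_trigger_switches_weight_at_fraction(self, medium_instance):
        p = puzzle_problem(*medium_instance)
        ref = astar(p)
        trace, report = weighted_astar(
            p,
            WeightSchedule(0.5, ((0.5, 0.6),)),
            reference_exploration=ref.nodes_expanded,
            optimal_cost=ref.solution_cost,
        )
        switch = math.ceil(0.5 * ref.nodes_expanded)
        omegas = [r.omega for r in trace.expansions]
        assert all(w == 0.5 for w in omegas[:switch])
        assert any(w == 0.6 for w in omegas[switch:])
        assert report.weight_used == 0.6

    def test_trace_records_satisfy_evaluation_identity(self, medium_instance):
        p = puzzle_problem(*medium_instance)
        trace, _ = weighted_astar(p, WeightSchedule(0.575), optimal_cost=1)
        for rec in trace.expansions:
            assert rec.f == pytest.approx(
                (1 - rec.omega) * rec.g + rec.omega * rec.h, abs=1e-12
            )

    def test_rejects_nonpositive_reference(self, medium_instance):
        with pytest.raises(ConfigError):
            weighted_astar(
                puzzle_problem(*medium_instance),
                WeightSchedule(),
                reference_exploration=0,
            )

    def test_weighted_run_never_costs_more_than_bound_on_grids(self, small_grids):
        from nfsearch.task_domains import optimal_grid_cost

        for gmap in small_grids:
            opt = optimal_grid_cost(gmap)
            trace, report = weighted_astar(
                grid_problem(gmap), WeightSchedule(0.65), optimal_cost=opt
            )
            assert trace.solution_cost <= (0.65 / 0.35) * opt + 1e-9
            assert report.bound_satisfied


class TestFocalSearch:
    def test_zero_slack_is_optimal(self, easy_instances):
        for start, goal in easy_instances[:5]:
            p = puzzle_problem(start, goal)
            trace = focal_search(p, 0.0, p.heuristic)
            assert trace.solution_cost == optimal_puzzle_cost(start, goal)

    def test_slack_bounds_cost(self, easy_instances):
        for start, goal in easy_instances:
            p = puzzle_problem(start, goal)
            trace = focal_search(p, 0.5, p.heuristic)
            opt = optimal_puzzle_cost(start, goal)
            assert trace.solution_cost <= 1.5 * opt + 1e-9

    def test_huge_slack_keeps_completeness(self):
        gmap = GridMap(width=3, height=3, start=(0, 0), goal=(2, 2))
        trace = focal_search(grid_problem(gmap), 10.0, lambda s: 0.0)
        assert trace.solved
        assert trace.solution_cost >= 4  # optimum is 4

    def test_negative_slack_rejected(self):
        p = puzzle_problem(GOAL, GOAL)
        with pytest.raises(DomainError):
            focal_search(p, -0.1, p.heuristic)


def _fake_trace(h_values):
    recs = [
        TraceRecord(i, f"s{i}", i, h, 0.5 * (i + h), 0.5, 0)
        for i, h in enumerate(h_values)
    ]
    return SearchTrace(expansions=recs)


class TestBacktrackingScore:
    @pytest.mark.parametrize(
        "hs,expected",
        [([5, 4, 3, 2, 1], 0), ([3, 2, 3, 1], 1), ([1, 2, 1, 2], 2), ([7], 0)],
    )
    def test_counts_h_increases(self, hs, expected):
        assert backtracking_score(_fake_trace(hs)) == expected

    def test_empty_trace_rejected(self):
        with pytest.raises(DomainError):
            backtracking_score(SearchTrace())

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=40))
    def test_matches_naive_count(self, hs):
        naive = sum(1 for i in range(1, len(hs)) if hs[i] > hs[i - 1])
        assert backtracking_score(_fake_trace(hs)) == naive


def test_trace_csv_round_trips_columns(tmp_path, medium_instance):
    trace = astar(puzzle_problem(*medium_instance))
    out = tmp_path / "trace.csv"
    trace.to_csv(out)
    header = out.read_text().splitlines()[0]
    assert header == "expansion_index,state_id,g,h,f,omega,open_size"
    assert len(out.read_text().splitlines()) == trace.nodes_expanded + 1


def test_bound_report_flags_violation():
    rep = BoundReport.from_run(0.6, optimal_cost=10.0, achieved_cost=16.0)
    assert rep.suboptimality_bound == pytest.approx(1.5)
    assert not rep.bound_satisfied
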