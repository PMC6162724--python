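"""Best-first search engines with dynamic heuristic re-weighting.

This module implements the search side of the closed loop: a graph-search
A* engine whose evaluation function

    f(n) = (1 - omega) * g(n) + omega * h(n)

interpolates between uniform-cost search (omega = 0), classical A*
(omega = 0.5, a positive rescaling of g + h), and greedy best-first search
(omega = 1).  Raising omega above 0.5 biases expansion towards the
heuristic and trades solution optimality for speed; with an admissible h
the returned cost is bounded by (omega / (1 - omega)) times the optimum,
so every omega < 1 yields an epsilon-admissible search.

The weight may change *during* a run.  A :class:`WeightSchedule` holds an
initial omega plus triggers expressed as fractions of a reference
exploration size (typically the node count of an admissible run on the
same instance); when the running expansion count crosses a trigger, the
new omega is installed and every OPEN-list priority is rebuilt.  This is
the mechanism the closed-loop controller uses to inject a brain-derived
weight part-way through a search.

A FOCAL (A*-epsilon) variant is also provided: instead of always popping
the minimum-f node, it restricts attention to the FOCAL set
{n in OPEN : f(n) <= (1 + eps) * min f} and picks the member minimising a
secondary heuristic, again epsilon-admissible for admissible h.

Every engine records a full :class:`SearchTrace` — one record per
expansion with g, h, f, the omega in effect, and the OPEN size — which
downstream modules use to measure search-space reduction and backtracking.

Conventions fixed here (the source material for this design leaves them
open):

* ties on f are broken by larger g, then by first-in insertion order;
* closed states are re-opened when rediscovered with a strictly lower g
  (this keeps the suboptimality bound valid for dynamic schedules);
* a weight change rebuilds the entire OPEN priority structure eagerly;
* floating-point comparisons use an absolute tolerance of 1e-9.
"""

from __future__ import annotations

import csv
import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Iterable, Optional, Sequence

from .errors import ConfigError, DomainError, NodeBudgetExceeded

State = Hashable

#: Default expansion budget; keeps degenerate configurations bounded.
DEFAULT_NODE_BUDGET = 5_000_000

#: Absolute tolerance for cost comparisons when costs are floats.
COST_EPS = 1e-9


def evaluate(g: float, h: float, omega: float) -> float:
    """Weighted evaluation function ``f = (1 - omega) * g + omega * h``.

    Parameters
    ----------
    g : accumulated path cost, ``>= 0``.
    h : heuristic estimate of remaining cost, ``>= 0``.
    omega : weighting coefficient in ``[0, 1]``; 0.5 reproduces the
        classical A* ordering up to a positive scale factor.

    Raises
    ------
    DomainError
        If ``omega`` lies outside ``[0, 1]`` or ``g``/``h`` is negative.
    """
    if not 0.0 <= omega <= 1.0:
        raise DomainError(f"omega must lie in [0, 1], got {omega!r}")
    if g < 0 or h < 0:
        raise DomainError(f"g and h must be non-negative, got g={g!r}, h={h!r}")
    return (1.0 - omega) * g + omega * h


@dataclass(frozen=True)
class SearchProblem:
    """An abstract state-space search task.

    Attributes
    ----------
    initial_state : opaque hashable state token.
    goal_test : predicate on states.
    successors : maps a state to an iterable of ``(state, edge_cost)``
        pairs with strictly positive edge costs.
    heuristic : maps a state to ``h >= 0``; must be 0 at any goal.
    """

    initial_state: State
    goal_test: Callable[[State], bool]
    successors: Callable[[State], Iterable[tuple[State, float]]]
    heuristic: Callable[[State], float]


@dataclass(frozen=True)
class WeightSchedule:
    """A weighting policy: initial omega plus progression-triggered changes.

    ``triggers`` is an ordered sequence of ``(trigger_fraction, new_weight)``
    pairs; a trigger fires once ``nodes_expanded >= fraction *
    reference_exploration``.  With ``monotone`` set, an installed weight may
    only increase over the run (a lower candidate keeps the current omega).

    Weights are restricted to ``[0.5, 1)``: 0.5 encodes the unmodified A*
    ordering, values above bias towards the heuristic.
    """

    initial_weight: float = 0.5
    triggers: tuple[tuple[float, float], ...] = ()
    monotone: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "triggers", tuple(tuple(t) for t in self.triggers))
        if not 0.5 <= self.initial_weight < 1.0:
            raise ConfigError(
                f"initial_weight must lie in [0.5, 1), got {self.initial_weight!r}"
            )
        prev_frac = -math.inf
        prev_w = self.initial_weight
        for frac, w in self.triggers:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"trigger fraction {frac!r} outside [0, 1]")
            if frac <= prev_frac:
                raise ConfigError("trigger fractions must be strictly increasing")
            if not 0.5 <= w < 1.0:
                raise ConfigError(f"trigger weight {w!r} outside [0.5, 1)")
            if self.monotone and w < prev_w:
                raise ConfigError(
                    "monotone schedule requires non-decreasing weights"
                )
            prev_frac, prev_w = frac, w

    @property
    def max_weight(self) -> float:
        return max([self.initial_weight] + [w for _, w in self.triggers])


#: Schedule encoding an unmodified admissible A* run.
TRIVIAL_SCHEDULE = WeightSchedule()


@dataclass(frozen=True)
class TraceRecord:
    """One node expansion: index, state, g, h, f, omega in effect, OPEN size."""

    expansion_index: int
    state: State
    g: float
    h: float
    f: float
    omega: float
    open_size: int


@dataclass
class SearchTrace:
    """Per-expansion log of a search run plus the solution, if any."""

    expansions: list[TraceRecord] = field(default_factory=list)
    solution_path: Optional[list[State]] = None
    solution_cost: Optional[float] = None

    @property
    def nodes_expanded(self) -> int:
        return len(self.expansions)

    @property
    def solved(self) -> bool:
        return self.solution_path is not None

    def h_series(self) -> list[float]:
        """Heuristic value of each expanded node, in expansion order."""
        return [rec.h for rec in self.expansions]

    def expansion_states(self) -> list[State]:
        return [rec.state for rec in self.expansions]

    def to_csv(self, path) -> None:
        """Write one row per expansion (the external trace format)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["expansion_index", "state_id", "g", "h", "f", "omega", "open_size"]
            )
            for rec in self.expansions:
                writer.writerow(
                    [
                        rec.expansion_index,
                        str(rec.state),
                        rec.g,
                        rec.h,
                        rec.f,
                        rec.omega,
                        rec.open_size,
                    ]
                )

    def summary(self) -> dict[str, Any]:
        return {
            "nodes_expanded": self.nodes_expanded,
            "solved": self.solved,
            "solution_cost": self.solution_cost,
            "solution_length": (
                len(self.solution_path) if self.solution_path is not None else None
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass(frozen=True)
class BoundReport:
    """Suboptimality accounting for a (possibly dynamic) weighted run.

    ``suboptimality_bound`` is ``omega / (1 - omega)`` for the largest
    omega applied; ``bound_satisfied`` asserts
    ``achieved_cost <= suboptimality_bound * optimal_cost``.
    """

    weight_used: float
    suboptimality_bound: float
    optimal_cost: float
    achieved_cost: Optional[float]
    bound_satisfied: bool

    @staticmethod
    def from_run(
        weight_used: float, optimal_cost: float, achieved_cost: Optional[float]
    ) -> "BoundReport":
        bound = weight_used / (1.0 - weight_used)
        ok = (
            achieved_cost is not None
            and achieved_cost <= bound * optimal_cost + COST_EPS
        )
        return BoundReport(weight_used, bound, optimal_cost, achieved_cost, ok)

    def to_dict(self) -> dict[str, Any]:
        return {
            "weight_used": self.weight_used,
            "suboptimality_bound": self.suboptimality_bound,
            "optimal_cost": self.optimal_cost,
            "achieved_cost": self.achieved_cost,
            "bound_satisfied": self.bound_satisfied,
        }


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


def _core_search(
    problem: SearchProblem,
    schedule: WeightSchedule,
    reference_exploration: Optional[int],
    node_budget: int,
) -> tuple[SearchTrace, float]:
    """Shared best-first loop.  Returns (trace, max omega applied).

    OPEN is a lazy-deletion binary heap keyed by
    ``((1 - omega) * g + omega * h, -g, tick)`` where ``tick`` is a global
    insertion counter implementing FIFO tie-breaking.  ``open_info`` maps
    each open state to its current ``(g, h, parent, tick)``; stale heap
    entries are skipped on pop.  A fired trigger rebuilds the heap from
    ``open_info`` with the new omega, preserving ticks so tie order
    survives the rebuild.
    """
    omega = schedule.initial_weight
    max_omega = omega
    pending = list(schedule.triggers)

    heuristic = problem.heuristic
    successors = problem.successors
    goal_test = problem.goal_test

    h_cache: dict[State, float] = {}

    def h_of(s: State) -> float:
        try:
            return h_cache[s]
        except KeyError:
            val = heuristic(s)
            h_cache[s] = val
            return val

    tick = 0
    start = problem.initial_state
    g0, h0 = 0.0, h_of(start)
    open_info: dict[State, tuple[float, float, Optional[State], int]] = {
        start: (g0, h0, None, tick)
    }
    heap: list[tuple[float, float, int, State]] = [
        ((1.0 - omega) * g0 + omega * h0, -g0, tick, start)
    ]
    closed: dict[State, float] = {}
    came_from: dict[State, Optional[State]] = {}

    records: list[TraceRecord] = []
    trace = SearchTrace(expansions=records)
    n_expanded = 0

    while heap:
        # Fire any triggers whose exploration fraction has been reached.
        while (
            pending
            and reference_exploration is not None
            and n_expanded >= pending[0][0] * reference_exploration
        ):
            _, new_w = pending.pop(0)
            if schedule.monotone and new_w < omega:
                continue
            if new_w != omega:
                omega = new_w
                max_omega = max(max_omega, omega)
                heap = [
                    ((1.0 - omega) * g + omega * h, -g, tk, s)
                    for s, (g, h, _, tk) in open_info.items()
                ]
                heapq.heapify(heap)

        key_f, neg_g, tk, state = heapq.heappop(heap)
        info = open_info.get(state)
        if info is None or info[3] != tk:
            continue  # stale entry
        g, h, parent, _ = info
        del open_info[state]
        closed[state] = g
        came_from[state] = parent

        records.append(
            TraceRecord(n_expanded, state, g, h, evaluate(g, h, omega), omega,
                        len(open_info))
        )
        n_expanded += 1

        if goal_test(state):
            path = [state]
            cur: Optional[State] = state
            while came_from[cur] is not None:
                cur = came_from[cur]
                path.append(cur)
            path.reverse()
            trace.solution_path = path
            trace.solution_cost = g
            return trace, max_omega

        if n_expanded >= node_budget:
            raise NodeBudgetExceeded(
                f"node budget of {node_budget} expansions exhausted"
            )

        for s2, cost in successors(state):
            if cost <= 0:
                raise DomainError(f"edge cost must be strictly positive, got {cost!r}")
            g2 = g + cost
            old_g = closed.get(s2)
            if old_g is not None:
                if g2 < old_g - COST_EPS:
                    del closed[s2]  # re-open with the better path
                else:
                    continue
            cur_info = open_info.get(s2)
            if cur_info is not None and cur_info[0] <= g2 + COST_EPS:
                continue
            h2 = h_of(s2)
            tick += 1
            open_info[s2] = (g2, h2, state, tick)
            heapq.heappush(
                heap, ((1.0 - omega) * g2 + omega * h2, -g2, tick, s2)
            )

    return trace, max_omega  # exhausted without a goal: unsolved trace


# ---------------------------------------------------------------------------
# public engines
# ---------------------------------------------------------------------------


def astar(
    problem: SearchProblem, node_budget: int = DEFAULT_NODE_BUDGET
) -> SearchTrace:
    """Admissible A* (omega fixed at 0.5, i.e. the classical g + h ordering).

    Returns a fully populated trace; if the reachable space is exhausted
    without a goal, the trace has no solution (no exception is raised).
    Optimal whenever the problem's heuristic is admissible.
    """
    trace, _ = _core_search(problem, TRIVIAL_SCHEDULE, None, node_budget)
    return trace


def weighted_astar(
    problem: SearchProblem,
    schedule: WeightSchedule,
    reference_exploration: int = 1,
    node_budget: int = DEFAULT_NODE_BUDGET,
    optimal_cost: Optional[float] = None,
) -> tuple[SearchTrace, BoundReport]:
    """Weighted A* with mid-search dynamic re-weighting.

    Parameters
    ----------
    schedule : the weighting policy; trigger fractions are converted to
        expansion counts via ``reference_exploration``.
    reference_exploration : expected nodes-expanded of the admissible run
        on this instance (used only to time triggers; must be > 0).
    optimal_cost : cost of the optimal solution for the bound report.
        When omitted, an admissible reference run is performed internally.

    Returns
    -------
    (SearchTrace, BoundReport)
    """
    if reference_exploration <= 0:
        raise ConfigError("reference_exploration must be positive")
    trace, max_omega = _core_search(
        problem, schedule, reference_exploration, node_budget
    )
    if optimal_cost is None:
        ref = astar(problem, node_budget=node_budget)
        if ref.solution_cost is None:
            raise DomainError("reference run found no solution; optimum undefined")
        optimal_cost = ref.solution_cost
    report = BoundReport.from_run(max_omega, optimal_cost, trace.solution_cost)
    return trace, report


def focal_search(
    problem: SearchProblem,
    epsilon: float,
    secondary_h: Callable[[State], float],
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> SearchTrace:
    """FOCAL (A*-epsilon) search.

    At each step FOCAL = {n in OPEN : f(n) <= (1 + epsilon) * min f}; the
    node minimising ``secondary_h`` within FOCAL is expanded (ties broken
    by f, then insertion order).  With an admissible primary heuristic the
    solution cost is at most ``(1 + epsilon)`` times the optimum.

    The trace records omega = 0.5, under which f is the A* ordering used
    to build FOCAL (membership is scale-invariant).
    """
    if epsilon < 0:
        raise DomainError(f"epsilon must be non-negative, got {epsilon!r}")

    heuristic = problem.heuristic
    h_cache: dict[State, float] = {}
    h2_cache: dict[State, float] = {}

    def h_of(s: State) -> float:
        if s not in h_cache:
            h_cache[s] = heuristic(s)
        return h_cache[s]

    def h2_of(s: State) -> float:
        if s not in h2_cache:
            h2_cache[s] = secondary_h(s)
        return h2_cache[s]

    tick = 0
    start = problem.initial_state
    open_info: dict[State, tuple[float, float, Optional[State], int]] = {
        start: (0.0, h_of(start), None, 0)
    }
    heap: list[tuple[float, float, int, State]] = [(h_of(start), 0.0, 0, start)]
    closed: dict[State, float] = {}
    came_from: dict[State, Optional[State]] = {}

    records: list[TraceRecord] = []
    trace = SearchTrace(expansions=records)
    n_expanded = 0

    while open_info:
        # Drop stale heap heads, then read the valid minimum f.
        while heap:
            f_min, neg_g, tk, s = heap[0]
            info = open_info.get(s)
            if info is None or info[3] != tk:
                heapq.heappop(heap)
            else:
                break
        if not heap:
            break
        bound = (1.0 + epsilon) * f_min + COST_EPS

        # Select argmin of (secondary, f, insertion order) within FOCAL.
        best = None
        for entry in heap:
            f_e, _, tk_e, s_e = entry
            if f_e > bound:
                continue
            info = open_info.get(s_e)
            if info is None or info[3] != tk_e:
                continue
            key = (h2_of(s_e), f_e, tk_e)
            if best is None or key < best[0]:
                best = (key, s_e)
        assert best is not None
        state = best[1]

        g, h, parent, _ = open_info.pop(state)
        closed[state] = g
        came_from[state] = parent
        records.append(
            TraceRecord(n_expanded, state, g, h, evaluate(g, h, 0.5), 0.5,
                        len(open_info))
        )
        n_expanded += 1

        if problem.goal_test(state):
            path = [state]
            cur: Optional[State] = state
            while came_from[cur] is not None:
                cur = came_from[cur]
                path.append(cur)
            path.reverse()
            trace.solution_path = path
            trace.solution_cost = g
            return trace

        if n_expanded >= node_budget:
            raise NodeBudgetExceeded(
                f"node budget of {node_budget} expansions exhausted"
            )

        for s2, cost in problem.successors(state):
            if cost <= 0:
                raise DomainError(f"edge cost must be strictly positive, got {cost!r}")
            g2 = g + cost
            old_g = closed.get(s2)
            if old_g is not None:
                if g2 < old_g - COST_EPS:
                    del closed[s2]
                else:
                    continue
            cur_info = open_info.get(s2)
            if cur_info is not None and cur_info[0] <= g2 + COST_EPS:
                continue
            h2 = h_of(s2)
            tick += 1
            open_info[s2] = (g2, h2, state, tick)
            heapq.heappush(heap, (g2 + h2, -g2, tick, s2))

    return trace


def backtracking_score(trace: SearchTrace) -> int:
    """Count expansions whose h exceeds the previously expanded node's h.

    An operational proxy for backtracking: a monotone descent towards the
    goal scores 0, while oscillations of the expanded-node heuristic
    trajectory each add one.
    """
    if not trace.expansions:
        raise DomainError("backtracking_score requires a non-empty trace")
    hs = trace.h_series()
    return sum(1 for a, b in zip(hs, hs[1:]) if b > a + COST_EPS)
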