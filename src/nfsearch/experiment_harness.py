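"""Scripted, seeded characterisation studies of the weighted-search loop.

Reproduces the speed-accuracy characterisation experiments as batch
studies: weighting-coefficient sweeps, intervention-timing sweeps,
heuristic-trajectory reports (backtracking), and cohort-level closed-loop
summaries over populations of virtual subjects.  Node counts are
heavy-tailed across instances, so sweeps are summarised by medians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .asymmetry_stats import score_block, session_success
from .bci_mapping import (
    LoopResult,
    MappingConfig,
    map_effect_to_weight,
    run_closed_loop_grid,
    run_closed_loop_puzzle,
)
from .errors import ConfigError
from .neuro_signal import BlockProtocol, VirtualSubject, simulate_session
from .search_core import (
    SearchTrace,
    WeightSchedule,
    astar,
    backtracking_score,
    weighted_astar,
)
from .task_domains import (
    GridMap,
    PuzzleState,
    grid_problem,
    puzzle_problem,
)

Instance = tuple[PuzzleState, PuzzleState]
Domain = Union[Instance, GridMap]


@dataclass
class SweepResult:
    """Per-instance node counts over a sweep axis (weights or fractions).

    ``reduction[i, j] = 1 - nodes[i, j] / reference_nodes[i]`` and
    ``cost_ratio[i, j] = achieved cost / optimal cost``; the reference is
    the admissible run on the same instance.
    """

    axis: list[float]
    axis_name: str
    nodes_expanded: np.ndarray  # (n_instances, n_axis)
    reduction: np.ndarray
    cost_ratio: np.ndarray
    reference_nodes: np.ndarray
    optimal_costs: np.ndarray

    def median_nodes(self) -> np.ndarray:
        return np.median(self.nodes_expanded, axis=0)

    def median_reduction(self) -> np.ndarray:
        return np.median(self.reduction, axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.nodes_expanded.shape[0]):
            for j, x in enumerate(self.axis):
                rows.append(
                    {
                        "instance": i,
                        self.axis_name: x,
                        "nodes_expanded": self.nodes_expanded[i, j],
                        "reduction": self.reduction[i, j],
                        "cost_ratio": self.cost_ratio[i, j],
                        "reference_nodes": self.reference_nodes[i],
                        "optimal_cost": self.optimal_costs[i],
                    }
                )
        return pd.DataFrame(rows)


def _problem_for(domain: Domain):
    if isinstance(domain, GridMap):
        return grid_problem(domain)
    start, goal = domain
    return puzzle_problem(start, goal)


def sweep_weighting(
    instances: Sequence[Domain],
    omega_grid: Sequence[float],
    seed: int = 0,
) -> SweepResult:
    """Fixed-weight WA* over every (instance, omega) cell.

    The omega = 0.5 cell reproduces the admissible reference run, so its
    reduction is exactly 0.  Deterministic; ``seed`` kept for interface
    symmetry with the stochastic studies.
    """
    omega_grid = list(omega_grid)
    n_i, n_w = len(instances), len(omega_grid)
    nodes = np.zeros((n_i, n_w))
    cost = np.zeros((n_i, n_w))
    ref_nodes = np.zeros(n_i)
    opt_costs = np.zeros(n_i)
    for i, inst in enumerate(instances):
        problem = _problem_for(inst)
        ref = astar(problem)
        ref_nodes[i] = ref.nodes_expanded
        opt_costs[i] = ref.solution_cost
        for j, w in enumerate(omega_grid):
            if w == 0.5:
                trace = ref
            else:
                trace, _ = weighted_astar(
                    problem,
                    WeightSchedule(initial_weight=w),
                    optimal_cost=ref.solution_cost,
                )
            nodes[i, j] = trace.nodes_expanded
            cost[i, j] = trace.solution_cost
    return SweepResult(
        axis=omega_grid,
        axis_name="omega",
        nodes_expanded=nodes,
        reduction=1.0 - nodes / ref_nodes[:, None],
        cost_ratio=cost / opt_costs[:, None],
        reference_nodes=ref_nodes,
        optimal_costs=opt_costs,
    )


def sweep_intervention_timing(
    instance: Domain,
    omega_fixed: float,
    fraction_grid: Sequence[float],
    seed: int = 0,
) -> SweepResult:
    """Dynamic WA* on one instance, triggered at each fraction of the
    admissible reference exploration.  Fraction 0 is a fixed-weight run."""
    fraction_grid = list(fraction_grid)
    problem = _problem_for(instance)
    ref = astar(problem)
    n_f = len(fraction_grid)
    nodes = np.zeros((1, n_f))
    cost = np.zeros((1, n_f))
    for j, frac in enumerate(fraction_grid):
        schedule = WeightSchedule(
            initial_weight=0.5, triggers=((frac, omega_fixed),)
        )
        trace, _ = weighted_astar(
            problem,
            schedule,
            reference_exploration=ref.nodes_expanded,
            optimal_cost=ref.solution_cost,
        )
        nodes[0, j] = trace.nodes_expanded
        cost[0, j] = trace.solution_cost
    ref_nodes = np.array([ref.nodes_expanded], dtype=float)
    opt_costs = np.array([ref.solution_cost], dtype=float)
    return SweepResult(
        axis=fraction_grid,
        axis_name="trigger_fraction",
        nodes_expanded=nodes,
        reduction=1.0 - nodes / ref_nodes[:, None],
        cost_ratio=cost / opt_costs[:, None],
        reference_nodes=ref_nodes,
        optimal_costs=opt_costs,
    )


def trajectory_report(trace: SearchTrace) -> dict:
    """Expanded-node heuristic trajectory plus oscillation summary.

    Returns the h-by-expansion series, the backtracking score, and the
    least-squares slope of h on expansion index (negative for an overall
    descent towards the goal)."""
    h = np.asarray(trace.h_series(), dtype=float)
    slope = float(np.polyfit(np.arange(len(h)), h, 1)[0]) if len(h) > 1 else 0.0
    return {
        "h_series": h,
        "backtracking_score": backtracking_score(trace),
        "h_slope": slope,
        "nodes_expanded": trace.nodes_expanded,
    }


def plot_trajectory(trace: SearchTrace, ax=None):
    """Plot the expanded-node heuristic trajectory (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rep = trajectory_report(trace)
    ax.plot(rep["h_series"], lw=0.8)
    ax.set_xlabel("expansion index")
    ax.set_ylabel("h of expanded node")
    return ax


SubjectFactory = Callable[[int, np.random.Generator], VirtualSubject]


def cohort_study(
    n_subjects: int,
    subject_factory: SubjectFactory,
    protocol: BlockProtocol,
    cfg: MappingConfig = MappingConfig(),
    domain: Optional[Domain] = None,
    seed: int = 0,
    n_blocks: int = 4,
) -> pd.DataFrame:
    """Session-success table for a cohort of sampled virtual subjects.

    For each subject, ``n_blocks`` NF blocks are simulated and scored and
    session success (at least half of blocks successful) recorded.  When
    a ``domain`` is supplied, a closed-loop run on it also records the
    final weight and search-space reduction.  Fully reproducible from
    ``seed``.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 777)))
    rows = []
    for i in range(n_subjects):
        subject = subject_factory(i, rng)
        subj_seed = int(rng.integers(0, 2**31 - 1))
        session = simulate_session(subject, protocol, n_blocks, seed=subj_seed)
        stats = [
            score_block(
                stream,
                protocol,
                alpha=cfg.alpha,
                boot_reps=cfg.boot_reps,
                boot_threshold=cfg.boot_threshold,
                seed=subj_seed + k,
            )
            for k, stream in enumerate(session)
        ]
        n_ok = sum(1 for b in stats if b.success)
        row = {
            "subject": i,
            "responder": subject.responder,
            "n_blocks": n_blocks,
            "n_success": n_ok,
            "session_success": session_success(stats),
            "mean_effect_size": float(np.mean([b.effect_size for b in stats])),
        }
        if domain is not None:
            if isinstance(domain, GridMap):
                loop = run_closed_loop_grid(
                    domain, subject, protocol, cfg, n_updates=n_blocks,
                    seed=subj_seed,
                )
            else:
                loop = run_closed_loop_puzzle(
                    domain, subject, protocol, cfg, seed=subj_seed
                )
            row["omega_applied"] = loop.omega_applied
            row["search_space_reduction"] = loop.search_space_reduction
            row["bound_satisfied"] = loop.bound.bound_satisfied
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["cohort_success_rate"] = float(df["session_success"].mean())
    return df


def save_study(
    out_dir,
    results: pd.DataFrame,
    config: dict,
    manifest_extra: Optional[dict] = None,
) -> None:
    """Write a study directory: config.yaml, results.csv, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    results.to_csv(out / "results.csv", index=False)
    manifest = {"n_rows": len(results)}
    manifest.update(results.attrs)
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
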