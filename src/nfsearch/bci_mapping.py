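"""Mapping block statistics onto search weights and running the closed loop.

The controller translates a scored NF block into a weighted-A* weighting
coefficient by a clamped linear map on the effect size d:

    omega = omega_base + min(max(d, 0), d_max) / d_max * (omega_max - omega_base)

gated (by default) on block success — a non-significant block leaves the
search admissible at omega_base = 0.5.  The mapped weight is installed
as a progression trigger in the running search:

* the 8-puzzle loop scores a single NF block and installs one trigger
  early in the search (within the first quarter of the reference
  exploration);
* the grid loop scores one block per update window and installs the
  running maximum of the candidate weights as a monotone schedule whose
  triggers are spread evenly over the run.

NF scoring and search progression are deliberately decoupled: the search
is (conceptually) paused at each trigger until its block score is
available, so no real-time co-scheduling is modelled.  The normalised
feedback value shown to the (virtual) subject during NF is the
baseline-referenced asymmetry scaled by a target gain and clamped to
[0, 1] — 1 denotes maximal focusing of the search-beam display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .asymmetry_stats import BlockStats, extract_windows, score_block
from .errors import ConfigError, DomainError
from .neuro_signal import BlockProtocol, NirsStream, VirtualSubject, simulate_session
from .search_core import (
    BoundReport,
    SearchTrace,
    WeightSchedule,
    astar,
    weighted_astar,
)
from .task_domains import GridMap, PuzzleState, grid_problem, puzzle_problem


@dataclass(frozen=True)
class MappingConfig:
    """Constants of the effect-size-to-weight map and loop timing.

    ``omega_max`` defaults to 0.6, bracketing the operative weights of
    the speed-accuracy characterisation (0.55-0.575) with headroom;
    ``d_max`` = 1.5 is a conventionally very large effect at which the
    ceiling weight is reached.  ``trigger_fraction`` places the single
    puzzle-loop intervention and must lie within
    ``trigger_fraction_range`` (default: the first quarter of the
    reference exploration).
    """

    omega_base: float = 0.5
    omega_max: float = 0.6
    d_max: float = 1.5
    require_significance: bool = True
    trigger_fraction: float = 0.1
    trigger_fraction_range: tuple[float, float] = (0.0, 0.25)
    alpha: float = 0.05
    boot_reps: int = 1000
    boot_threshold: float = 0.95
    feedback_target_gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.omega_base < self.omega_max < 1.0:
            raise ConfigError(
                f"need omega_base < omega_max < 1, got "
                f"{self.omega_base}, {self.omega_max}"
            )
        if self.d_max <= 0:
            raise ConfigError(f"d_max must be positive, got {self.d_max}")
        lo, hi = self.trigger_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("trigger_fraction_range must be within [0, 1]")
        if not lo <= self.trigger_fraction <= hi:
            raise ConfigError(
                f"trigger_fraction {self.trigger_fraction} outside "
                f"range {self.trigger_fraction_range}"
            )
        if self.feedback_target_gain <= 0:
            raise ConfigError("feedback_target_gain must be positive")


def map_effect_to_weight(stats: BlockStats, cfg: MappingConfig) -> float:
    """Clamped linear map from effect size to the weighting coefficient.

    Returns ``omega_base`` when significance is required and the block
    failed; otherwise interpolates linearly in d between ``omega_base``
    (d <= 0) and ``omega_max`` (d >= d_max).
    """
    if cfg.require_significance and not stats.success:
        return cfg.omega_base
    d = min(max(stats.effect_size, 0.0), cfg.d_max)
    return cfg.omega_base + d / cfg.d_max * (cfg.omega_max - cfg.omega_base)


def feedback_value(
    current_asymmetry: float, baseline_mean: float, target_gain: float
) -> float:
    """Normalised NF display value in [0, 1]; 1 = the narrowest beam."""
    if target_gain <= 0:
        raise DomainError(f"target_gain must be positive, got {target_gain}")
    return float(
        np.clip((current_asymmetry - baseline_mean) / target_gain, 0.0, 1.0)
    )


@dataclass
class LoopResult:
    """Outcome of one closed-loop run (one or more NF scoring windows)."""

    block_stats: list[BlockStats]
    candidate_weights: list[float]
    installed_weights: list[float]
    omega_applied: float
    schedule: WeightSchedule
    trace: SearchTrace
    bound: BoundReport
    feedback_series: list[np.ndarray]
    reference_exploration: int
    search_space_reduction: float

    def to_json_dict(self) -> dict:
        return {
            "block_stats": [b.to_dict() for b in self.block_stats],
            "candidate_weights": list(self.candidate_weights),
            "installed_weights": list(self.installed_weights),
            "omega_applied": self.omega_applied,
            "schedule": {
                "initial_weight": self.schedule.initial_weight,
                "triggers": [list(t) for t in self.schedule.triggers],
                "monotone": self.schedule.monotone,
            },
            "nodes_expanded": self.trace.nodes_expanded,
            "solution_cost": self.trace.solution_cost,
            "solution_length": (
                len(self.trace.solution_path)
                if self.trace.solution_path is not None
                else None
            ),
            "bound": self.bound.to_dict(),
            "feedback_series": [list(map(float, f)) for f in self.feedback_series],
            "reference_exploration": self.reference_exploration,
            "search_space_reduction": self.search_space_reduction,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)


def _feedback_for_block(
    stream: NirsStream, protocol: BlockProtocol, target_gain: float
) -> np.ndarray:
    win = extract_windows(stream, protocol)
    return np.clip(
        (win.nf_samples - win.baseline_mean) / target_gain, 0.0, 1.0
    )


def run_closed_loop_puzzle(
    instance: tuple[PuzzleState, PuzzleState],
    subject: VirtualSubject,
    protocol: BlockProtocol,
    cfg: MappingConfig = MappingConfig(),
    seed: int = 0,
) -> LoopResult:
    """One NF block steering one 8-puzzle search.

    An admissible reference run fixes the exploration size and optimal
    cost; the block is scored, mapped to a weight, and installed as a
    single trigger at ``cfg.trigger_fraction`` of the reference
    exploration.  Records the search-space reduction
    ``1 - nodes_expanded / reference_exploration``.
    """
    start, goal = instance
    problem = puzzle_problem(start, goal)
    reference = astar(problem)
    if reference.solution_cost is None:
        raise DomainError("instance is unsolvable")
    ref_nodes = reference.nodes_expanded

    [stream] = simulate_session(subject, protocol, 1, seed=seed)
    stats = score_block(
        stream,
        protocol,
        alpha=cfg.alpha,
        boot_reps=cfg.boot_reps,
        boot_threshold=cfg.boot_threshold,
        seed=seed,
    )
    omega = map_effect_to_weight(stats, cfg)
    schedule = WeightSchedule(
        initial_weight=cfg.omega_base,
        triggers=((cfg.trigger_fraction, omega),) if omega > cfg.omega_base else (),
        monotone=True,
    )
    trace, bound = weighted_astar(
        problem,
        schedule,
        reference_exploration=ref_nodes,
        optimal_cost=reference.solution_cost,
    )
    feedback = _feedback_for_block(stream, protocol, cfg.feedback_target_gain)
    return LoopResult(
        block_stats=[stats],
        candidate_weights=[omega],
        installed_weights=[omega],
        omega_applied=omega,
        schedule=schedule,
        trace=trace,
        bound=bound,
        feedback_series=[feedback],
        reference_exploration=ref_nodes,
        search_space_reduction=1.0 - trace.nodes_expanded / ref_nodes,
    )


def run_closed_loop_grid(
    gmap: GridMap,
    subject: VirtualSubject,
    protocol: BlockProtocol,
    cfg: MappingConfig = MappingConfig(),
    n_updates: int = 3,
    seed: int = 0,
) -> LoopResult:
    """Repeated NF interventions steering a grid path-planning search.

    ``n_updates`` blocks are scored; candidate weights are replaced by
    their running maximum (the weighting factor may only increase over
    the run) and installed at evenly spaced progression fractions
    ``j / n_updates``.
    """
    if n_updates < 1:
        raise ConfigError("n_updates must be >= 1")
    problem = grid_problem(gmap)
    reference = astar(problem)
    if reference.solution_cost is None:
        raise DomainError("grid has no start-goal path")
    ref_nodes = reference.nodes_expanded

    session = simulate_session(subject, protocol, n_updates, seed=seed)
    all_stats: list[BlockStats] = []
    candidates: list[float] = []
    feedback: list[np.ndarray] = []
    for k, stream in enumerate(session):
        stats = score_block(
            stream,
            protocol,
            alpha=cfg.alpha,
            boot_reps=cfg.boot_reps,
            boot_threshold=cfg.boot_threshold,
            seed=seed + k,
        )
        all_stats.append(stats)
        candidates.append(map_effect_to_weight(stats, cfg))
        feedback.append(_feedback_for_block(stream, protocol, cfg.feedback_target_gain))

    installed = [float(w) for w in np.maximum.accumulate(candidates)]
    triggers = tuple(
        (j / n_updates, installed[j])
        for j in range(n_updates)
        if installed[j] > cfg.omega_base
    )
    # collapse consecutive triggers carrying the same weight
    deduped = []
    for frac, w in triggers:
        if not deduped or w > deduped[-1][1]:
            deduped.append((frac, w))
    schedule = WeightSchedule(
        initial_weight=cfg.omega_base, triggers=tuple(deduped), monotone=True
    )
    trace, bound = weighted_astar(
        problem,
        schedule,
        reference_exploration=ref_nodes,
        optimal_cost=reference.solution_cost,
    )
    return LoopResult(
        block_stats=all_stats,
        candidate_weights=candidates,
        installed_weights=installed,
        omega_applied=installed[-1],
        schedule=schedule,
        trace=trace,
        bound=bound,
        feedback_series=feedback,
        reference_exploration=ref_nodes,
        search_space_reduction=1.0 - trace.nodes_expanded / ref_nodes,
    )
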