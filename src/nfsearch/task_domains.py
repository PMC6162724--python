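"""Benchmark search domains: the 8-puzzle and grid-based path planning.

Both domains are exposed as :class:`~nfsearch.search_core.SearchProblem`
providers with admissible, consistent heuristics (Manhattan distance for
the puzzle, Euclidean straight-line distance for grids), together with
seeded instance generators and exhaustive oracles (breadth-first search
over the 181,440-state reachable half of the puzzle space; Dijkstra over
grid graphs) used to label instance difficulty and to verify optimality.

Conventions: coordinates are 0-based ``(row, col)`` with row 0 at the
top; puzzle states are serialised as 9-character digit strings in
row-major order with ``0`` denoting the blank.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import ConfigError, DomainError, FormatError, GenerationError
from .search_core import SearchProblem

# ---------------------------------------------------------------------------
# 8-puzzle
# ---------------------------------------------------------------------------

#: Blank-index -> indices reachable by sliding one tile (3x3 board).
_PUZZLE_MOVES: tuple[tuple[int, ...], ...] = tuple(
    tuple(
        r2 * 3 + c2
        for r2, c2 in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
        if 0 <= r2 < 3 and 0 <= c2 < 3
    )
    for r in range(3)
    for c in range(3)
)


@dataclass(frozen=True)
class PuzzleState:
    """A 3x3 sliding-tile arrangement; ``tiles`` is a 9-digit string, 0 = blank."""

    tiles: str

    def __post_init__(self) -> None:
        if len(self.tiles) != 9 or sorted(self.tiles) != list("012345678"):
            raise DomainError(
                f"tiles must be a permutation of digits 0-8, got {self.tiles!r}"
            )

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "PuzzleState":
        return cls("".join(str(v) for row in rows for v in row))

    @property
    def rows(self) -> tuple[tuple[int, ...], ...]:
        return tuple(
            tuple(int(self.tiles[r * 3 + c]) for c in range(3)) for r in range(3)
        )

    def __str__(self) -> str:
        return self.tiles


#: Canonical goal: tiles 1..8 in order, blank at bottom-right.
GOAL = PuzzleState("123456780")


def puzzle_neighbours(tiles: str) -> list[str]:
    """Serialised states reachable by one slide (unit cost each)."""
    blank = tiles.index("0")
    out = []
    lst = list(tiles)
    for j in _PUZZLE_MOVES[blank]:
        lst[blank], lst[j] = lst[j], lst[blank]
        out.append("".join(lst))
        lst[j], lst[blank] = lst[blank], lst[j]
    return out


@lru_cache(maxsize=32)
def _goal_positions(goal_tiles: str) -> tuple[tuple[int, int], ...]:
    pos = [(0, 0)] * 9
    for idx, ch in enumerate(goal_tiles):
        pos[int(ch)] = divmod(idx, 3)
    return tuple(pos)


def puzzle_heuristic(state: PuzzleState | str, goal: PuzzleState | str = GOAL) -> int:
    """Sum of Manhattan (city-block) distances of non-blank tiles to their
    goal cells; admissible and consistent for unit-cost slides."""
    s = state.tiles if isinstance(state, PuzzleState) else state
    g = goal.tiles if isinstance(goal, PuzzleState) else goal
    if sorted(s) != list("012345678"):
        raise DomainError(f"invalid puzzle state {s!r}")
    pos = _goal_positions(g)
    total = 0
    for idx, ch in enumerate(s):
        if ch == "0":
            continue
        r, c = divmod(idx, 3)
        gr, gc = pos[int(ch)]
        total += abs(r - gr) + abs(c - gc)
    return total


def puzzle_solvable(state: PuzzleState | str, goal: PuzzleState | str = GOAL) -> bool:
    """True iff ``state`` can reach ``goal``: the permutation carrying the
    non-blank tile order of one to the other must be even (the slide move
    preserves this parity on a width-3 board)."""
    s = state.tiles if isinstance(state, PuzzleState) else state
    g = goal.tiles if isinstance(goal, PuzzleState) else goal
    seq_s = [ch for ch in s if ch != "0"]
    seq_g = [ch for ch in g if ch != "0"]
    rank = {ch: i for i, ch in enumerate(seq_g)}
    perm = [rank[ch] for ch in seq_s]
    inversions = sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )
    return inversions % 2 == 0


def puzzle_problem(
    start: PuzzleState | str, goal: PuzzleState | str = GOAL
) -> SearchProblem:
    """Unit-cost SearchProblem over serialised puzzle states."""
    s = start.tiles if isinstance(start, PuzzleState) else PuzzleState(start).tiles
    g = goal.tiles if isinstance(goal, PuzzleState) else PuzzleState(goal).tiles
    pos = _goal_positions(g)

    def heuristic(tiles: str) -> int:
        total = 0
        for idx, ch in enumerate(tiles):
            if ch != "0":
                r, c = divmod(idx, 3)
                gr, gc = pos[int(ch)]
                total += abs(r - gr) + abs(c - gc)
        return total

    return SearchProblem(
        initial_state=s,
        goal_test=lambda t: t == g,
        successors=lambda t: [(n, 1) for n in puzzle_neighbours(t)],
        heuristic=heuristic,
    )


@lru_cache(maxsize=4)
def bfs_distance_table(goal_tiles: str = GOAL.tiles) -> dict[str, int]:
    """Exact move distances from every reachable state to ``goal_tiles``,
    by exhaustive breadth-first search (181,440 states).

    This is the brute-force oracle used to label instance difficulty and
    to check A* optimality; it is independent of the best-first engines.
    """
    PuzzleState(goal_tiles)  # validate
    dist = {goal_tiles: 0}
    frontier = [goal_tiles]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for s in frontier:
            for t in puzzle_neighbours(s):
                if t not in dist:
                    dist[t] = d
                    nxt.append(t)
        frontier = nxt
    return dist


def optimal_puzzle_cost(
    start: PuzzleState | str, goal: PuzzleState | str = GOAL
) -> int:
    """Oracle-optimal solution length; DomainError if unsolvable."""
    s = start.tiles if isinstance(start, PuzzleState) else start
    g = goal.tiles if isinstance(goal, PuzzleState) else goal
    table = bfs_distance_table(g)
    try:
        return table[s]
    except KeyError:
        raise DomainError(f"state {s!r} cannot reach goal {g!r}") from None


def random_scramble(
    goal: PuzzleState | str = GOAL, k: int = 30, seed: int | random.Random = 0
) -> PuzzleState:
    """Apply ``k`` random slides to ``goal``; always yields a solvable state."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    tiles = goal.tiles if isinstance(goal, PuzzleState) else goal
    for _ in range(k):
        tiles = rng.choice(puzzle_neighbours(tiles))
    return PuzzleState(tiles)


#: Longest optimal 8-puzzle solution (the puzzle's diameter in moves).
PUZZLE_DIAMETER = 31


def generate_puzzle_instances(
    n: int,
    difficulty: int = 0,
    seed: int = 0,
    goal: PuzzleState | str = GOAL,
) -> list[tuple[PuzzleState, PuzzleState]]:
    """``n`` solvable instances drawn uniformly from states whose
    oracle-optimal length is ``>= difficulty``, reproducible from ``seed``.

    Sampling is without replacement over the BFS distance table, so every
    returned instance is distinct and its difficulty label exact.
    """
    if difficulty > PUZZLE_DIAMETER:
        raise ConfigError(
            f"difficulty {difficulty} exceeds the 8-puzzle diameter "
            f"({PUZZLE_DIAMETER})"
        )
    goal_state = goal if isinstance(goal, PuzzleState) else PuzzleState(goal)
    table = bfs_distance_table(goal_state.tiles)
    candidates = sorted(s for s, d in table.items() if d >= difficulty)
    if n > len(candidates):
        raise ConfigError(
            f"only {len(candidates)} states have difficulty >= {difficulty}"
        )
    rng = random.Random(seed)
    chosen = rng.sample(candidates, n)
    return [(PuzzleState(s), goal_state) for s in chosen]


# ---------------------------------------------------------------------------
# grid path planning
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class GridMap:
    """An occupancy grid with start and goal cells.

    ``connectivity`` is 4 (unit-cost orthogonal moves) or 8 (adds
    diagonal moves at cost sqrt(2)).
    """

    width: int
    height: int
    blocked: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    start: tuple[int, int] = (0, 0)
    goal: tuple[int, int] = (0, 0)
    connectivity: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocked", frozenset(self.blocked))
        object.__setattr__(self, "start", tuple(self.start))
        object.__setattr__(self, "goal", tuple(self.goal))
        if self.width < 1 or self.height < 1:
            raise ConfigError("grid dimensions must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        for name, cell in (("start", self.start), ("goal", self.goal)):
            if not self.in_bounds(cell):
                raise ConfigError(f"{name} cell {cell} outside the grid")
            if cell in self.blocked:
                raise ConfigError(f"{name} cell {cell} is blocked")

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.height and 0 <= c < self.width

    def free(self, cell: tuple[int, int]) -> bool:
        return self.in_bounds(cell) and cell not in self.blocked

    def successors(self, cell: tuple[int, int]) -> list[tuple[tuple[int, int], float]]:
        r, c = cell
        out: list[tuple[tuple[int, int], float]] = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            t = (r + dr, c + dc)
            if self.free(t):
                out.append((t, 1.0))
        if self.connectivity == 8:
            for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                t = (r + dr, c + dc)
                if self.free(t):
                    out.append((t, _SQRT2))
        return out

    # -- serialisation ----------------------------------------------------

    def to_ascii(self) -> str:
        """`#` blocked, `.` free, `S` start, `G` goal; one row per line."""
        rows = []
        for r in range(self.height):
            line = []
            for c in range(self.width):
                cell = (r, c)
                if cell == self.start:
                    line.append("S")
                elif cell == self.goal:
                    line.append("G")
                elif cell in self.blocked:
                    line.append("#")
                else:
                    line.append(".")
            rows.append("".join(line))
        return "\n".join(rows)

    @classmethod
    def from_ascii(cls, text: str, connectivity: int = 4) -> "GridMap":
        lines = [ln for ln in text.strip().splitlines() if ln]
        if not lines or len({len(ln) for ln in lines}) != 1:
            raise FormatError("ASCII grid rows must be non-empty and equal length")
        blocked = set()
        start = goal = None
        for r, line in enumerate(lines):
            for c, ch in enumerate(line):
                if ch == "#":
                    blocked.add((r, c))
                elif ch == "S":
                    start = (r, c)
                elif ch == "G":
                    goal = (r, c)
                elif ch != ".":
                    raise FormatError(f"unexpected grid character {ch!r}")
        if start is None or goal is None:
            raise FormatError("ASCII grid must contain exactly one S and one G")
        return cls(
            width=len(lines[0]),
            height=len(lines),
            blocked=frozenset(blocked),
            start=start,
            goal=goal,
            connectivity=connectivity,
        )

    def to_json_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "blocked": sorted(list(c) for c in self.blocked),
            "start": list(self.start),
            "goal": list(self.goal),
            "connectivity": self.connectivity,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "GridMap":
        return cls(
            width=data["width"],
            height=data["height"],
            blocked=frozenset(tuple(c) for c in data["blocked"]),
            start=tuple(data["start"]),
            goal=tuple(data["goal"]),
            connectivity=data.get("connectivity", 4),
        )


def grid_heuristic(cell: tuple[int, int], goal_cell: tuple[int, int]) -> float:
    """Euclidean straight-line distance in cell units; admissible for both
    4-connected (unit) and 8-connected (unit / sqrt 2) move costs."""
    return math.hypot(cell[0] - goal_cell[0], cell[1] - goal_cell[1])


def grid_problem(gmap: GridMap) -> SearchProblem:
    goal = gmap.goal
    return SearchProblem(
        initial_state=gmap.start,
        goal_test=lambda c: c == goal,
        successors=gmap.successors,
        heuristic=lambda c: grid_heuristic(c, goal),
    )


def grid_connected(gmap: GridMap) -> bool:
    """Flood-fill check that the goal is reachable from the start."""
    seen = {gmap.start}
    stack = [gmap.start]
    while stack:
        cell = stack.pop()
        if cell == gmap.goal:
            return True
        for t, _ in gmap.successors(cell):
            if t not in seen:
                seen.add(t)
                stack.append(t)
    return False


def grid_graph(gmap: GridMap) -> nx.Graph:
    """The free-cell adjacency graph with move costs as edge weights."""
    g = nx.Graph()
    for r in range(gmap.height):
        for c in range(gmap.width):
            cell = (r, c)
            if not gmap.free(cell):
                continue
            g.add_node(cell)
            for t, w in gmap.successors(cell):
                g.add_edge(cell, t, weight=w)
    return g


def dijkstra_distances(
    gmap: GridMap, source: Optional[tuple[int, int]] = None
) -> dict[tuple[int, int], float]:
    """Exhaustive Dijkstra oracle: optimal cost from ``source`` (default:
    the start cell) to every reachable free cell (networkx implementation,
    independent of the package's best-first engines)."""
    return nx.single_source_dijkstra_path_length(
        grid_graph(gmap), gmap.start if source is None else source, weight="weight"
    )


def optimal_grid_cost(gmap: GridMap) -> float:
    dist = dijkstra_distances(gmap)
    try:
        return dist[gmap.goal]
    except KeyError:
        raise DomainError("goal unreachable from start") from None


def generate_grid(
    width: int,
    height: int,
    obstacle_density: float = 0.0,
    seed: int = 0,
    connectivity: int = 4,
    max_retries: int = 100,
) -> GridMap:
    """A random connected grid with ``round(density * cells)`` obstacles.

    Start and goal are placed at opposite corners; obstacle layouts are
    redrawn (bounded retries) until a start-goal path exists.
    """
    if not 0.0 <= obstacle_density < 1.0:
        raise ConfigError(f"obstacle_density must lie in [0, 1), got {obstacle_density}")
    start = (0, 0)
    goal = (height - 1, width - 1)
    if start == goal:
        raise ConfigError("grid must contain at least two cells")
    cells = [
        (r, c)
        for r in range(height)
        for c in range(width)
        if (r, c) not in (start, goal)
    ]
    n_blocked = min(round(obstacle_density * width * height), len(cells))
    rng = random.Random(seed)
    for _ in range(max_retries):
        blocked = frozenset(rng.sample(cells, n_blocked))
        gmap = GridMap(width, height, blocked, start, goal, connectivity)
        if grid_connected(gmap):
            return gmap
    raise GenerationError(
        f"no connected layout found in {max_retries} retries "
        f"(density {obstacle_density})"
    )
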