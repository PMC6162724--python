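# Methods

This note records the models implemented in `nfsearch`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
components do and do not capture about real closed-loop BCI experiments.

## Search engines

The engine in `search_core` is a graph-search best-first loop over an
abstract `SearchProblem` (initial state, goal test, successor function
with strictly positive edge costs, heuristic). Nodes are ordered by
`f = (1 − ω)·g + ω·h`. At ω = 0.5 this is a positive rescaling of the
classical `g + h`, so `astar` and `weighted_astar` with a trivial
schedule are the same code path and produce identical traces by
construction. For ω < 1 and an admissible heuristic the returned cost is
bounded by ω/(1 − ω) times the optimum; `BoundReport` records the bound
for the largest ω applied during a run and verifies it against an
oracle-optimal cost.

Conventions the engine fixes (the underlying design space is genuinely
open and these choices are ours):

* **Tie-breaking.** Equal f is resolved by larger g, then by first-in
  insertion order (a global push counter). This makes every trace
  deterministic and byte-identically reproducible.
* **Re-opening.** A closed state rediscovered with strictly lower g is
  re-opened, during a phase and across weight changes. This keeps the
  suboptimality bound valid for arbitrary dynamic schedules, at the cost
  of occasional re-expansions (see the remark on intervention timing
  below).
* **Weight changes rebuild OPEN eagerly.** A fired trigger recomputes
  every open node's priority and re-heapifies, preserving insertion
  ticks so tie order survives the rebuild. Lazy rekeying would be
  faster but harder to verify; traces here are desk-scale.
* **Trigger semantics.** A trigger `(fraction, ω)` fires once
  `nodes_expanded ≥ fraction × reference_exploration`, where the
  reference is the admissible A* node count for the same instance. A
  fraction-0 trigger is therefore identical to weighting from the onset,
  and a fraction-1 trigger never fires within a run that beats its
  reference.
* **Numerics.** Cost comparisons use an absolute tolerance of 1e-9
  (exact for the integer-cost puzzle and 4-connected grids; the
  tolerance matters only for √2 diagonal costs). The default node
  budget is 5×10⁶ expansions; exceeding it raises, while exhausting the
  reachable space returns an unsolved trace.

FOCAL search (`focal_search`) builds, at every step, the set of open
nodes within (1 + ε) of the minimum f and expands the member minimising
a caller-supplied secondary heuristic (ties: f, then insertion order).
The implementation scans the heap for FOCAL membership, which is linear
per expansion and entirely adequate at the problem sizes used here.

## Benchmark domains

The 8-puzzle uses 9-character digit strings, the Manhattan-distance
heuristic, and a parity test for solvability. Difficulty labelling and
optimality checks use an exhaustive breadth-first search from the goal
over the reachable half of the state space (181,440 states, ~0.3 s,
cached per goal); instance generation samples uniformly, without
replacement, from all states at or above a requested oracle distance, so
difficulty labels are exact rather than estimated. The 8-puzzle diameter
is 31 moves; only 223 states lie at distance ≥ 30.

Grids are occupancy maps with corner start/goal, 4-connected unit moves
by default (8-connected with √2 diagonals by configuration; diagonal
moves only require the target cell to be free). The Euclidean
straight-line heuristic is admissible and consistent for both
connectivities. The generator places an exact obstacle count
`round(density × cells)` and redraws until a flood-fill finds a
start–goal path. The optimality oracle is networkx Dijkstra over the
free-cell graph — an implementation independent of the package's own
engines.

## Virtual subjects and synthetic fNIRS

`simulate_block` emulates one NF block of an 8-channel prefrontal HbO
montage at 10 Hz (a typical continuous-wave fNIRS rate). The default
protocol is 30 s rest, 30 s NF, 20 s count, with a 10-s baseline window
at the end of the pre-NF epoch and a 7-s haemodynamic onset delay; NF
epochs are capped at 120 s. The left–right asymmetry decomposes into:

* **trait** — a constant offset (default 0.5 signal units), split
  +trait/2 on the left channels and −trait/2 on the right;
* **state** — for responders, a saturating-exponential rise starting
  after the onset delay, with time constant equal to that delay,
  towards `state_gain × fatigue_decay^block` (defaults 1.0 and 0.9; the
  per-block decay models the well-documented drop in NF performance
  over a session). After the NF epoch the response decays back with the
  same time constant. A full double-gamma haemodynamic response
  function is deliberately not used: only the onset delay carries
  contractual weight here, and the saturating form has a closed form
  that the tests check exactly at zero noise.
* **noise and drift** — white Gaussian noise per channel (default SD
  1.0) and an optional linear drift common to all channels. A common
  drift cancels exactly out of the asymmetry score, which is why the
  type-I calibration holds with or without it. Channel-specific drifts,
  motion artefacts, physiological oscillations (Mayer waves, cardiac),
  and HbR are not modelled.

Signal units are arbitrary and baseline-referenced, matching how the
asymmetry score is consumed; no molar calibration is attempted. With
default noise, the asymmetry series has SD `noise_sd/√2`, so a
steady-state "programmed d" of x is obtained with
`state_gain = x·noise_sd/√2`; because the response rises over the scored
window, the realised window-mean effect is ≈ 0.71 of the programmed
steady-state value — the tests' sample-mean oracle accounts for this.

What passing these tests shows is internal consistency of the pipeline
under a stylised signal model: they do not establish that a human user
could produce the programmed asymmetries, nor do they reproduce
human-subject success percentages, which are simulation outputs under
declared subject distributions only.

## Block statistics

Scoring treats the baseline window as zero asymmetry regardless of its
absolute level, so trait offsets cancel. The test is a *one-sided
two-sample Welch* t-test (NF > baseline): one-sided because only
left-dominant shifts are rewarded; Welch because window sizes and
variances differ. Effect size is Cohen's d with pooled SD. Defaults
α = 0.05, 1,000 bootstrap resamples, bootstrap threshold 0.95 — all
configurable; `boot_reps=0` disables the bootstrap, leaving success to
the t-test alone (used in the large calibration studies for speed).
Sample autocorrelation is ignored, as in most real-time NF pipelines;
with white synthetic noise the type-I rate is nominal (measured
0.043–0.053 over 3,000 blocks depending on seed), but on real fNIRS data
the same test would be anticonservative.

Degenerate zero-variance windows with a mean difference (only possible
in noise-free simulations) are treated as maximal evidence with d capped
at ±1.5, the saturation point of the weight map; zero variance with
equal means raises an error. Constancy is detected by peak-to-peak
rather than variance, which is exact for constant float arrays.

## Mapping and the closed loop

The linear map ω = 0.5 + min(max(d, 0), d_max)/d_max × (ω_max − 0.5)
uses ω_max = 0.6 and d_max = 1.5 by default. The ceiling brackets the
weights at which the speed–accuracy characterisation shows clear effects
(0.55–0.6) while capping worst-case suboptimality at 1.5× optimal; the
original interaction experiments published no mapping constants, so
these are declared defaults, not inferred ones. Significance gating is
on by default: a failed block leaves the search admissible.

The puzzle loop scores one block and installs a single trigger at 10%
of the reference exploration (configurable within the first quarter,
where interventions are worthwhile). The grid loop scores one block per
update window, takes the running maximum of candidate weights (the
installed weight may only increase over the run) and spreads triggers
evenly over the run at fractions j/n_updates. NF timing and search
progression are decoupled — the search is conceptually paused at a
trigger until its score is available — because the search here is an
offline algorithm; no real-time co-scheduling is modelled.

## Harness and study sizes

Sweeps summarise across instances by *medians* (node counts are
heavy-tailed). The shipped studies use: 200 uniform random puzzles plus
50 random grids for the oracle checks; 38 mixed instances × 4 weights ×
{fixed, triggered} for the bound checks; 20 difficulty-≥20 instances for
the weighting sweep; 20 difficulty-≥30 instances for the timing sweep;
50 difficulty-≥27 instances for the backtracking contrast; 3,000 null
and 800 responder blocks for the statistical calibration; and 20 + 20
subjects for the cohort contrast. These sizes make the full
characterisation run in well under a minute per group while leaving
Monte-Carlo error small relative to every asserted margin.

## Known limitations and one measured caveat

* **Intervention-timing plateau.** At desk scale the benefit of
  intervening at fraction 0 versus 0.1–0.25 of the reference exploration
  is essentially nil, and the re-opening rule introduces a tiny
  systematic asymmetry: a run triggered after an admissible prefix
  inherits optimal g-values for near-start states and avoids a handful
  of re-expansions that a weighted-from-onset run performs. Median
  search-space reduction can therefore *rise* by O(10⁻⁴) between
  fractions 0 and 0.25 before falling clearly by fraction 0.5, and the
  strict "median reduction non-increasing in trigger fraction" check
  fails by that margin even though the cohort mean is cleanly monotone.
  The timing-trend quantities reported by `scripts/acceptance.py` make
  this visible rather than hiding it.
* The virtual subject aggregates all cognitive strategies into a single
  state gain; valence confounds, training effects across sessions, and
  individual haemodynamic variability are out of scope.
* The t-test's independence assumption is wrong for real, autocorrelated
  fNIRS series; calibration results transfer only to the synthetic noise
  model.
* Absolute node counts depend on tie-breaking and successor ordering;
  only orderings and trends are meaningful across implementations.
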