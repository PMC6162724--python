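# nfsearch

Closed-loop neurofeedback control of weighted heuristic search.

`nfsearch` is a testable implementation of a brain–computer-interface
paradigm in which a *motivational* brain signal steers the behaviour of a
running AI search. The user's prefrontal-cortex (PFC) asymmetry — the
difference between left- and right-hemisphere oxygenated-haemoglobin (HbO)
activity measured by fNIRS, with left dominance associated with approach
motivation — is raised volitionally under a neurofeedback (NF) block
protocol. The resulting block statistics are mapped onto the weighting
coefficient of a weighted-A\* engine, trading solution optimality for
computation speed under an explicit suboptimality bound. Since no fNIRS
hardware is involved, the human is replaced by a parameterised *virtual
subject* model, making the whole loop simulatable, seedable and testable.

The package is aimed at researchers in human-in-the-loop AI and passive/
active BCI who want a reproducible benchmark of the closed loop itself:
how signal quality, responder status, fatigue and intervention timing
propagate into search-space reduction and solution cost.

## The model

**Search side.** A best-first engine orders nodes by the weighted
evaluation function

    f(n) = (1 − ω)·g(n) + ω·h(n),      ω ∈ [0.5, 1)

where `g` is the accumulated path cost and `h` an admissible heuristic.
ω = 0.5 is classical A\* (optimal); ω > 0.5 biases towards the heuristic
and is *ε-admissible*: the returned cost is at most ω/(1 − ω) times the
optimum. The weight may change mid-run through a schedule of triggers
expressed as fractions of a reference exploration size; every OPEN-list
priority is rebuilt at a weight change. A FOCAL (A\*ε) variant and two
benchmark domains — the 8-puzzle (Manhattan-distance heuristic, exhaustive
181,440-state BFS oracle) and occupancy-grid path planning (Euclidean
heuristic, Dijkstra oracle) — are included.

**Brain side.** An 8-channel synthetic HbO montage (4 left, 4 right)
carries a trait asymmetry (stable offset), a state response during the NF
epoch (saturating exponential after a 7-s haemodynamic onset delay), white
channel noise, and per-block fatigue. The per-sample asymmetry score is
`mean(left 4) − mean(right 4)`. Each block is scored against the last
10 s of its pre-NF epoch ("zero asymmetry" baseline) with a one-sided
Welch t-test, Cohen's *d*, and a bootstrap confirmation; a block succeeds
when the test rejects and the bootstrap fraction clears its threshold, and
a session succeeds when at least half of its blocks do.

**Coupling.** Effect size maps linearly onto the weight,
`ω = 0.5 + min(d, d_max)/d_max · (ω_max − 0.5)` (defaults ω_max = 0.6,
d_max = 1.5), gated on block significance. The 8-puzzle loop installs a
single trigger within the first quarter of the reference exploration; the
grid loop applies repeated, monotonically non-decreasing weight updates as
the search progresses.

## Worked example

Steer a hard 8-puzzle search with one simulated NF block
(`example.yaml` holds a responder subject with unit channel noise and the
default 30 s rest / 30 s NF / 20 s count protocol):

```yaml
# example.yaml
subject: {trait_asymmetry: 0.5, state_gain: 1.0, noise_sd: 1.0, seed: 0}
domain:  {difficulty: 26}
```

```bash
nfsearch closed-loop --domain puzzle --config example.yaml --seed 3 --out loop_demo
```

prints

```
omega_applied=0.5649 reduction=0.481 cost=27.0
```

and writes `loop_demo/manifest.json` with the full accounting: the block
reached effect size d = 0.97 (one-sided p ≈ 8e-15), which the linear map
turned into ω = 0.565; the weighted run expanded 1,185 nodes against a
reference exploration of 2,282 (a 48% search-space reduction) and still
returned the optimal 27-move solution, comfortably inside the
ω/(1 − ω) = 1.30 cost bound. A non-responder subject leaves ω at 0.5 and
reproduces the reference search exactly.

The same loop is available programmatically via
`nfsearch.run_closed_loop_puzzle` / `run_closed_loop_grid`, and the
characterisation studies (weighting sweeps, intervention-timing sweeps,
backtracking trajectories, cohort tables) via `nfsearch.experiment_harness`.

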