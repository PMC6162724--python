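"""Asymmetry scoring and per-block statistics for NF streams.

The signal-analysis chain mirrors real-time NF practice:

1. the per-sample asymmetry score is the mean of the four left HbO
   channels minus the mean of the four right channels;
2. the baseline is the asymmetry over the last ``baseline_window``
   seconds of the epoch preceding the NF epoch, and is treated as "zero
   asymmetry" regardless of its absolute value;
3. the scored NF window is the NF epoch minus the first
   ``haemodynamic_delay`` seconds (haemodynamic onset);
4. a one-sided two-sample Welch t-test asks whether the NF-window
   asymmetry exceeds the baseline (only left-dominant shifts are
   rewarded), with Cohen's d (pooled SD) as the effect size;
5. a bootstrap over both windows gives the fraction of resamples in
   which the NF mean exceeds the baseline mean, used as a post-hoc
   confirmation.

A block is *successful* when the t-test rejects at ``alpha`` and the
bootstrap fraction reaches its threshold; a session is successful when
at least half of its blocks are.  Sample autocorrelation is ignored in
the t-test, a deliberate simplification shared with most real-time NF
pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DomainError,
    FormatError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .neuro_signal import (
    BlockProtocol,
    LEFT_CHANNELS,
    N_CHANNELS,
    NirsStream,
    RIGHT_CHANNELS,
)

#: Effect-size cap used for degenerate zero-variance windows; matches the
#: saturation point of the default weight mapping.
DEFAULT_D_CAP = 1.5


def asymmetry(stream: NirsStream) -> np.ndarray:
    """Per-sample asymmetry: mean(ch0..ch3) - mean(ch4..ch7)."""
    if stream.channels.shape[1] != N_CHANNELS:
        raise FormatError(
            f"asymmetry requires exactly {N_CHANNELS} channels, "
            f"got {stream.channels.shape[1]}"
        )
    return (
        stream.channels[:, LEFT_CHANNELS].mean(axis=1)
        - stream.channels[:, RIGHT_CHANNELS].mean(axis=1)
    )


@dataclass
class AsymmetryScore:
    """Asymmetry series split into the baseline and scored NF windows."""

    series: np.ndarray
    baseline_mean: float
    baseline_sd: float
    baseline_samples: np.ndarray
    nf_samples: np.ndarray


def extract_windows(stream: NirsStream, protocol: BlockProtocol) -> AsymmetryScore:
    """Split a stream's asymmetry series into baseline and NF windows.

    The baseline window is the last ``baseline_window`` seconds before
    the NF epoch; the NF window excludes the haemodynamic onset delay.
    """
    series = asymmetry(stream)
    t = stream.times
    b0, b1 = protocol.baseline_interval
    n0, n1 = protocol.scored_nf_interval
    base = series[(t >= b0 - 1e-9) & (t < b1 - 1e-9)]
    nf = series[(t >= n0 - 1e-9) & (t < n1 - 1e-9)]
    return AsymmetryScore(
        series=series,
        baseline_mean=float(base.mean()) if len(base) else math.nan,
        baseline_sd=float(base.std(ddof=1)) if len(base) > 1 else math.nan,
        baseline_samples=base,
        nf_samples=nf,
    )


@dataclass(frozen=True)
class BlockStats:
    """Statistics of one NF block.

    ``success`` requires the one-sided p-value below alpha and, when the
    bootstrap is enabled, a bootstrap fraction at or above its threshold.
    """

    t_statistic: float
    p_value: float
    effect_size: float
    bootstrap_fraction: Optional[float]
    success: bool
    n_baseline: int
    n_nf: int

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "bootstrap_fraction": self.bootstrap_fraction,
            "success": self.success,
            "n_baseline": self.n_baseline,
            "n_nf": self.n_nf,
        }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference (x minus y) with pooled SD."""
    nx, ny = len(x), len(y)
    pooled_var = (
        (nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)
    ) / (nx + ny - 2)
    sd = math.sqrt(pooled_var)
    if sd == 0.0:
        raise UndefinedStatisticError("pooled SD is zero")
    return float((x.mean() - y.mean()) / sd)


def score_block(
    stream: NirsStream,
    protocol: BlockProtocol,
    alpha: float = 0.05,
    boot_reps: int = 1000,
    boot_threshold: float = 0.95,
    seed: int = 0,
    d_cap: float = DEFAULT_D_CAP,
) -> BlockStats:
    """Score one NF block against its own baseline.

    Welch's one-sided two-sample t-test (NF > baseline), Cohen's d with
    pooled SD, and a ``boot_reps``-resample bootstrap of both windows.
    Set ``boot_reps=0`` to disable the bootstrap (``bootstrap_fraction``
    is then None and success rests on the t-test alone).

    A zero-variance pair of windows with a mean difference is treated as
    maximal evidence: d is capped at ``+/- d_cap`` and p set to 0 or 1
    by the sign of the difference.

    Raises
    ------
    InsufficientDataError : fewer than 3 samples in either window.
    UndefinedStatisticError : both windows constant with equal means.
    """
    win = extract_windows(stream, protocol)
    nf, base = win.nf_samples, win.baseline_samples
    if len(nf) < 3 or len(base) < 3:
        raise InsufficientDataError(
            f"need >= 3 samples per window, got nf={len(nf)}, baseline={len(base)}"
        )

    # peak-to-peak is exact for constant arrays, unlike var (summation dust)
    degenerate = np.ptp(nf) == 0.0 and np.ptp(base) == 0.0
    if degenerate:
        diff = float(nf[0] - base[0])  # exact: both windows are constant
        if diff == 0.0:
            raise UndefinedStatisticError(
                "zero variance in both windows with equal means"
            )
        positive = diff > 0
        t_stat = math.inf if positive else -math.inf
        p_value = 0.0 if positive else 1.0
        d = d_cap if positive else -d_cap
        boot_frac: Optional[float] = None
        if boot_reps > 0:
            boot_frac = 1.0 if positive else 0.0
    else:
        t_stat, p_value = sps.ttest_ind(
            nf, base, equal_var=False, alternative="greater"
        )
        t_stat, p_value = float(t_stat), float(p_value)
        d = cohens_d(nf, base)
        boot_frac = None
        if boot_reps > 0:
            rng = np.random.default_rng(np.random.SeedSequence((seed, 4242)))
            nf_idx = rng.integers(0, len(nf), size=(boot_reps, len(nf)))
            base_idx = rng.integers(0, len(base), size=(boot_reps, len(base)))
            nf_means = nf[nf_idx].mean(axis=1)
            base_means = base[base_idx].mean(axis=1)
            boot_frac = float(np.mean(nf_means > base_means))

    success = p_value < alpha and (boot_frac is None or boot_frac >= boot_threshold)
    return BlockStats(
        t_statistic=t_stat,
        p_value=p_value,
        effect_size=d,
        bootstrap_fraction=boot_frac,
        success=bool(success),
        n_baseline=len(base),
        n_nf=len(nf),
    )


def session_success(blocks: Sequence[BlockStats]) -> bool:
    """A session succeeds when at least half of its blocks do."""
    if len(blocks) == 0:
        raise DomainError("session_success requires at least one block")
    n_ok = sum(1 for b in blocks if b.success)
    return n_ok >= len(blocks) / 2.0
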