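"""Synthetic prefrontal fNIRS streams from parameterised virtual subjects.

The generator emulates an 8-channel oxygenated-haemoglobin (HbO) montage
over the prefrontal cortex — channels 0-3 on the left hemisphere, 4-7 on
the right — recorded under a block-design neurofeedback (NF) protocol.
It stands in for the human participant in closed-loop experiments.

A virtual subject combines:

* a *trait* asymmetry: a stable resting left-minus-right HbO offset,
  split evenly across hemispheres (+trait/2 on the left, -trait/2 on the
  right);
* a *state* gain: the additional left-dominant asymmetry the subject can
  raise volitionally during the NF epoch.  The response follows a
  saturating exponential that starts after the haemodynamic onset delay
  and uses that same delay as its time constant, reaching
  ``state_gain * fatigue_decay ** block_index`` asymptotically;
* *fatigue*: a multiplicative per-block decay of the state gain,
  modelling the drop in BCI performance towards later blocks;
* additive white channel noise and an optional slow linear drift common
  to all channels (a common drift cancels out of the left-right
  asymmetry, as in baseline-referenced practice).

Signal units are arbitrary and baseline-relative; no molar concentration
calibration is attempted.  Non-responders have an effective state gain
of zero regardless of the programmed value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

#: Channel index ranges of the montage.
LEFT_CHANNELS = slice(0, 4)
RIGHT_CHANNELS = slice(4, 8)
N_CHANNELS = 8

EPOCH_LABELS = ("rest", "count", "nf", "washout")


@dataclass(frozen=True)
class VirtualSubject:
    """Parameters of one simulated NF participant (signal units arbitrary)."""

    trait_asymmetry: float = 0.5
    state_gain: float = 1.0
    responder: bool = True
    fatigue_decay: float = 0.9
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.fatigue_decay <= 1.0:
            raise ConfigError(
                f"fatigue_decay must lie in (0, 1], got {self.fatigue_decay}"
            )

    def effective_gain(self, block_index: int) -> float:
        """State gain actually expressed in block ``block_index`` (0-based)."""
        if not self.responder:
            return 0.0
        return self.state_gain * self.fatigue_decay**block_index


@dataclass(frozen=True)
class BlockProtocol:
    """One NF block: an ordered list of epochs plus timing constants.

    ``baseline_window`` is the final stretch (seconds) of the epoch
    immediately preceding the NF epoch, used as the asymmetry baseline;
    ``haemodynamic_delay`` is the onset delay of the haemodynamic
    response, excluded from the scored NF window.
    """

    epochs: tuple[tuple[str, float], ...] = (("rest", 30.0), ("nf", 30.0), ("count", 20.0))
    baseline_window: float = 10.0
    haemodynamic_delay: float = 7.0
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "epochs", tuple((str(lbl), float(d)) for lbl, d in self.epochs)
        )
        labels = [lbl for lbl, _ in self.epochs]
        for lbl, dur in self.epochs:
            if lbl not in EPOCH_LABELS:
                raise ConfigError(f"unknown epoch label {lbl!r}")
            if dur <= 0:
                raise ConfigError(f"epoch duration must be positive, got {dur}")
        if labels.count("nf") != 1:
            raise ConfigError("protocol must contain exactly one nf epoch")
        nf_idx = labels.index("nf")
        if nf_idx == 0:
            raise ConfigError("nf epoch needs a preceding epoch for the baseline")
        if self.epochs[nf_idx][1] > 120.0:
            raise ConfigError("nf epoch may not exceed 120 s")
        if self.baseline_window > self.epochs[nf_idx - 1][1]:
            raise ConfigError("baseline_window exceeds the pre-nf epoch duration")
        if self.haemodynamic_delay < 0 or self.haemodynamic_delay >= self.epochs[nf_idx][1]:
            raise ConfigError("haemodynamic_delay must lie within the nf epoch")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")

    # -- derived timing ---------------------------------------------------

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.epochs)

    @property
    def nf_interval(self) -> tuple[float, float]:
        """(start, end) of the nf epoch in seconds from block start."""
        t = 0.0
        for lbl, d in self.epochs:
            if lbl == "nf":
                return (t, t + d)
            t += d
        raise AssertionError("validated protocol always has an nf epoch")

    @property
    def baseline_interval(self) -> tuple[float, float]:
        """(start, end) of the baseline window (last ``baseline_window``
        seconds of the epoch preceding nf)."""
        nf_start, _ = self.nf_interval
        return (nf_start - self.baseline_window, nf_start)

    @property
    def scored_nf_interval(self) -> tuple[float, float]:
        """NF window used for scoring: the nf epoch minus the onset delay."""
        nf_start, nf_end = self.nf_interval
        return (nf_start + self.haemodynamic_delay, nf_end)

    def to_dict(self) -> dict:
        return {
            "epochs": [list(e) for e in self.epochs],
            "baseline_window": self.baseline_window,
            "haemodynamic_delay": self.haemodynamic_delay,
            "sampling_rate": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BlockProtocol":
        return cls(
            epochs=tuple(tuple(e) for e in data["epochs"]),
            baseline_window=data.get("baseline_window", 10.0),
            haemodynamic_delay=data.get("haemodynamic_delay", 7.0),
            sampling_rate=data.get("sampling_rate", 10.0),
        )


@dataclass
class NirsStream:
    """Uniformly sampled 8-channel HbO series with per-sample epoch labels."""

    times: np.ndarray
    channels: np.ndarray  # shape (n_samples, 8)
    annotations: np.ndarray  # epoch label per sample

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        self.annotations = np.asarray(self.annotations, dtype=object)
        if self.channels.ndim != 2 or self.channels.shape[1] != N_CHANNELS:
            raise FormatError(
                f"channels must have shape (n, {N_CHANNELS}), got {self.channels.shape}"
            )
        if not (len(self.times) == len(self.channels) == len(self.annotations)):
            raise FormatError("times, channels and annotations must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.channels, columns=[f"ch{i}" for i in range(N_CHANNELS)]
        )
        df.insert(0, "time_s", self.times)
        df["epoch_label"] = self.annotations
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NirsStream":
        df = pd.read_csv(path)
        cols = [f"ch{i}" for i in range(N_CHANNELS)]
        missing = [c for c in ["time_s", "epoch_label", *cols] if c not in df.columns]
        if missing:
            raise FormatError(f"stream CSV missing columns: {missing}")
        return cls(
            times=df["time_s"].to_numpy(),
            channels=df[cols].to_numpy(),
            annotations=df["epoch_label"].to_numpy(),
        )


def nf_response(
    times: np.ndarray, protocol: BlockProtocol, gain: float
) -> np.ndarray:
    """Closed-form left-minus-right asymmetry response to the NF epoch.

    Zero before ``nf_start + delay``; rises as a saturating exponential
    with time constant equal to the haemodynamic delay towards ``gain``
    during the nf epoch; decays back with the same time constant after
    the epoch ends.  With delay = 0 the response is an instant step.
    """
    t = np.asarray(times, dtype=float)
    nf_start, nf_end = protocol.nf_interval
    tau = protocol.haemodynamic_delay
    onset = nf_start + tau
    resp = np.zeros_like(t)
    if gain == 0.0:
        return resp
    rising = t >= onset
    if tau > 0:
        resp[rising] = gain * (1.0 - np.exp(-(t[rising] - onset) / tau))
        falling = t >= nf_end
        level_at_end = gain * (1.0 - np.exp(-max(nf_end - onset, 0.0) / tau))
        resp[falling] = level_at_end * np.exp(-(t[falling] - nf_end) / tau)
    else:
        resp[rising & (t < nf_end)] = gain
    return resp


def _block_rng(subject: VirtualSubject, block_index: int, seed: Optional[int]) -> np.random.Generator:
    base = subject.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence((base, block_index)))


def simulate_block(
    subject: VirtualSubject,
    protocol: BlockProtocol,
    block_index: int = 0,
    seed: Optional[int] = None,
) -> NirsStream:
    """Simulate one NF block for ``subject``.

    Deterministic given the subject's seed (or the ``seed`` override) and
    ``block_index``.  Fatigue is applied as
    ``state_gain * fatigue_decay ** block_index``.
    """
    n = int(round(protocol.duration * protocol.sampling_rate))
    times = np.arange(n) / protocol.sampling_rate

    channels = np.zeros((n, N_CHANNELS))
    half_trait = subject.trait_asymmetry / 2.0
    channels[:, LEFT_CHANNELS] += half_trait
    channels[:, RIGHT_CHANNELS] -= half_trait

    resp = nf_response(times, protocol, subject.effective_gain(block_index))
    channels[:, LEFT_CHANNELS] += resp[:, None] / 2.0
    channels[:, RIGHT_CHANNELS] -= resp[:, None] / 2.0

    if subject.drift_slope != 0.0:
        channels += (subject.drift_slope * times)[:, None]

    if subject.noise_sd > 0.0:
        rng = _block_rng(subject, block_index, seed)
        channels += rng.normal(0.0, subject.noise_sd, size=channels.shape)

    annotations = np.empty(n, dtype=object)
    t0 = 0.0
    for lbl, dur in protocol.epochs:
        annotations[(times >= t0) & (times < t0 + dur)] = lbl
        t0 += dur
    # float edge guard: any unlabelled trailing sample belongs to the last epoch
    annotations[annotations == None] = protocol.epochs[-1][0]  # noqa: E711

    return NirsStream(times=times, channels=channels, annotations=annotations)


def simulate_session(
    subject: VirtualSubject,
    protocol: BlockProtocol,
    n_blocks: int,
    seed: Optional[int] = None,
) -> list[NirsStream]:
    """Simulate ``n_blocks`` consecutive blocks: shared subject parameters,
    independent noise per block, fatigue applied by block index."""
    if n_blocks < 1:
        raise ConfigError("n_blocks must be >= 1")
    return [
        simulate_block(subject, protocol, block_index=k, seed=seed)
        for k in range(n_blocks)
    ]
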