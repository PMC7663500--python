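"""Uniform and context-adaptive duty-cycle sampling.

The context-adaptive strategy follows the n-shots measure paradigm:
once per decision period the sensor wakes, takes ``n`` samples per
channel, and summarises them into a context measure θt (per-channel
mean rectified amplitude, maximum across channels — EMG is zero-mean,
so the raw mean would vanish).  A linear map converts θt into a
candidate duty rate D* anchored at (θl → Dl) and (θh → Dh), and a
two-state attentive/inattentive response model turns candidates into
the applied duty rate: while attentive the duty never decreases, and
the model only falls back to the inattentive state once the attention
time τ has elapsed with the candidate below the duty threshold DTH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cost_models import OperationCount
from .synthetic_emg import AnnotatedSignal

__all__ = [
    "SamplerParams",
    "SamplerState",
    "SampledStream",
    "context_measure",
    "map_duty",
    "step_response",
    "run_sampler",
    "sampler_op_count",
]


@dataclass(frozen=True)
class SamplerParams:
    """Context-adaptive sampler knobs (defaults from the study's operating
    point: Dh=1, Dl=0.1, DTH=0.6, n=4, τ=3 s, θl=10 mV, θh=180 mV)."""

    d_low: float = 0.1
    d_high: float = 1.0
    d_threshold: float = 0.6
    theta_low: float = 10.0    # mV
    theta_high: float = 180.0  # mV
    n_shots: int = 4
    tau: float = 3.0           # s, attention time
    period: float = 1.0        # s between n-shot measures

    def __post_init__(self) -> None:
        if not 0.0 < self.d_low <= self.d_high <= 1.0:
            raise ValueError("need 0 < Dl <= Dh <= 1")
        if not self.d_low <= self.d_threshold <= self.d_high:
            raise ValueError("need Dl <= DTH <= Dh")
        if not self.theta_low < self.theta_high:
            raise ValueError("need θl < θh")
        if self.n_shots < 1:
            raise ValueError("need n >= 1")
        if self.tau <= 0 or self.period <= 0:
            raise ValueError("τ and the period must be positive")


@dataclass(frozen=True)
class SamplerState:
    attentive: bool = False
    duty: float = 0.1
    attention_clock: float = 0.0  # seconds of τ remaining

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty must lie in [0, 1]")


@dataclass
class SampledStream:
    """Result of a sampler run over one stream."""

    kept_mask: np.ndarray          # per-sample booleans
    duty_trace: np.ndarray         # applied duty rate per decision period
    params: SamplerParams | None = None

    @property
    def reduction(self) -> float:
        """Fraction of samples not taken."""
        return float(1.0 - self.kept_mask.mean())

    def sampled_channels(self, channels: np.ndarray,
                         fill: str = "interp") -> np.ndarray:
        """Reconstruct the acquired stream on the uniform grid.

        ``interp`` (default) linearly interpolates between the kept
        samples — what a consumer of the duty-cycled stream actually
        sees; ``zero`` leaves the not-taken samples at zero.
        """
        x = np.atleast_2d(np.asarray(channels, dtype=float))
        if fill == "zero":
            return x * self.kept_mask
        if fill != "interp":
            raise ValueError(f"unknown fill mode {fill!r}")
        if self.kept_mask.all():
            return x
        idx = np.flatnonzero(self.kept_mask)
        grid = np.arange(x.shape[1])
        return np.vstack([np.interp(grid, idx, ch[idx]) for ch in x])


def context_measure(shot: np.ndarray) -> float:
    """Context measure θt from an n-shot block of shape (K, n).

    Per-channel mean rectified amplitude, then the maximum across
    channels; non-negative by construction.
    """
    block = np.atleast_2d(np.asarray(shot, dtype=float))
    if block.size == 0:
        raise ValueError("empty n-shot block")
    per_channel = np.abs(block).mean(axis=1)
    return float(per_channel.max())


def map_duty(theta_t: float, params: SamplerParams) -> float:
    """Linear context-to-duty map, clamped to [Dl, Dh]."""
    slope = (params.d_high - params.d_low) / (params.theta_high - params.theta_low)
    d_star = params.d_low + slope * (theta_t - params.theta_low)
    return float(min(max(d_star, params.d_low), params.d_high))


def step_response(state: SamplerState, d_star: float,
                  params: SamplerParams) -> SamplerState:
    """One decision step of the attentive/inattentive response model.

    Candidate above DTH: enter/stay attentive, apply max(Dt, D*) and
    rewind the attention clock to τ.  Candidate at or below DTH while
    attentive: hold the duty until τ has elapsed, then fall back to the
    inattentive state and apply the candidate.  Inattentive: apply the
    candidate directly.
    """
    if d_star > params.d_threshold:
        return SamplerState(attentive=True,
                            duty=max(state.duty, d_star),
                            attention_clock=params.tau)
    if state.attentive:
        clock = state.attention_clock - params.period
        if clock > 0:
            return SamplerState(attentive=True, duty=state.duty,
                                attention_clock=clock)
        return SamplerState(attentive=False, duty=d_star, attention_clock=0.0)
    return SamplerState(attentive=False, duty=d_star, attention_clock=0.0)


def _kept_indices(duty: float, samples_per_period: int, n_shots: int) -> np.ndarray:
    """Evenly spaced kept-sample indices within one period.

    The n-shot samples at the period start are measured and therefore
    counted as kept.
    """
    k = math.ceil(duty * samples_per_period)
    k = min(max(k, 0), samples_per_period)
    idx = np.unique(np.round(np.linspace(0, samples_per_period - 1, k)).astype(int)) \
        if k else np.empty(0, dtype=int)
    return np.union1d(idx, np.arange(min(n_shots, samples_per_period)))


def run_sampler(sig: AnnotatedSignal, params: SamplerParams,
                mode: str = "adaptive") -> SampledStream:
    """Run the sampler over a stream; deterministic.

    ``uniform`` keeps every sample at duty 1.  ``adaptive`` takes one
    n-shot measure per decision period, updates the response model, and
    keeps ceil(Dt+1 · samples_per_period) evenly spaced samples of the
    period.  A trailing partial period is kept in full.
    """
    n = sig.n_samples
    spp = round(params.period * sig.sample_rate)
    if mode == "uniform":
        n_periods = max(n // spp, 1)
        return SampledStream(kept_mask=np.ones(n, dtype=bool),
                             duty_trace=np.ones(n_periods), params=params)
    if mode != "adaptive":
        raise ValueError(f"unknown sampling mode {mode!r}")
    if spp < params.n_shots:
        raise ValueError("decision period shorter than the n-shot block")

    n_periods = n // spp
    kept = np.zeros(n, dtype=bool)
    duty_trace = np.empty(n_periods)
    state = SamplerState(duty=params.d_low)
    index_cache: dict[float, np.ndarray] = {}  # duty values recur heavily
    for p in range(n_periods):
        lo = p * spp
        shot = sig.channels[:, lo:lo + params.n_shots]
        theta = context_measure(shot)
        d_star = map_duty(theta, params)
        state = step_response(state, d_star, params)
        duty_trace[p] = state.duty
        key = round(state.duty, 9)
        idx = index_cache.get(key)
        if idx is None:
            idx = _kept_indices(state.duty, spp, params.n_shots)
            index_cache[key] = idx
        kept[lo + idx] = True
    kept[n_periods * spp:] = True  # partial tail kept as-is
    return SampledStream(kept_mask=kept, duty_trace=duty_trace, params=params)


def sampler_op_count(params: SamplerParams, n_periods: int,
                     n_channels: int = 2) -> OperationCount:
    """Operation tally of the adaptive sampler over ``n_periods`` measures.

    Per n-shot measure: context measure (Add 2n·g, Div 2, Comp n−1,
    one float), response output (Add 4, Mult 1, Div 1, four floats),
    attention time (Comp 2, two floats).  Arithmetic scales with the
    period count; the memory cells are static state.
    """
    if n_periods < 0:
        raise ValueError("n_periods must be >= 0")
    n, g = params.n_shots, n_channels
    per_period = OperationCount(add=2 * n * g + 4, mult=1, div=3,
                                comp=(n - 1) + 2, float_cells=7,
                                label="adaptive_sampler")
    return per_period.times_ops(n_periods)
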