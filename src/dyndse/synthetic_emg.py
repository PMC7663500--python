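"""Synthetic day-long chewing-EMG streams with event annotations.

The study dataset — two-channel temporalis EMG from eyeglasses-mounted
electrodes, sampled uniformly at 256 Hz for a full day, with eating
events journalled at one-minute resolution — is not public.  This
module generates annotated surrogate streams with the same surface
statistics so the sampling, spotting and evaluation machinery can be
exercised end to end:

* a zero-mean Gaussian noise floor whose scale matches the lower
  context bound θl (≈10 mV),
* rhythmic chewing bursts inside eating events: band-limited (20–120
  Hz) noise, amplitude-modulated at the chew rate, on both channels,
* optional 50 Hz line interference (to exercise the notch filter),
* optional brief non-eating confounder bursts,
* annotations aligned to whole minutes; the actual burst activity may
  start/stop up to a configurable jitter inside the annotated span,
  emulating diet-journal label noise at event edges.

Streams are written as plain delimited text (one file for samples, one
for the event intervals).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "AnnotatedSignal",
    "GeneratorParams",
    "generate_participant",
    "round_events_to_minutes",
    "event_mask",
    "write_signal",
    "read_signal",
]

DEFAULT_SAMPLE_RATE = 256.0


def _validate_events(events: Sequence[tuple[float, float]], duration: float) -> None:
    prev_end = -np.inf
    for start, end in events:
        if not (0.0 <= start < end <= duration + 1e-9):
            raise ValueError(f"event ({start}, {end}) outside [0, {duration}]")
        if start < prev_end:
            raise ValueError("events must be sorted and non-overlapping")
        prev_end = end


@dataclass
class AnnotatedSignal:
    """Multichannel sampled stream plus ground-truth event intervals.

    ``channels`` has shape (K, n_samples) in mV; ``events`` is a sorted
    list of (start_s, end_s) intervals.
    """

    sample_rate: float
    channels: np.ndarray
    events: list[tuple[float, float]]
    participant_id: str = ""
    duration: float | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.duration is None:
            self.duration = self.channels.shape[1] / self.sample_rate
        expected = round(self.duration * self.sample_rate)
        if self.channels.shape[1] != expected:
            raise ValueError(
                f"channel length {self.channels.shape[1]} != "
                f"round(duration*rate) = {expected}")
        self.events = sorted((float(s), float(e)) for s, e in self.events)
        _validate_events(self.events, self.duration)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class GeneratorParams:
    """Generator knobs; defaults emulate one day-long study participant."""

    duration: float = 16 * 3600.0          # seconds worn (~getting up to bed)
    n_events: int = 6                      # meals + snacks per day
    event_duration_range: tuple[float, float] = (300.0, 1200.0)  # 5-20 min
    chew_rate: float = 1.6                 # Hz, chewing-cycle repetition
    burst_amplitude: float = 150.0         # mV, chewing-burst scale
    noise_floor: float = 10.0              # mV, matches the lower bound θl
    line_hum_amplitude: float = 0.0        # mV at 50 Hz
    edge_jitter: float = 20.0              # s, burst onset/offset inside the label
    n_confounders: int = 0                 # brief non-eating bursts
    confounder_duration: float = 3.0       # s
    n_channels: int = 2
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.event_duration_range
        if not 0 < lo <= hi:
            raise ValueError("event duration range must be positive and ordered")
        if self.noise_floor >= self.burst_amplitude:
            raise ValueError("noise floor must be below the burst amplitude")


def round_events_to_minutes(events: Sequence[tuple[float, float]],
                            duration: float) -> list[tuple[float, float]]:
    """Round event intervals outward to whole minutes and merge overlaps."""
    rounded = [(np.floor(s / 60.0) * 60.0, min(np.ceil(e / 60.0) * 60.0, duration))
               for s, e in events]
    rounded.sort()
    merged: list[tuple[float, float]] = []
    for s, e in rounded:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def event_mask(events: Sequence[tuple[float, float]], n_samples: int,
               sample_rate: float) -> np.ndarray:
    """Boolean per-sample mask of the event intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for s, e in events:
        i0 = int(round(s * sample_rate))
        i1 = min(int(round(e * sample_rate)), n_samples)
        mask[i0:i1] = True
    return mask


def _place_events(params: GeneratorParams, rng: np.random.Generator
                  ) -> list[tuple[float, float]]:
    """Draw non-overlapping minute-aligned event intervals."""
    total_minutes = int(params.duration // 60)
    lo, hi = params.event_duration_range
    starts: list[tuple[int, int]] = []  # (start_min, dur_min)
    for _ in range(params.n_events):
        placed = False
        for _attempt in range(200):
            dur_min = max(1, int(round(rng.uniform(lo, hi) / 60.0)))
            if dur_min >= total_minutes:
                continue
            start_min = int(rng.integers(0, total_minutes - dur_min))
            ok = all(start_min + dur_min + 1 <= s or start_min >= s + d + 1
                     for s, d in starts)
            if ok:
                starts.append((start_min, dur_min))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place the requested events without overlap")
    return sorted((60.0 * s, 60.0 * (s + d)) for s, d in starts)


def _chewing_burst(n: int, fs: float, chew_rate: float, amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated band-limited (20-120 Hz) noise burst."""
    carrier = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, 120.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, carrier)
    std = carrier.std()
    if std > 0:
        carrier /= std
    t = np.arange(n) / fs
    # half-wave chew envelope: one activity burst per chewing cycle
    envelope = np.clip(np.sin(2 * np.pi * chew_rate * t), 0.0, None)
    return amplitude * envelope * carrier


def generate_participant(params: GeneratorParams) -> AnnotatedSignal:
    """Generate one annotated participant stream (seeded, deterministic)."""
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = round(params.duration * fs)
    channels = rng.normal(0.0, params.noise_floor, size=(params.n_channels, n))

    events = _place_events(params, rng)
    for start, end in events:
        # actual muscle activity starts/stops inside the journalled span
        jit0 = rng.uniform(0.0, params.edge_jitter)
        jit1 = rng.uniform(0.0, params.edge_jitter)
        a0 = start + jit0
        a1 = max(end - jit1, a0 + 1.0)
        i0, i1 = int(round(a0 * fs)), min(int(round(a1 * fs)), n)
        for k in range(params.n_channels):
            gain = rng.uniform(0.8, 1.2)  # per-channel electrode gain spread
            channels[k, i0:i1] += _chewing_burst(
                i1 - i0, fs, params.chew_rate, gain * params.burst_amplitude, rng)

    busy = event_mask(events, n, fs)
    for _ in range(params.n_confounders):
        dur = int(round(params.confounder_duration * fs))
        for _attempt in range(100):
            i0 = int(rng.integers(0, max(n - dur, 1)))
            if not busy[i0:i0 + dur].any():
                for k in range(params.n_channels):
                    channels[k, i0:i0 + dur] += _chewing_burst(
                        dur, fs, params.chew_rate, params.burst_amplitude, rng)
                break

    if params.line_hum_amplitude > 0:
        t = np.arange(n) / fs
        channels += params.line_hum_amplitude * np.sin(2 * np.pi * 50.0 * t)

    annotations = round_events_to_minutes(events, params.duration)
    return AnnotatedSignal(sample_rate=fs, channels=channels,
                           events=annotations,
                           participant_id=f"synthetic-{params.seed}",
                           duration=params.duration)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------
# Signal file: UTF-8, '#'-prefixed metadata lines, then a tab-separated
# header "time_s\tch1_mV\t..." and one row per sample (decimal point,
# six decimals).  Events file: header "start_s\tend_s", one row per
# event.

def write_signal(sig: AnnotatedSignal, path) -> None:
    """Write the stream to ``<path>`` and its events to ``<path>.events``."""
    path = Path(path)
    n = sig.n_samples
    t = np.arange(n) / sig.sample_rate
    header = [f"# sample_rate_hz={sig.sample_rate:g}",
              f"# participant={sig.participant_id}",
              "time_s\t" + "\t".join(f"ch{k+1}_mV" for k in range(sig.n_channels))]
    data = np.column_stack([t, sig.channels.T])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter="\t")
    with open(path.with_suffix(path.suffix + ".events"), "w", encoding="utf-8") as fh:
        fh.write("start_s\tend_s\n")
        for s, e in sig.events:
            fh.write(f"{s:.3f}\t{e:.3f}\n")


def read_signal(path) -> AnnotatedSignal:
    """Read a stream previously written by :func:`write_signal`."""
    path = Path(path)
    sample_rate = DEFAULT_SAMPLE_RATE
    participant = ""
    body = io.StringIO()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key.strip() == "sample_rate_hz":
                    sample_rate = float(value)
                elif key.strip() == "participant":
                    participant = value
            elif line.startswith("time_s"):
                continue
            else:
                body.write(line)
    body.seek(0)
    data = np.loadtxt(body, delimiter="\t", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("signal file needs a time column and >=1 channel")
    channels = data[:, 1:].T

    events: list[tuple[float, float]] = []
    events_path = path.with_suffix(path.suffix + ".events")
    with open(events_path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or (i == 0 and line.startswith("start_s")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed events row: {line!r}")
            events.append((float(parts[0]), float(parts[1])))
    for (s0, e0), (s1, _) in zip(events, events[1:]):
        if s1 < e0:
            raise ValueError("events file contains overlapping or unsorted intervals")
    return AnnotatedSignal(sample_rate=sample_rate, channels=channels,
                           events=events, participant_id=participant)
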