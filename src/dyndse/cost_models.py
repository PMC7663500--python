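"""Analytical hardware cost models.

Maps per-function arithmetic-operation tallies onto concrete
microcontroller profiles to estimate execution time (ET), energy
consumption (EC, split into microcontroller / sensor / memory / radio
parts), memory demand (MD) and communication latency (CL).  The three
shipped microcontroller profiles (PSoC1 M8C, TI MSP430F1611, ARM
CortexM3), the EMG sensor front-end, the BLE radio and the Li-Ion
battery are read from ``profiles/hardware.yaml``, field-for-field from
the component datasheet values used in the study.

Unit conventions
----------------
Currents are mA (except the memory write current, μA), voltages V,
times enter in seconds (converted to hours internally for the energy
terms), energies are reported in mWh, memory in bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "OperationCount",
    "MicrocontrollerProfile",
    "SensorProfile",
    "RadioProfile",
    "BatteryProfile",
    "HardwareProfiles",
    "load_profiles",
    "cycles",
    "execution_time",
    "et_aggregate",
    "kernel_svm_counts",
    "rbf_kernel_counts",
    "mcu_energy",
    "sensor_energy",
    "memory_energy",
    "radio_energy",
    "total_energy",
    "EnergyBreakdown",
    "energy_requirement",
    "memory_demand",
    "ring_buffer_peak",
    "comm_latency",
]

OP_KINDS = ("add", "mult", "div", "root", "comp", "exp")

FLOAT_BYTES = 4  # all operations assumed float-typed; 4-byte IEEE cells


@dataclass
class OperationCount:
    """Tally of arithmetic operations and memory cells for one function.

    ``add`` counts additions and subtractions; ``comp`` comparisons;
    ``exp`` exponentials.  ``int_cells``/``float_cells`` are the number
    of integer/float variables the function keeps live (memory demand,
    not operation counts — they do not scale with repetitions).
    """

    add: int = 0
    mult: int = 0
    div: int = 0
    root: int = 0
    comp: int = 0
    exp: int = 0
    int_cells: int = 0
    float_cells: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        for kind in OP_KINDS + ("int_cells", "float_cells"):
            if getattr(self, kind) < 0:
                raise ValueError(f"negative count for {kind!r}")

    def __add__(self, other: "OperationCount") -> "OperationCount":
        if not isinstance(other, OperationCount):
            return NotImplemented
        kwargs = {
            k: getattr(self, k) + getattr(other, k)
            for k in OP_KINDS + ("int_cells", "float_cells")
        }
        return OperationCount(**kwargs)

    def times_ops(self, k: int) -> "OperationCount":
        """Scale the operation counts by ``k`` repetitions.

        Memory cells are static storage and are left unscaled.
        """
        if k < 0:
            raise ValueError("repetition count must be >= 0")
        kwargs = {kind: getattr(self, kind) * k for kind in OP_KINDS}
        return OperationCount(
            int_cells=self.int_cells if k else 0,
            float_cells=self.float_cells if k else 0,
            label=self.label,
            **kwargs,
        )

    def memory_bytes(self, int_bytes: int, float_bytes: int = FLOAT_BYTES) -> int:
        return self.int_cells * int_bytes + self.float_cells * float_bytes


@dataclass
class MicrocontrollerProfile:
    name: str
    cycles: dict[str, int]  # per-operation machine cycles, keys = OP_KINDS
    clock_hz: float
    i_act_ma: float
    i_stb_ma: float
    voltage: float
    resolution_bits: int
    ram_bytes: int
    flash_bytes: int
    mem_block_bytes: int
    i_write_ua: float
    t_write_ms: float

    def __post_init__(self) -> None:
        missing = set(OP_KINDS) - set(self.cycles)
        if missing:
            raise ValueError(f"cycle table missing operations: {sorted(missing)}")
        for f in ("clock_hz", "i_act_ma", "i_stb_ma", "voltage", "ram_bytes",
                  "flash_bytes", "mem_block_bytes", "i_write_ua", "t_write_ms"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.ram_bytes >= self.flash_bytes:
            raise ValueError("RAM expected smaller than flash")

    @property
    def p_act_mw(self) -> float:
        return self.i_act_ma * self.voltage

    @property
    def p_stb_mw(self) -> float:
        return self.i_stb_ma * self.voltage

    @property
    def int_bytes(self) -> int:
        return self.resolution_bits // 8


@dataclass
class SensorProfile:
    name: str
    i_act_ma: float
    i_stb_ma: float
    voltage: float

    def __post_init__(self) -> None:
        if self.i_stb_ma > self.i_act_ma:
            raise ValueError("stand-by current exceeds active current")


@dataclass
class RadioProfile:
    name: str
    i_trans_ma: float = 21.7
    t_trans_ms: float = 16.0
    packet_bytes: int = 114
    mps_bits: int = 216
    conn_interval_ms: float = 7.5

    CONN_INTERVAL_RANGE_MS = (7.5, 4000.0)
    CONN_INTERVAL_STEP_MS = 1.25

    def __post_init__(self) -> None:
        lo, hi = self.CONN_INTERVAL_RANGE_MS
        if not lo <= self.conn_interval_ms <= hi:
            raise ValueError("connInterval outside BLE range")

    def data_rate_bps(self, conn_interval_ms: float | None = None) -> float:
        """Transmission data rate ν_tr = MPS / connInterval in bits/s."""
        ci = self.conn_interval_ms if conn_interval_ms is None else conn_interval_ms
        lo, hi = self.CONN_INTERVAL_RANGE_MS
        if not lo <= ci <= hi:
            raise ValueError("connInterval outside BLE range")
        return self.mps_bits / (ci / 1000.0)


@dataclass
class BatteryProfile:
    name: str
    capacity_mwh: float = 925.0
    runtime_h: float = 16.0
    phi: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must be in (0, 1]")
        if self.capacity_mwh <= 0 or self.runtime_h <= 0:
            raise ValueError("capacity and runtime must be positive")


@dataclass
class HardwareProfiles:
    microcontrollers: dict[str, MicrocontrollerProfile]
    sensor: SensorProfile
    radio: RadioProfile
    battery: BatteryProfile

    def to_dict(self) -> dict:
        return {
            "microcontrollers": {k: asdict(v) for k, v in self.microcontrollers.items()},
            "sensor": asdict(self.sensor),
            "radio": asdict(self.radio),
            "battery": asdict(self.battery),
        }


def load_profiles(path=None) -> HardwareProfiles:
    """Load hardware profiles from YAML (the shipped file by default)."""
    if path is None:
        text = resources.files("dyndse").joinpath("profiles/hardware.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mcus = {k: MicrocontrollerProfile(**v) for k, v in raw["microcontrollers"].items()}
    return HardwareProfiles(
        microcontrollers=mcus,
        sensor=SensorProfile(**raw["sensor"]),
        radio=RadioProfile(**raw["radio"]),
        battery=BatteryProfile(**raw["battery"]),
    )


# ---------------------------------------------------------------------------
# execution time
# ---------------------------------------------------------------------------

def cycles(counts: OperationCount, mcu: MicrocontrollerProfile) -> int:
    """Machine cycles for a function: Σ_x n_x^op · n_x^cyc."""
    return sum(getattr(counts, k) * mcu.cycles[k] for k in OP_KINDS)


def execution_time(n_cycles: float, mcu: MicrocontrollerProfile) -> float:
    """Execution time in seconds: cycles divided by the clock frequency."""
    if n_cycles < 0:
        raise ValueError("cycle count must be >= 0")
    return n_cycles / mcu.clock_hz


def et_aggregate(frame_ets, mode: str) -> float:
    """Aggregate per-function execution times into the ET metric.

    ``real_time``: ET is the per-frame budget — the sum of the function
    times within one frame; when several frames are given, the maximum
    per-frame sum is returned (the bound checked against the frame
    length m).  ``online``: ET is the total over all frames, checked
    against the runtime T.  ``frame_ets`` may be a flat sequence (one
    frame) or a sequence of per-frame sequences.
    """
    if mode not in ("real_time", "online"):
        raise ValueError(f"unknown runtime mode {mode!r}")
    frames = list(frame_ets)
    if not frames:
        return 0.0
    if not isinstance(frames[0], (list, tuple, np.ndarray)):
        frames = [frames]
    per_frame = [float(sum(f)) for f in frames]
    return max(per_frame) if mode == "real_time" else float(sum(per_frame))


def kernel_svm_counts(v: int, d: int, convention: str = "worked_example") -> OperationCount:
    """Operation tally for one linear kernel-SVM evaluation pass.

    ``worked_example`` counts Add = v (the convention of the in-text
    cycle computation); ``table`` counts Add = v + 1.
    """
    if convention == "worked_example":
        add = v
    elif convention == "table":
        add = v + 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return OperationCount(add=add, mult=2 * v, comp=1,
                          int_cells=v, float_cells=v * (d + 1),
                          label="kernel_svm")


def rbf_kernel_counts(v: int, d: int, convention: str = "worked_example") -> OperationCount:
    """Operation tally for the RBF kernel over v support vectors.

    The multiplication count is v(d−1) under the worked-example
    convention and v(d+1) under the table convention.
    """
    if convention == "worked_example":
        mult = v * (d - 1)
    elif convention == "table":
        mult = v * (d + 1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return OperationCount(add=v * (2 * d - 1), mult=mult, comp=1, exp=v,
                          float_cells=1, label="rbf_kernel")


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def mcu_energy(active_ets_s: Iterable[float], total_time_s: float,
               mcu: MicrocontrollerProfile) -> float:
    """Microcontroller energy in mWh: active time at P_act, rest at P_stb.

    Raises if the active time exceeds ``total_time_s`` (an
    over-committed schedule, i.e. real-time infeasibility).
    """
    active_s = float(sum(active_ets_s))
    t_stb_s = total_time_s - active_s
    if t_stb_s < -1e-9:
        raise ValueError("active execution time exceeds the available runtime")
    t_stb_s = max(t_stb_s, 0.0)
    return (active_s / 3600.0) * mcu.p_act_mw + (t_stb_s / 3600.0) * mcu.p_stb_mw


def sensor_energy(duty_trace: Sequence[float], sensor: SensorProfile,
                  tr_s: float = 1.0) -> float:
    """Sensor energy in mWh from the instantaneous duty-cycle trace.

    Each trace entry covers one simulation step of ``tr_s`` seconds at
    current I_act·D + I_stb·(1−D).
    """
    d = np.asarray(duty_trace, dtype=float)
    if d.size and (d.min() < 0 or d.max() > 1):
        raise ValueError("duty values must lie in [0, 1]")
    i_ma = sensor.i_act_ma * d + sensor.i_stb_ma * (1.0 - d)
    return float(np.sum(i_ma) * sensor.voltage * (tr_s / 3600.0))


def memory_energy(n_blocks: int, mcu: MicrocontrollerProfile,
                  total_time_s: float, i_stb_mem_ma: float = 0.0) -> float:
    """Non-volatile-memory energy in mWh: per-block writes plus a static term.

    Read energy is neglected.  The memory stand-by current is not part
    of the shipped datasheet values and defaults to zero.
    """
    if n_blocks < 0:
        raise ValueError("block count must be >= 0")
    t_write_s = mcu.t_write_ms / 1000.0
    if total_time_s < n_blocks * t_write_s:
        raise ValueError("total time shorter than cumulative write time")
    write = n_blocks * (mcu.i_write_ua / 1000.0) * mcu.voltage * (t_write_s / 3600.0)
    static = i_stb_mem_ma * mcu.voltage * ((total_time_s - n_blocks * t_write_s) / 3600.0)
    return write + static


def radio_energy(n_packets: int, radio: RadioProfile, voltage: float = 3.3) -> float:
    """Radio transmission energy in mWh for ``n_packets`` packets."""
    if n_packets < 0:
        raise ValueError("packet count must be >= 0")
    per_packet = radio.i_trans_ma * voltage * (radio.t_trans_ms / 1000.0 / 3600.0)
    return n_packets * per_packet


@dataclass
class EnergyBreakdown:
    """EC split into its four parts (all mWh)."""

    mcu: float = 0.0
    sensor: float = 0.0
    memory: float = 0.0
    radio: float = 0.0

    @property
    def total(self) -> float:
        return self.mcu + self.sensor + self.memory + self.radio


def total_energy(parts: Iterable[float]) -> float:
    """Total EC as the exact sum of its component parts."""
    return float(sum(parts))


def energy_requirement(batt: BatteryProfile) -> float:
    """Energy budget zρ2 in mWh: BC / RT · ϕ."""
    return batt.capacity_mwh / batt.runtime_h * batt.phi


# ---------------------------------------------------------------------------
# memory demand
# ---------------------------------------------------------------------------

def ring_buffer_peak(frame_et_s: float, frame_duration_s: float, n_frames: int) -> int:
    """Peak ring-buffer occupancy (frames) for online processing.

    Frames arrive every ``frame_duration_s`` and are serviced serially,
    each taking ``frame_et_s``.  When the service keeps up (ET < frame
    duration) the peak is one frame; otherwise the backlog grows.
    """
    if n_frames <= 0:
        return 0
    if frame_et_s <= frame_duration_s:
        return 1
    peak = 1
    completed = 0  # frames fully serviced so far
    completion = 0.0  # completion time of the last serviced frame
    completions: list[float] = []
    for k in range(n_frames):
        arrival = k * frame_duration_s
        completion = max(arrival, completion) + frame_et_s
        completions.append(completion)
        while completed < k and completions[completed] <= arrival:
            completed += 1
        peak = max(peak, k + 1 - completed)
    return peak


def memory_demand(function_counts: Iterable[OperationCount],
                  frame_bytes: int,
                  mcu: MicrocontrollerProfile,
                  mode: str,
                  n_events_buffered: int = 1,
                  code_bytes: int = 8192,
                  ring_peak_frames: int = 1) -> int:
    """Upper bound MD = m_c + m_d + Σ_f m_f + m_e in bytes.

    ``m_d`` is one frame in real-time mode and ``ring_peak_frames``
    frames in online mode (the simulated ring-buffer peak).  Each
    buffered event costs 4 bytes (two 2-byte timestamps).
    """
    if mode not in ("real_time", "online"):
        raise ValueError(f"unknown runtime mode {mode!r}")
    m_f = sum(c.memory_bytes(mcu.int_bytes) for c in function_counts)
    m_d = frame_bytes if mode == "real_time" else frame_bytes * max(ring_peak_frames, 1)
    m_e = 4 * n_events_buffered
    return code_bytes + m_d + m_f + m_e


# ---------------------------------------------------------------------------
# communication latency
# ---------------------------------------------------------------------------

def comm_latency(et_sum_s: float, event_bits: int, radio: RadioProfile,
                 conn_interval_ms: float | None = None) -> float:
    """Latency CL in seconds: processing time plus transmission time.

    CL = Σ_f ET_f + m_e / ν_tr with ν_tr = MPS / connInterval.
    """
    if event_bits < 0:
        raise ValueError("event payload must be >= 0 bits")
    rate = radio.data_rate_bps(conn_interval_ms)
    return et_sum_s + event_bits / rate
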