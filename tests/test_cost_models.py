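"""Machine-cycle, energy, memory and latency cost models."""

import numpy as np
import pytest

from dyndse import cost_models as cm

# Every printed cell of the shipped hardware tables, frozen here for the
# round-trip check (cycle counts; clock MHz; currents mA; V; resolution
# bits; flash/RAM kB; block bytes; write current uA; write time ms).
EXPECTED_MCUS = {
    "psoc1_m8c": {
        "cycles": {"add": 544, "mult": 560, "div": 912, "root": 1344,
                   "comp": 80, "exp": 2672},
        "clock_mhz": 24, "i_act_ma": 8.0, "i_stb_ma": 0.025, "voltage": 3.3,
        "resolution_bits": 8, "flash_kb": 32, "ram_kb": 2,
        "mem_block_bytes": 64, "i_write_ua": 619.5, "t_write_ms": 1.5,
    },
    "msp430f1611": {
        "cycles": {"add": 177, "mult": 153, "div": 405, "root": 668,
                   "comp": 37, "exp": 334},
        "clock_mhz": 8, "i_act_ma": 0.57, "i_stb_ma": 0.05, "voltage": 3.0,
        "resolution_bits": 16, "flash_kb": 48.25, "ram_kb": 10,
        "mem_block_bytes": 60, "i_write_ua": 2300.0, "t_write_ms": 23.0,
    },
    "arm_cortex_m3": {
        "cycles": {"add": 60, "mult": 50, "div": 80, "root": 380,
                   "comp": 12, "exp": 210},
        "clock_mhz": 48, "i_act_ma": 7.0, "i_stb_ma": 0.55, "voltage": 3.3,
        "resolution_bits": 32, "flash_kb": 512, "ram_kb": 96,
        "mem_block_bytes": 256, "i_write_ua": 500.0, "t_write_ms": 3.28,
    },
}


class TestProfiles:
    def test_mcu_round_trip(self, profiles):
        assert set(profiles.microcontrollers) == set(EXPECTED_MCUS)
        for key, exp in EXPECTED_MCUS.items():
            mcu = profiles.microcontrollers[key]
            assert mcu.cycles == exp["cycles"]
            assert mcu.clock_hz == exp["clock_mhz"] * 1e6
            assert mcu.i_act_ma == exp["i_act_ma"]
            assert mcu.i_stb_ma == exp["i_stb_ma"]
            assert mcu.voltage == exp["voltage"]
            assert mcu.resolution_bits == exp["resolution_bits"]
            assert mcu.flash_bytes == exp["flash_kb"] * 1000
            assert mcu.ram_bytes == exp["ram_kb"] * 1000
            assert mcu.mem_block_bytes == exp["mem_block_bytes"]
            assert mcu.i_write_ua == exp["i_write_ua"]
            assert mcu.t_write_ms == exp["t_write_ms"]

    def test_peripheral_round_trip(self, profiles):
        s, r, b = profiles.sensor, profiles.radio, profiles.battery
        assert (s.i_act_ma, s.i_stb_ma, s.voltage) == (4.0, 0.008, 3.3)
        assert (r.i_trans_ma, r.t_trans_ms, r.packet_bytes, r.mps_bits) == \
            (21.7, 16.0, 114, 216)
        assert (b.capacity_mwh, b.runtime_h, b.phi) == (925.0, 16.0, 0.9)


class TestCycles:
    def test_single_add_on_msp430(self, profiles):
        counts = cm.OperationCount(add=1)
        assert cm.cycles(counts, profiles.microcontrollers["msp430f1611"]) == 177

    def test_empty_counts(self, arm):
        assert cm.cycles(cm.OperationCount(), arm) == 0

    def test_dot_product_oracle_all_profiles(self, profiles):
        rng = np.random.default_rng(3)
        for mcu in profiles.microcontrollers.values():
            for _ in range(20):
                ops = {k: int(rng.integers(0, 1000)) for k in cm.OP_KINDS}
                counts = cm.OperationCount(**ops)
                oracle = sum(ops[k] * mcu.cycles[k] for k in cm.OP_KINDS)
                assert cm.cycles(counts, mcu) == oracle

    def test_table_conventions(self):
        k = cm.kernel_svm_counts(1500, 20, convention="table")
        assert (k.add, k.mult, k.comp) == (1501, 3000, 1)
        r = cm.rbf_kernel_counts(1500, 20, convention="table")
        assert r.mult == 1500 * 21
        r = cm.rbf_kernel_counts(1500, 20, convention="worked_example")
        assert r.mult == 1500 * 19


class TestExecutionTime:
    def test_one_second_at_clock(self, arm):
        assert cm.execution_time(48_000_000, arm) == pytest.approx(1.0)

    def test_inverse_proportional_to_clock(self, profiles):
        arm = profiles.microcontrollers["arm_cortex_m3"]
        from dataclasses import replace
        half = replace(arm, clock_hz=arm.clock_hz / 2)
        assert cm.execution_time(1000, half) == 2 * cm.execution_time(1000, arm)

    def test_aggregate_real_time_sums_functions(self):
        assert cm.et_aggregate([0.002, 0.003], "real_time") == pytest.approx(0.005)

    def test_aggregate_online_sums_frames(self):
        assert cm.et_aggregate([[0.005]] * 10, "online") == pytest.approx(0.05)

    def test_aggregate_empty(self):
        assert cm.et_aggregate([], "online") == 0.0


class TestMcuEnergy:
    def test_idle_hour_on_arm(self, arm):
        # stand-by only: 0.55 mA * 3.3 V * 1 h
        assert cm.mcu_energy([], 3600.0, arm) == pytest.approx(1.815)

    def test_zero_time(self, arm):
        assert cm.mcu_energy([], 0.0, arm) == 0.0

    def test_overcommitted_schedule_raises(self, arm):
        with pytest.raises(ValueError):
            cm.mcu_energy([10.0], 5.0, arm)


class TestSensorEnergy:
    def test_full_duty_hour(self, profiles):
        trace = np.ones(3600)
        assert cm.sensor_energy(trace, profiles.sensor) == pytest.approx(13.2)

    def test_zero_duty_hour(self, profiles):
        trace = np.zeros(3600)
        assert cm.sensor_energy(trace, profiles.sensor) == pytest.approx(0.0264)

    def test_linearity_in_duty(self, profiles):
        e0 = cm.sensor_energy(np.zeros(100), profiles.sensor)
        e1 = cm.sensor_energy(np.ones(100), profiles.sensor)
        e_half = cm.sensor_energy(np.full(100, 0.5), profiles.sensor)
        assert e_half == pytest.approx((e0 + e1) / 2)

    def test_out_of_range_duty_rejected(self, profiles):
        with pytest.raises(ValueError):
            cm.sensor_energy([1.2], profiles.sensor)


class TestMemoryEnergy:
    def test_single_block_write_term_psoc1(self, profiles):
        psoc = profiles.microcontrollers["psoc1_m8c"]
        # 619.5 uA * 3.3 V * 1.5 ms
        e = cm.memory_energy(1, psoc, total_time_s=10.0)
        assert e == pytest.approx(8.518e-7, rel=1e-3)

    def test_zero_blocks_static_term_only(self, arm):
        assert cm.memory_energy(0, arm, 3600.0) == 0.0
        e = cm.memory_energy(0, arm, 3600.0, i_stb_mem_ma=0.01)
        assert e == pytest.approx(0.01 * 3.3)

    def test_linear_in_block_count(self, arm):
        e1 = cm.memory_energy(1, arm, 3600.0)
        e10 = cm.memory_energy(10, arm, 3600.0)
        assert e10 == pytest.approx(10 * e1)


class TestRadioEnergy:
    def test_zero_packets(self, profiles):
        assert cm.radio_energy(0, profiles.radio) == 0.0

    def test_single_packet(self, profiles):
        # 21.7 mA * 3.3 V * 16 ms
        assert cm.radio_energy(1, profiles.radio) == pytest.approx(3.183e-4, rel=1e-3)

    def test_linear(self, profiles):
        assert cm.radio_energy(100, profiles.radio) == \
            pytest.approx(100 * cm.radio_energy(1, profiles.radio))


class TestTotals:
    def test_sum_of_parts(self):
        assert cm.total_energy([1, 2, 3, 4]) == 10
        assert cm.EnergyBreakdown(1, 2, 3, 4).total == 10

    def test_energy_requirement_simple(self):
        batt = cm.BatteryProfile("b", capacity_mwh=100, runtime_h=10, phi=1.0)
        assert cm.energy_requirement(batt) == pytest.approx(10.0)

    def test_energy_requirement_decreasing_in_runtime(self):
        b1 = cm.BatteryProfile("b", capacity_mwh=925, runtime_h=16, phi=0.9)
        b2 = cm.BatteryProfile("b", capacity_mwh=925, runtime_h=24, phi=0.9)
        assert cm.energy_requirement(b2) < cm.energy_requirement(b1)


class TestMemoryDemand:
    def test_real_time_frame_bytes(self, arm):
        # m=256 samples, 2 channels, 4-byte floats -> 2048-byte data term
        md = cm.memory_demand([], frame_bytes=2 * 256 * 4, mcu=arm,
                              mode="real_time", n_events_buffered=0,
                              code_bytes=0)
        assert md == 2048

    def test_event_memory_four_bytes(self, arm):
        md = cm.memory_demand([], frame_bytes=0, mcu=arm, mode="real_time",
                              n_events_buffered=1, code_bytes=0)
        assert md == 4

    def test_function_cells_use_data_resolution(self, profiles):
        counts = [cm.OperationCount(int_cells=2, float_cells=3)]
        msp = profiles.microcontrollers["msp430f1611"]  # 16-bit ints
        md = cm.memory_demand(counts, frame_bytes=0, mcu=msp,
                              mode="real_time", n_events_buffered=0,
                              code_bytes=0)
        assert md == 2 * 2 + 3 * 4


class TestRingBuffer:
    def test_service_keeps_up(self):
        assert cm.ring_buffer_peak(0.5, 1.0, 1000) == 1

    def test_backlog_grows_when_slow(self):
        peaks = [cm.ring_buffer_peak(2.0, 1.0, n) for n in (10, 100, 1000)]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_backlog_matches_queue_oracle(self):
        # explicit event-by-event queue simulation
        et, m, n = 1.7, 1.0, 50
        arrivals = [k * m for k in range(n)]
        completion, completions = 0.0, []
        for a in arrivals:
            completion = max(a, completion) + et
            completions.append(completion)
        peak = max(sum(1 for j in range(k + 1) if completions[j] > arrivals[k])
                   for k in range(n))
        assert cm.ring_buffer_peak(et, m, n) == peak


class TestCommLatency:
    def test_data_rate(self, profiles):
        assert profiles.radio.data_rate_bps() == pytest.approx(28_800)

    def test_zero_payload(self, profiles):
        assert cm.comm_latency(0.1, 0, profiles.radio) == pytest.approx(0.1)

    def test_non_decreasing_in_conn_interval(self, profiles):
        cls = [cm.comm_latency(0.1, 32, profiles.radio, conn_interval_ms=ci)
               for ci in (7.5, 100.0, 1000.0)]
        assert cls == sorted(cls)

    def test_interval_outside_ble_range_rejected(self, profiles):
        with pytest.raises(ValueError):
            cm.comm_latency(0.1, 32, profiles.radio, conn_interval_ms=5000.0)
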