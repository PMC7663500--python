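"""Spotting pipelines: preprocessing, features, gating, training, counts."""

import numpy as np
import pytest
from scipy import signal as sps

from dyndse.spotting import (
    OracleSpotter,
    SpottingParams,
    TrainedSpotter,
    extract_features_fft,
    frame_labels,
    gate_frame,
    merge_frames_to_events,
    preprocess,
    segment_frames,
    spot_events,
    spot_frames,
    spotting_op_count,
    total_op_count,
    train_spotter,
    wpd_leaf_coeffs,
)

FS = 256.0
WPD = SpottingParams(kind="wpd", m=1.0, d=20)
FFT = SpottingParams(kind="fft", m=1.0, d=4)


class TestPreprocess:
    def test_high_pass_kills_dc(self):
        frame = np.full((2, 256), 100.0)
        out = preprocess(frame, "wpd", FS)
        # rectified output of the 20 Hz high-pass on a DC input
        assert np.sqrt(np.mean(out[:, 64:] ** 2)) < 1.0

    def test_notch_attenuates_50hz_by_20db(self):
        # frequency response of the designed notch at 50 Hz
        b, a = sps.iirnotch(50.0, Q=30.0, fs=FS)
        _, h = sps.freqz(b, a, worN=[50.0], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) <= -20.0

    def test_output_rectified(self):
        rng = np.random.default_rng(0)
        out = preprocess(rng.normal(size=(2, 512)), "wpd", FS)
        assert np.all(out >= 0)

    def test_fft_kind_smooths(self):
        x = np.zeros((1, 8))
        x[0, 3] = 2.0
        out = preprocess(x, "fft", FS)
        np.testing.assert_allclose(out[0, 3:5], [1.0, 1.0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((1, 8)), "cnn", FS)


class TestSegmentation:
    def test_covers_stream_without_overlap(self):
        x = np.arange(2 * 1000).reshape(2, 1000)
        frames = segment_frames(x, 256)
        assert frames.shape == (3, 2, 256)
        np.testing.assert_array_equal(
            np.concatenate([f[0] for f in frames]), x[0, :768])


class TestGate:
    def test_below_threshold(self):
        assert not gate_frame(np.full((2, 10), 5.0), 12.0)

    def test_at_threshold_inclusive(self):
        assert gate_frame(np.full((2, 10), 12.0), 12.0)

    def test_percentile_threshold_gates_out_noise(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(0, 10, size=(2000, 2, 256))
        maxima = frames.max(axis=(1, 2))
        threshold = np.percentile(maxima, 95.0)
        gated_in = np.mean([gate_frame(f, threshold) for f in frames])
        assert gated_in == pytest.approx(0.05, abs=0.02)


class TestFFTFeatures:
    def test_zero_frame_gives_zero_vector(self):
        out = extract_features_fft(np.zeros((2, 256)), FFT)
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_unit_norm_for_nonzero_frame(self):
        rng = np.random.default_rng(1)
        out = extract_features_fft(rng.normal(size=(2, 256)), FFT)
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_spectral_maximum_matches_fourier_oracle(self):
        # sinusoid at an exact bin of the padded transform
        n, k = 256, 16
        t = np.arange(n)
        frame = np.sin(2 * np.pi * k * t / n)[None, :]
        mags = np.abs(np.fft.rfft(frame[0], n=n))
        assert np.argmax(mags) == k
        feats_raw = np.concatenate(
            [frame.std(axis=1), np.abs(np.fft.rfft(frame, n=n)).max(axis=1)])
        expected = feats_raw / np.linalg.norm(feats_raw)
        params = SpottingParams(kind="fft", m=n, m_unit="samples", d=2,
                                n_channels=1)
        np.testing.assert_allclose(
            extract_features_fft(frame, params), expected, rtol=1e-12)


class TestWPDFeatures:
    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(10, 256))
        coeffs = wpd_leaf_coeffs(frames, "db2")
        assert coeffs.shape == (10, 256)
        np.testing.assert_allclose(
            np.sum(coeffs ** 2, axis=1), np.sum(frames ** 2, axis=1),
            rtol=1e-6)

    def test_zero_frame_gives_zero_coeffs(self):
        assert not wpd_leaf_coeffs(np.zeros((1, 64)), "db2").any()

    def test_too_short_frame_rejected(self):
        with pytest.raises(ValueError):
            wpd_leaf_coeffs(np.zeros((1, 2)), "db2")


class TestEventMerging:
    def test_all_negative(self):
        assert merge_frames_to_events(np.zeros(10, dtype=bool), 1.0) == []

    def test_single_run(self):
        flags = np.zeros(12, dtype=bool)
        flags[3:8] = True
        assert merge_frames_to_events(flags, 1.0) == [(3.0, 8.0)]

    def test_multiple_runs(self):
        flags = np.array([True, False, True, True, False])
        assert merge_frames_to_events(flags, 0.5) == [(0.0, 0.5), (1.0, 2.0)]


class TestOracleSpotting:
    def test_oracle_reproduces_minute_rounded_truth(self, short_streams):
        sig = short_streams[0]
        params = SpottingParams(kind="wpd", m=1.0, d=20)
        oracle = OracleSpotter(sig, params)
        events = spot_events(sig, oracle, params)
        assert events == sig.events


@pytest.fixture(scope="module")
def separable_streams():
    from dyndse.synthetic_emg import GeneratorParams, generate_participant
    return [generate_participant(GeneratorParams(
        duration=1800.0, n_events=3, event_duration_range=(180.0, 300.0),
        burst_amplitude=300.0, edge_jitter=5.0, seed=40 + s))
        for s in range(3)]


class TestTraining:
    def test_separable_data_high_heldout_f1(self, separable_streams):
        from sklearn.metrics import f1_score
        params = SpottingParams(kind="wpd", m=1.0, d=20)
        spotter = train_spotter(separable_streams, params, holdout=0, seed=0)
        flags = spot_frames(separable_streams[0].channels, spotter, params)
        labels = frame_labels(separable_streams[0], params.frame_len)
        assert f1_score(labels, flags) >= 0.9

    def test_same_seed_same_hyperparameters(self, short_streams):
        a = train_spotter(short_streams, WPD, seed=3)
        b = train_spotter(short_streams, WPD, seed=3)
        assert a.hyperparams == b.hyperparams
        assert a.gate_threshold == b.gate_threshold

    def test_single_grid_point_chosen(self, short_streams):
        grid = {"gamma": [0.3], "nu": [0.1]}
        spotter = train_spotter(short_streams, WPD, grid=grid)
        assert spotter.hyperparams == {"gamma": 0.3, "nu": 0.1}

    def test_no_event_frames_rejected(self):
        from dyndse.synthetic_emg import GeneratorParams, generate_participant
        quiet = [generate_participant(GeneratorParams(
            duration=300.0, n_events=0, seed=s)) for s in range(2)]
        with pytest.raises(ValueError):
            train_spotter(quiet, WPD)

    def test_fft_kind_has_no_gate(self, short_streams):
        spotter = train_spotter(short_streams, FFT,
                                grid={"gamma": ["scale"], "nu": [0.1]})
        assert spotter.gate_threshold == -np.inf

    def test_serialization_round_trip(self, short_streams, tmp_path):
        spotter = train_spotter(short_streams, WPD,
                                grid={"gamma": ["scale"], "nu": [0.1]})
        path = tmp_path / "spotter.json"
        spotter.to_file(path)
        restored = TrainedSpotter.from_file(path)
        sig = short_streams[0]
        np.testing.assert_array_equal(
            spot_frames(sig.channels, spotter, WPD),
            spot_frames(sig.channels, restored, WPD))

    def test_gated_frames_skip_feature_extraction(self, short_streams):
        spotter = train_spotter(short_streams, WPD,
                                grid={"gamma": ["scale"], "nu": [0.1]})
        sig = short_streams[0]
        raw = segment_frames(sig.channels, WPD.frame_len)
        pre = segment_frames(preprocess(sig.channels, "wpd", FS), WPD.frame_len)
        calls = []
        original = spotter.features

        def counting(pre_frames):
            calls.append(len(pre_frames))
            return original(pre_frames)

        spotter.features = counting
        flags = spotter.frame_flags(raw, pre)
        gated_in = int((raw.max(axis=(1, 2)) >= spotter.gate_threshold).sum())
        assert sum(calls) == gated_in < len(raw)
        assert not flags[raw.max(axis=(1, 2)) < spotter.gate_threshold].any()


class TestOperationCounts:
    def test_kernel_svm_row(self):
        params = SpottingParams(kind="wpd", m=256, m_unit="samples", d=20, v=1500)
        stages = spotting_op_count(params)
        kernel = [c for c in stages["spotting"] if c.label == "kernel_svm"][0]
        assert (kernel.add, kernel.mult, kernel.comp) == (1501, 3000, 1)
        assert kernel.int_cells == 1500 and kernel.float_cells == 1500 * 21

    def test_standard_deviation_row(self):
        m = 256
        params = SpottingParams(kind="fft", m=m, m_unit="samples", d=4)
        stages = spotting_op_count(params)
        std = [c for c in stages["feature_extraction"]
               if c.label == "standard_deviation"][0]
        assert (std.add, std.mult, std.div, std.root) == (3 * m - 1, m, 2, 1)

    def test_fft_row(self):
        m = 256
        params = SpottingParams(kind="fft", m=m, m_unit="samples", d=4)
        stages = spotting_op_count(params)
        fft = [c for c in stages["feature_extraction"] if c.label == "fft"][0]
        assert fft.add == 3 * m * 8 and fft.mult == 2 * m * 8

    def test_rbf_conventions(self):
        params = SpottingParams(kind="wpd", m=256, m_unit="samples", d=20, v=1500)
        worked = spotting_op_count(params)["spotting"][1]
        table = spotting_op_count(params, rbf_convention="table")["spotting"][1]
        assert worked.mult == 1500 * 19
        assert table.mult == 1500 * 21
        assert worked.add == table.add == 1500 * 39

    def test_counts_affine_in_v_and_d(self):
        # the support-vector and feature-dimension dependencies are affine
        def totals(v, d):
            p = SpottingParams(kind="wpd", m=256, m_unit="samples", d=d, v=v)
            t = total_op_count(spotting_op_count(p))
            return np.array([t.add, t.mult, t.comp, t.exp], dtype=float)

        f0, f1, f2 = totals(100, 10), totals(200, 10), totals(300, 10)
        np.testing.assert_allclose(f2 - f1, f1 - f0)
        g0, g1, g2 = totals(100, 10), totals(100, 20), totals(100, 30)
        np.testing.assert_allclose(g2 - g1, g1 - g0)

    def test_low_pass_counted_for_both_pipelines(self):
        for kind in ("fft", "wpd"):
            params = SpottingParams(kind=kind, m=256, m_unit="samples",
                                    d=4 if kind == "fft" else 20)
            pre = spotting_op_count(params)["pre_processing"]
            assert pre[0].add == 256
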