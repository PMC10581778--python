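"""Trace I/O, downsampling, segmentation, leak and maximum-current metrics."""

import numpy as np
import pytest

from thermoclamp import scenarios
from thermoclamp.gating import current_piecewise
from thermoclamp.simulate import ActivationSchedule, CellPopulationSpec, simulate_cell_population
from thermoclamp.protocols import default_temp_protocol
from thermoclamp.traces import (
    ActivationSegment,
    Recording,
    ResamplingError,
    TraceFormatError,
    downsample,
    measure_leak,
    measure_max_current,
    read_trace,
    segment_activations,
    write_trace,
)


def _recording(n=6000, fs=100.0, temp=None, current=None):
    t = np.arange(n) / fs
    return Recording(
        time=t,
        temperature=np.full(n, 6.0) if temp is None else temp,
        current=np.full(n, -50.0) if current is None else current,
        voltage=np.full(n, -60.0),
        sample_rate=fs,
        metadata={"cell_id": "c0", "condition": "control"},
    )


class TestTraceIO:
    def test_round_trip_preserves_values_and_metadata(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = _recording(current=rng.normal(-50, 5, 6000))
        rec.metadata["rna_ng"] = 92.0
        path = tmp_path / "cell.csv"
        write_trace(rec, path)
        back = read_trace(path)
        assert len(back) == 6000
        assert back.sample_rate == pytest.approx(100.0)
        np.testing.assert_allclose(back.current, rec.current, rtol=1e-4)
        assert back.metadata["cell_id"] == "c0"
        assert back.metadata["rna_ng"] == pytest.approx(92.0)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# cell_id: x\ntime_s,current_nA,voltage_mV\n0,1,2\n0.01,1,2\n")
        with pytest.raises(TraceFormatError, match="temp_C"):
            read_trace(path)

    def test_nonuniform_grid_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_s,temp_C,current_nA,voltage_mV\n"
            "0.00,6,-50,-60\n0.01,6,-50,-60\n0.05,6,-50,-60\n"
        )
        with pytest.raises(TraceFormatError, match="non-uniform"):
            read_trace(path)

    def test_crlf_and_extra_columns_tolerated(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text(
            "# cell_id: z\r\n"
            "time_s,temp_C,current_nA,voltage_mV,extra\r\n"
            "0.00,6,-50,-60,1\r\n0.01,6,-50,-60,2\r\n0.02,6,-50,-60,3\r\n"
        )
        rec = read_trace(path)
        assert len(rec) == 3


class TestDownsample:
    def test_factor_twenty_block_mean(self):
        rec = _recording(n=120_000, fs=2000.0)
        out = downsample(rec, 100.0)
        assert len(out) == 6000
        assert out.sample_rate == 100.0

    def test_constant_signal_unchanged(self):
        rec = _recording()
        out = downsample(rec, 10.0)
        np.testing.assert_allclose(out.current, -50.0)

    def test_white_noise_sd_shrinks_by_sqrt_factor(self):
        rng = np.random.default_rng(1)
        sigma = 4.0
        rec = _recording(n=200_000, fs=2000.0, current=rng.normal(0, sigma, 200_000))
        out = downsample(rec, 100.0)
        assert out.current.std() == pytest.approx(sigma / np.sqrt(20), rel=0.05)

    def test_non_integer_factor_rejected(self):
        rec = _recording(fs=100.0)
        with pytest.raises(ResamplingError):
            downsample(rec, 33.0)


class TestSegmentation:
    def test_three_cycles_give_three_indexed_segments(self):
        proto = default_temp_protocol(n_cycles=3, cycle_duration=20.0, sample_rate=100.0)
        spec = CellPopulationSpec(
            n_cells=1, channel_params=scenarios.TRPA1B, noise_sd=0.0, seed=0
        )
        rec = simulate_cell_population(spec, proto)[0].recording
        segs = segment_activations(rec)
        assert [s.activation_index for s in segs] == [1, 2, 3]
        for s in segs:
            assert s.hold_temp == pytest.approx(6.0, abs=0.3)
            assert s.temperature[-1] == pytest.approx(40.0, abs=0.5)

    def test_constant_temperature_gives_no_segments(self):
        assert segment_activations(_recording()) == []

    def test_downsample_then_segment_matches_segment_then_downsample(self):
        proto = default_temp_protocol(n_cycles=3, cycle_duration=20.0, sample_rate=1000.0)
        spec = CellPopulationSpec(
            n_cells=1, channel_params=scenarios.TRPA1B, noise_sd=0.0, seed=0
        )
        rec = simulate_cell_population(spec, proto)[0].recording
        n_after = len(segment_activations(downsample(rec, 100.0)))
        n_before = len(segment_activations(rec))
        assert n_after == n_before == 3

    def test_segmentation_robust_to_noise(self, noisy_trpa1b_recordings):
        recs, proto = noisy_trpa1b_recordings
        rec = downsample(recs[0], 100.0)
        segs = segment_activations(rec)
        assert len(segs) == proto.n_cycles


class TestLeakAndMaxCurrent:
    def test_leak_of_constant_hold(self):
        seg = ActivationSegment(
            activation_index=1,
            temperature=np.full(500, 6.0),
            current=np.full(500, -50.0),
            sample_rate=100.0,
            hold_temp=6.0,
            onset_index=400,
        )
        leak = measure_leak(seg, window=2.0)
        assert leak.leak_nA == pytest.approx(-50.0)
        assert leak.hold_temp_C == pytest.approx(6.0)
        assert not leak.shrunk

    def test_short_hold_window_shrinks_with_flag(self):
        seg = ActivationSegment(
            activation_index=1,
            temperature=np.full(100, 6.0),
            current=np.full(100, -10.0),
            sample_rate=100.0,
            hold_temp=6.0,
            onset_index=50,
        )
        leak = measure_leak(seg, window=2.0)
        assert leak.shrunk and leak.leak_nA == pytest.approx(-10.0)

    def test_leak_matches_ohmic_closed_form(self):
        # leak-only population: leak at the hold is g*(V - E_rev)
        proto = default_temp_protocol(n_cycles=1, cycle_duration=30.0, sample_rate=100.0)
        spec = CellPopulationSpec(
            n_cells=1, channel_params=None, leak_g=0.5, leak_q10=1.24,
            leak_t_ref=6.0, noise_sd=0.5, seed=5,
        )
        rec = simulate_cell_population(spec, proto)[0].recording
        (seg,) = segment_activations(rec)
        leak = measure_leak(seg)
        assert leak.leak_nA == pytest.approx(0.5 * (-60.0), abs=0.5)

    def test_leak_series_nondecreasing_after_scheduled_runup(self):
        proto = default_temp_protocol(n_cycles=4, cycle_duration=20.0, sample_rate=100.0)
        spec = CellPopulationSpec(
            n_cells=1, channel_params=None, leak_g=0.5, leak_q10=1.24,
            leak_t_ref=6.0, noise_sd=0.2, seed=6,
            schedule=ActivationSchedule(
                q10_factors=(1.0,) * 4,
                leak_factors=(1.0, 1.0, 1.4, 1.9),
                threshold_lost=(False,) * 4,
            ),
        )
        rec = simulate_cell_population(spec, proto)[0].recording
        segs = segment_activations(rec)
        leaks = [abs(measure_leak(s).leak_nA) for s in segs]
        assert leaks[2] > leaks[1] and leaks[3] > leaks[2]

    def test_max_current_arithmetic(self):
        T = np.linspace(6.0, 40.0, 400)
        I = np.linspace(-50.0, -1000.0, 400)
        seg = ActivationSegment(
            activation_index=1, temperature=T, current=I,
            sample_rate=100.0, hold_temp=6.0, onset_index=10,
        )
        expected = abs(np.interp(35.0, T, I)) - 50.0
        res = measure_max_current(seg, at_temp=35.0, leak=-50.0)
        assert res.defined
        assert res.value_nA == pytest.approx(expected, rel=1e-6)

    def test_max_current_matches_piecewise_closed_form(self, noiseless_trpa1b_segment):
        seg = noiseless_trpa1b_segment
        leak = measure_leak(seg)
        res = measure_max_current(seg, at_temp=35.0, leak=leak.leak_nA)
        expected = abs(current_piecewise(35.0, scenarios.TRPA1B)) - abs(leak.leak_nA)
        assert res.value_nA == pytest.approx(expected, rel=0.01)

    def test_unreachable_temperature_flags_undefined(self):
        seg = ActivationSegment(
            activation_index=1,
            temperature=np.linspace(6.0, 20.0, 100),
            current=np.linspace(-50.0, -80.0, 100),
            sample_rate=100.0, hold_temp=6.0, onset_index=10,
        )
        res = measure_max_current(seg, at_temp=35.0, leak=-50.0)
        assert not res.defined and np.isnan(res.value_nA)

    def test_metrics_invariant_to_sign_convention(self, noiseless_trpa1b_segment):
        seg = noiseless_trpa1b_segment
        flipped = ActivationSegment(
            activation_index=seg.activation_index,
            temperature=seg.temperature,
            current=-seg.current,
            sample_rate=seg.sample_rate,
            hold_temp=seg.hold_temp,
            onset_index=seg.onset_index,
        )
        a = measure_max_current(seg, 35.0, measure_leak(seg).leak_nA)
        b = measure_max_current(flipped, 35.0, measure_leak(flipped).leak_nA)
        assert a.value_nA == pytest.approx(b.value_nA, rel=1e-12)
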