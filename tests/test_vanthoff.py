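"""Van't Hoff transform, segmented fitting, Q10 and threshold metrics."""

import math

import numpy as np
import pytest

from oracles import brute_force_segmented_rss
from thermoclamp import scenarios
from thermoclamp.gating import CELSIUS_OFFSET, PiecewiseQ10Params
from thermoclamp.simulate import CellPopulationSpec, simulate_cell_population
from thermoclamp.traces import ActivationSegment, segment_activations
from thermoclamp.vanthoff import (
    CLASS_BASELINE,
    CLASS_DISTINCT,
    CLASS_NO_DISTINCT,
    EmptyCurveError,
    ExtrapolationError,
    FitError,
    VantHoffCurve,
    derive_metrics,
    fit_segmented,
    q10_between,
    to_vanthoff,
    windowed_q10,
)


def _segment(T, I, fs=100.0, onset=0):
    return ActivationSegment(
        activation_index=1, temperature=np.asarray(T, float),
        current=np.asarray(I, float), sample_rate=fs,
        hold_temp=float(np.asarray(T)[0]), onset_index=onset,
    )


def _piecewise_curve(breaks_C, slopes_per_K, n=120, T_range=(6.0, 40.0),
                     noise=0.0, seed=0, intercept=1.0):
    """Continuous piecewise line in (1/T, y) with kinks at breaks_C."""
    T = np.linspace(*T_range, n)
    x = 1.0 / (T + CELSIUS_OFFSET)
    knots = sorted(1.0 / (b + CELSIUS_OFFSET) for b in breaks_C)
    y = intercept + slopes_per_K[0] * x
    for extra, b in zip(slopes_per_K[1:], knots):
        y = y + extra * np.maximum(x - b, 0.0)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, n)
    return VantHoffCurve(inv_T=x, log_abs_I=y, log_base=math.e)


class TestTransform:
    def test_inverse_kelvin_and_natural_log(self):
        seg = _segment([25.0, 25.0], [1.0, -1.0])
        curve = to_vanthoff(seg)
        assert curve.inv_T[0] == pytest.approx(1.0 / 298.15, rel=1e-12)
        assert curve.inv_T[0] == pytest.approx(3.3540e-3, rel=1e-4)
        assert curve.log_abs_I[0] == pytest.approx(0.0, abs=1e-12)

    def test_subfloor_currents_dropped_and_counted(self):
        seg = _segment([10.0, 20.0, 30.0], [1e-6, -5.0, -10.0])
        curve = to_vanthoff(seg, current_floor=1e-3)
        assert len(curve) == 2 and curve.n_dropped == 1

    def test_all_dropped_raises(self):
        seg = _segment([10.0, 20.0], [1e-9, -1e-9])
        with pytest.raises(EmptyCurveError):
            to_vanthoff(seg)

    def test_exact_q10_process_is_only_approximately_linear_in_inv_T(self):
        # log-linear-in-T data mapped to 1/T keeps a small residual curvature
        # (a few percent of a log unit over the full 6-40 degC span);
        # quantify it instead of assuming linearity
        T = np.linspace(6.0, 40.0, 400)
        y = np.log(10.0) + math.log(2.0) / 10.0 * (T - 6.0)
        x = 1.0 / (T + CELSIUS_OFFSET)
        A = np.vstack([np.ones_like(x), x]).T
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        assert 1e-4 < np.abs(resid).max() < 0.1


class TestSegmentedFitOracle:
    def test_exact_line_selects_zero_breakpoints(self):
        curve = _piecewise_curve([], [-5000.0])
        fit = fit_segmented(curve)
        assert fit.n_breakpoints == 0
        assert fit.slopes[0] == pytest.approx(-5000.0, rel=1e-10)

    def test_noiseless_single_kink_recovered_on_grid(self):
        # kink placed exactly on an observed sample so the one-breakpoint
        # model reproduces the data exactly and is selected
        T = np.linspace(6.0, 40.0, 201)
        b = float(T[100])
        x = 1.0 / (T + CELSIUS_OFFSET)
        bx = 1.0 / (b + CELSIUS_OFFSET)
        y = 1.0 - 1500.0 * x - 22000.0 * np.maximum(x - bx, 0.0)
        curve = VantHoffCurve(inv_T=x, log_abs_I=y, log_base=math.e)
        fit = fit_segmented(curve)
        assert fit.n_breakpoints == 1
        got_C = 1.0 / fit.breakpoints[0] - CELSIUS_OFFSET
        grid_step = 34.0 / 200
        assert abs(got_C - b) <= grid_step

    def test_noiseless_double_kink_recovered(self):
        curve = _piecewise_curve([22.91, 34.46], [-1500.0, -22000.0, 15000.0], n=220)
        fit = fit_segmented(curve)
        assert fit.n_breakpoints == 2
        got = sorted(1.0 / bp - CELSIUS_OFFSET for bp in fit.breakpoints)
        assert got[0] == pytest.approx(22.91, abs=0.2)
        assert got[1] == pytest.approx(34.46, abs=0.2)

    def test_grid_search_attains_brute_force_minimum(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(40, 90))
            breaks = sorted(rng.uniform(12.0, 34.0, size=2))
            curve = _piecewise_curve(
                breaks, [-2000.0, -15000.0, 12000.0], n=n,
                noise=0.1, seed=int(rng.integers(1 << 30)),
            )
            fit = fit_segmented(curve, max_candidates=10**6)
            for k in (1, 2):
                if k not in fit.model_stats:
                    continue
                oracle = brute_force_segmented_rss(
                    curve.inv_T, curve.log_abs_I, k, min_seg_points=5
                )
                assert fit.model_stats[k]["rss"] == pytest.approx(
                    oracle, rel=1e-9, abs=1e-12
                )

    def test_underdetermined_fit_names_constraint(self):
        curve = _piecewise_curve([], [-5000.0], n=6)
        with pytest.raises(FitError, match="segment"):
            fit_segmented(curve, force_k=2)

    def test_identical_temperatures_rejected(self):
        curve = VantHoffCurve(
            inv_T=np.full(30, 3.4e-3), log_abs_I=np.zeros(30), log_base=math.e
        )
        with pytest.raises(FitError):
            fit_segmented(curve)

    def test_bootstrap_se_available_and_seeded(self):
        curve = _piecewise_curve([25.0], [-1500.0, -20000.0], n=150, noise=0.05, seed=3)
        fit_a = fit_segmented(curve, bootstrap_reps=50, seed=9)
        fit_b = fit_segmented(curve, bootstrap_reps=50, seed=9)
        assert fit_a.breakpoint_se is not None
        np.testing.assert_array_equal(fit_a.breakpoint_se, fit_b.breakpoint_se)
        assert 0 < fit_a.breakpoint_se[0] < 1e-4  # tight kink, small SE in 1/K


class TestQ10Between:
    def _line_fit(self, q10, T_range=(10.0, 30.0)):
        T = np.linspace(*T_range, 100)
        I = 10.0 * q10 ** ((T - T_range[0]) / 10.0)
        curve = VantHoffCurve(
            inv_T=1.0 / (T + CELSIUS_OFFSET), log_abs_I=np.log(I), log_base=math.e
        )
        return fit_segmented(curve, max_breakpoints=0)

    def test_one_decade_doubling(self):
        fit = self._line_fit(2.0, (15.0, 25.0))
        assert q10_between(fit, 15.0, 25.0) == pytest.approx(2.0, rel=1e-3)

    def test_half_decade_doubling_gives_four(self):
        fit = self._line_fit(4.0, (20.0, 25.0))
        assert q10_between(fit, 20.0, 25.0) == pytest.approx(4.0, rel=1e-3)

    def test_orientation_invariant(self):
        # (I2/I1)**(10/(T2-T1)) inverts both ratio and exponent on a swap,
        # so the Q10 between two temperatures is direction-independent
        fit = self._line_fit(2.0, (15.0, 25.0))
        assert q10_between(fit, 25.0, 15.0) == pytest.approx(
            q10_between(fit, 15.0, 25.0), rel=1e-12
        )

    def test_extrapolation_rejected(self):
        fit = self._line_fit(2.0, (15.0, 25.0))
        with pytest.raises(ExtrapolationError):
            q10_between(fit, 10.0, 30.0)

    def test_activation_q10_recovery_within_convention_bound(
        self, noiseless_trpa1b_segment
    ):
        # the 1/T-vs-degC approximation limits noiseless endpoint Q10
        # recovery to ~1e-3 relative over this span
        fit = fit_segmented(to_vanthoff(noiseless_trpa1b_segment))
        bps_C = sorted(1.0 / b - CELSIUS_OFFSET for b in fit.breakpoints)
        q10 = q10_between(fit, bps_C[0], bps_C[1])
        assert q10 == pytest.approx(11.09, rel=0.02)


class TestDeriveMetrics:
    def test_breakpoint_unit_conversion(self):
        # 1/(22.91 + 273.15) K^-1 converts back to 22.91 degC
        assert 1.0 / (1.0 / 296.06) - CELSIUS_OFFSET == pytest.approx(22.91, abs=1e-9)

    def test_distinct_threshold_on_noiseless_trpa1b(self, noiseless_trpa1b_segment):
        seg = noiseless_trpa1b_segment
        m = derive_metrics(fit_segmented(to_vanthoff(seg)), seg)
        assert m.classification == CLASS_DISTINCT
        assert m.threshold_C == pytest.approx(22.91, abs=0.25)
        assert m.second_breakpoint_C == pytest.approx(34.46, abs=0.25)
        assert m.baseline_q10 == pytest.approx(1.59, rel=0.02)
        assert m.activation_q10 == pytest.approx(11.09, rel=0.02)
        assert m.supra_q10 == pytest.approx(3.26, rel=0.02)

    def test_low_q10_flat_fit_is_baseline_only(self):
        T = np.linspace(6.0, 40.0, 200)
        I = 30.0 * 1.3 ** ((T - 6.0) / 10.0)
        seg = _segment(T, -I, onset=5)
        m = derive_metrics(fit_segmented(to_vanthoff(seg)), seg)
        assert m.classification == CLASS_BASELINE
        assert m.threshold_C is None
        assert m.baseline_q10 == pytest.approx(1.3, rel=0.05)

    def test_high_q10_from_cold_hold_is_no_distinct_threshold(self):
        # channels already open at a 2.6 degC hold: steep growth, no kink
        T = np.linspace(2.6, 40.0, 200)
        I = 5.0 * 9.0 ** ((T - 2.6) / 10.0)
        seg = _segment(T, -I, onset=5)
        m = derive_metrics(fit_segmented(to_vanthoff(seg)), seg)
        assert m.classification == CLASS_NO_DISTINCT
        assert m.threshold_C is None
        assert m.activation_q10 is not None and m.activation_q10 > 3.0

    def test_base_invariance_of_all_metrics(self, noiseless_trpa1b_segment):
        seg = noiseless_trpa1b_segment
        m_e = derive_metrics(fit_segmented(to_vanthoff(seg, log_base=math.e)), seg)
        m_10 = derive_metrics(fit_segmented(to_vanthoff(seg, log_base=10.0)), seg)
        assert m_10.threshold_C == pytest.approx(m_e.threshold_C, abs=1e-9)
        assert m_10.second_breakpoint_C == pytest.approx(m_e.second_breakpoint_C, abs=1e-9)
        for a, b in [
            (m_10.baseline_q10, m_e.baseline_q10),
            (m_10.activation_q10, m_e.activation_q10),
            (m_10.supra_q10, m_e.supra_q10),
        ]:
            assert a == pytest.approx(b, rel=1e-10)


class TestRoundTripAndMonotonicity:
    def test_noiseless_roundtrip_matches_oracle_and_truth(self, small_protocol):
        """Pipeline recovery equals the independent grid oracle exactly and
        stays within the 1/T-convention curvature bound of the truth."""
        spec = CellPopulationSpec(
            n_cells=1, channel_params=scenarios.TRPA1B,
            between_cell_cv=0.0, threshold_sd_C=0.0, noise_sd=0.0, seed=0,
        )
        rec = simulate_cell_population(spec, small_protocol)[0].recording
        (seg,) = segment_activations(rec)
        curve = to_vanthoff(seg)
        fit = fit_segmented(curve, max_candidates=10**6)
        # exact agreement with the brute-force oracle on the selected model
        oracle = brute_force_segmented_rss(curve.inv_T, curve.log_abs_I, 2)
        assert fit.model_stats[2]["rss"] == pytest.approx(oracle, rel=1e-9, abs=1e-12)
        # absolute recovery: curvature-limited, far inside the ±1 degC band
        m = derive_metrics(fit, seg)
        p = scenarios.TRPA1B
        assert m.threshold_C == pytest.approx(p.threshold, abs=0.25)
        assert m.second_breakpoint_C == pytest.approx(p.second_breakpoint, abs=0.25)
        assert m.baseline_q10 == pytest.approx(p.q10_baseline, rel=0.02)
        assert m.activation_q10 == pytest.approx(p.q10_activation, rel=0.02)
        assert m.supra_q10 == pytest.approx(p.q10_supra, rel=0.02)

    def test_recovered_q10_increases_with_generator_q10(self, small_protocol):
        recovered = []
        for q10 in (6.0, 11.09, 18.0):
            params = PiecewiseQ10Params(
                i_ref=-25.0, t_ref=6.0, q10_baseline=1.59, threshold=22.91,
                q10_activation=q10, second_breakpoint=34.46, q10_supra=3.26,
            )
            spec = CellPopulationSpec(
                n_cells=1, channel_params=params, noise_sd=0.0, seed=0
            )
            rec = simulate_cell_population(spec, small_protocol)[0].recording
            (seg,) = segment_activations(rec)
            m = derive_metrics(fit_segmented(to_vanthoff(seg)), seg)
            recovered.append(m.activation_q10)
        assert recovered[0] < recovered[1] < recovered[2]


class TestWindowedQ10:
    def _leak_segment(self, leak_q10=1.24, T_range=(1.0, 40.0)):
        T = np.linspace(*T_range, 500)
        I = -30.0 * leak_q10 ** ((T - T_range[0]) / 10.0)
        return _segment(T, I, onset=5)

    def test_leak_only_window_recovers_leak_q10(self):
        seg = self._leak_segment()
        assert windowed_q10(seg, 1.0, 5.0) == pytest.approx(1.24, rel=0.01)

    def test_empty_window_flags_undefined(self):
        seg = self._leak_segment()
        assert windowed_q10(seg, 41.0, 45.0) is None

    def test_subthreshold_window_sees_baseline_not_activation(self, small_protocol):
        from dataclasses import replace

        proto = replace(small_protocol, hold_temp=1.0)
        spec = CellPopulationSpec(
            n_cells=1, channel_params=scenarios.TRPA1B, noise_sd=0.0, seed=0
        )
        rec = simulate_cell_population(spec, proto)[0].recording
        (seg,) = segment_activations(rec)
        q = windowed_q10(seg, 1.0, 5.0)
        assert q == pytest.approx(1.59, rel=0.05)
        assert q < 3.0
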