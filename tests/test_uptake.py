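import numpy as np
import pytest
from dataclasses import replace

from rhizosense.calibration import convert_trace
from rhizosense.config import RunConfig
from rhizosense.signal_processing import estimate_baseline, find_post_addition_peak
from rhizosense.synth import TraceSpec, generate_trace, synthetic_calibration
from rhizosense.trace_io import ExperimentRecord, TimeSeries
from rhizosense.uptake import (
    NormalizedUptake,
    UptakeError,
    UptakeResult,
    compute_uptake,
    find_fit_window,
    fit_power_law,
    normalize_uptake,
    run_batch,
)


def _conc(values, dt=60.0):
    times = np.arange(len(values), dtype=float) * dt
    return TimeSeries(times, values, "concentration")


class TestFitWindow:
    def test_crossing_detected_at_first_sample_within_band(self):
        # decays through baseline*(1+tol): baseline 1.0, tol 0.05 -> band 1.05
        v = [1.0, 1.0, 5.0, 3.0, 1.6, 1.04, 0.9]
        t_end, reached = find_fit_window(_conc(v), t_peak=120.0, baseline=1.0)
        assert reached
        assert t_end == 300.0  # first sample at/below 1.05

    def test_no_crossing_runs_to_end(self):
        v = [1.0, 5.0, 4.0, 3.0, 2.5]
        t_end, reached = find_fit_window(_conc(v), t_peak=60.0, baseline=1.0)
        assert not reached
        assert t_end == 240.0

    def test_default_tolerance_is_five_percent(self):
        import inspect

        sig = inspect.signature(find_fit_window)
        assert sig.parameters["tolerance"].default == 0.05

    def test_peak_at_last_sample_rejected(self):
        v = [1.0, 2.0, 3.0]
        with pytest.raises(UptakeError):
            find_fit_window(_conc(v), t_peak=120.0, baseline=1.0)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        tau = np.arange(1.0, 200.0)
        c = 2.0 * tau ** (-0.3)
        s = TimeSeries(tau + 500.0, c, "concentration")
        b, k, r2 = fit_power_law(s, 501.0, 699.0, t_origin=500.0)
        assert k == pytest.approx(-0.3, abs=1e-12)
        assert b == pytest.approx(2.0, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_equals_closed_form_ols(self):
        rng = np.random.default_rng(3)
        tau = np.arange(1.0, 500.0)
        c = 0.01 * tau ** (-0.4) * np.exp(rng.normal(0, 0.01, tau.size))
        s = TimeSeries(tau, c, "concentration")
        b, k, _ = fit_power_law(s, 1.0, 499.0, t_origin=0.0)
        x, y = np.log10(tau), np.log10(c)
        sx = x - x.mean()
        slope = (sx * (y - y.mean())).sum() / (sx**2).sum()
        intercept = y.mean() - slope * x.mean()
        assert k == pytest.approx(slope, abs=1e-12)
        assert b == pytest.approx(10**intercept, rel=1e-12)

    def test_constant_series_gives_k_zero(self):
        s = _conc([4.0] * 10)
        b, k, r2 = fit_power_law(s, 60.0, 540.0, t_origin=0.0)
        assert k == 0.0
        assert b == 4.0
        assert r2 == 1.0

    def test_scale_equivariance(self):
        tau = np.arange(1.0, 100.0)
        c = 0.5 * tau ** (-0.25)
        s1 = TimeSeries(tau, c, "concentration")
        s2 = TimeSeries(tau, 7.0 * c, "concentration")
        b1, k1, _ = fit_power_law(s1, 1, 99, 0.0)
        b2, k2, _ = fit_power_law(s2, 1, 99, 0.0)
        assert k2 == pytest.approx(k1, abs=1e-12)
        assert b2 == pytest.approx(7.0 * b1, rel=1e-10)

    def test_too_few_samples_rejected(self):
        s = _conc([1.0, 2.0])
        with pytest.raises(UptakeError):
            fit_power_law(s, 0.0, 60.0, t_origin=-1.0)

    def test_nonpositive_concentration_rejected(self):
        s = _conc([1.0, -1.0, 2.0, 3.0])
        with pytest.raises(UptakeError):
            fit_power_law(s, 0.0, 180.0, t_origin=-1.0)

    def test_nonlinear_method_agrees_on_exact_data(self):
        tau = np.arange(1.0, 100.0)
        c = 2.0 * tau ** (-0.3)
        s = TimeSeries(tau, c, "concentration")
        b, k, r2 = fit_power_law(s, 1, 99, 0.0, method="nonlinear")
        assert k == pytest.approx(-0.3, abs=1e-8)
        assert b == pytest.approx(2.0, rel=1e-8)


class TestComputeUptake:
    def test_generator_roundtrip_recovers_k(self, curve):
        spec = TraceSpec("KNO3", curve, k_true=-0.4, noise_sd=0.0, drift_rate=0.0)
        res = compute_uptake(generate_trace(spec), curve)
        assert abs(res.k_uptake - (-0.4)) <= 1e-6
        assert not res.zero_uptake

    def test_non_decreasing_post_addition_is_zero_uptake(self, curve):
        times = np.arange(0.0, 5 * 3600.0, 60.0)
        # impedance falls monotonically -> concentration rises monotonically
        z = 2e4 - 0.5 * times
        rec = ExperimentRecord(
            trace=TimeSeries(times, z, "impedance"),
            salt_name="KNO3",
            addition_time=3 * 3600.0,
        )
        res = compute_uptake(rec, curve)
        assert res.zero_uptake
        assert res.k_uptake == 0.0

    def test_missing_addition_time_rejected(self, curve, impedance_record):
        rec = ExperimentRecord(
            trace=impedance_record.trace, salt_name="KNO3", addition_time=None
        )
        with pytest.raises(UptakeError):
            compute_uptake(rec, curve)

    def test_equals_manual_stage_composition(self, curve):
        """The one-call pipeline has no hidden state beyond its stages."""
        spec = TraceSpec("KNO3", curve, k_true=-0.3, noise_sd=0.004, seed=11)
        rec = generate_trace(spec)
        config = RunConfig()
        res = compute_uptake(rec, curve, config)

        conc, _ = convert_trace(rec.trace, curve)
        from rhizosense.signal_processing import percentile_filter

        baseline = estimate_baseline(conc, config.baseline_window_hours)
        detect = percentile_filter(conc, config.smoothing)
        t_peak, _ = find_post_addition_peak(detect, rec.addition_time, baseline)
        t_end, reached = find_fit_window(detect, t_peak, baseline, config.tolerance)
        b, k, r2 = fit_power_law(conc, t_peak, t_end, rec.addition_time)
        assert res.k_uptake == pytest.approx(k, abs=1e-15)
        assert res.B == pytest.approx(b, rel=1e-15)
        assert res.reached_baseline == reached

    def test_zero_uptake_invariant_enforced(self):
        with pytest.raises(UptakeError):
            UptakeResult(
                B=1.0, k_uptake=-0.1, t_fit_start=None, t_fit_end=None,
                baseline=1.0, reached_baseline=False, zero_uptake=True,
            )


class TestNormalize:
    def _res(self, k):
        return UptakeResult(
            B=1.0, k_uptake=k, t_fit_start=0.0, t_fit_end=1.0, baseline=1.0,
            reached_baseline=False, zero_uptake=False,
        )

    def test_self_normalization(self):
        out = normalize_uptake(-0.05, [self._res(-0.05)])
        assert out.ratio == pytest.approx(1.0)

    def test_regime_example(self):
        out = normalize_uptake(-0.31, [self._res(-0.04), self._res(-0.06)])
        assert out.ratio == pytest.approx(6.2)
        assert out.k_control_mean == pytest.approx(-0.05)

    def test_zero_control_mean_flagged_undefined(self):
        out = normalize_uptake(-0.3, [self._res(0.0), self._res(0.0)])
        assert out.undefined
        assert np.isnan(out.ratio)

    def test_empty_controls_rejected(self):
        with pytest.raises(UptakeError):
            normalize_uptake(-0.3, [])


class TestBatch:
    def test_empty_manifest_rejected(self, curve, tmp_path):
        import pandas as pd

        manifest = pd.DataFrame(columns=["path", "salt_name", "role"])
        with pytest.raises(UptakeError):
            run_batch(manifest, {"KNO3": curve}, base_dir=tmp_path)

    def test_missing_calibration_rejected(self, tmp_path, curve):
        import pandas as pd

        manifest = pd.DataFrame(
            [{"path": "x.csv", "salt_name": "CuSO4", "role": "plant"}]
        )
        with pytest.raises(UptakeError, match="CuSO4"):
            run_batch(manifest, {"KNO3": curve}, base_dir=tmp_path)
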