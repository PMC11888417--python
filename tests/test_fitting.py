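"""Fitting engine: round trips, weighting, confidence bounds, ratios."""

import json

import numpy as np
import pytest

from orgmodel import (
    ORGTrace,
    ResponseParams,
    SimulationConfig,
    TwoFlashParams,
    compare_models,
    eval_two_flash,
    fit_background,
    fit_single_flash,
    fit_two_flash,
    goodness_of_fit,
    ratio_trend,
    response_ratios,
    simulate_background_trace,
    simulate_single_flash_trace,
    simulate_two_flash_trace,
)
from orgmodel.fitting import _weight_vector
from .conftest import EXEMPLAR


class TestSingleFlashFit:
    def test_noiseless_round_trip(self, noiseless_trace):
        fit = fit_single_flash(noiseless_trace)
        assert fit.converged
        expected = EXEMPLAR.as_dict()
        for name, value in expected.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_nm == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_quality(self, exemplar_params):
        """With 10 nm noise the fit should recover the trace up to the
        noise floor: RMS residual near sigma (well under the 22 nm scale
        of real residuals) and R-squared near its analytic ceiling
        1 - sigma^2/Var(signal)."""
        cfg = SimulationConfig(noise_sigma_nm=10.0, seed=3)
        clean = simulate_single_flash_trace(
            exemplar_params, SimulationConfig(noise_sigma_nm=0.0)
        )
        expected_r2 = 1.0 - 100.0 / np.var(clean.dopl)
        fit = fit_single_flash(simulate_single_flash_trace(exemplar_params, cfg))
        assert fit.rms_nm < 22.0
        assert fit.r_squared == pytest.approx(expected_r2, abs=0.02)
        assert fit.r_squared > 0.9

    def test_all_zero_trace_gives_zero_amplitudes(self):
        t = np.arange(1200) / 400.0
        trace = ORGTrace(t, np.zeros_like(t), 400.0, (0.2,))
        fit = fit_single_flash(trace)
        assert fit.params["a1"] == pytest.approx(0.0, abs=1e-9)
        assert fit.flags.get("degenerate_data")

    def test_canonical_orientation_reported(self, noiseless_trace):
        fit = fit_single_flash(noiseless_trace)
        assert fit.params["tau_a"] >= fit.params["tau_b"]
        assert fit.params["a1"] >= 0

    def test_requires_post_onset_samples(self):
        t = np.arange(10) / 400.0
        trace = ORGTrace(t, np.zeros_like(t), 400.0, (0.5,))
        with pytest.raises(ValueError):
            fit_single_flash(trace)

    def test_random_draw_recovery(self):
        """Noiseless 3 s / 400 Hz fits recover 50 random parameter draws."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = ResponseParams(
                rng.uniform(-80, -5), rng.uniform(30, 500),
                rng.uniform(2, 20), rng.uniform(0.02, 0.3),
            )
            trace = simulate_single_flash_trace(p, SimulationConfig(noise_sigma_nm=0.0))
            fit = fit_single_flash(trace)
            expected = p.canonical().as_dict()
            for name, value in expected.items():
                assert fit.params[name] == pytest.approx(value, rel=1e-3)

    def test_ci_coverage(self, exemplar_params):
        """95% linearized intervals cover the generating a0/a1 in >=85%
        of 200 noisy realizations (the intervals are approximate)."""
        hits_a0 = hits_a1 = 0
        n_runs = 200
        for seed in range(n_runs):
            cfg = SimulationConfig(noise_sigma_nm=10.0, seed=seed)
            fit = fit_single_flash(simulate_single_flash_trace(exemplar_params, cfg))
            hits_a0 += fit.ci_low["a0"] <= exemplar_params.a0 <= fit.ci_high["a0"]
            hits_a1 += fit.ci_low["a1"] <= exemplar_params.a1 <= fit.ci_high["a1"]
        assert hits_a0 >= 0.85 * n_runs
        assert hits_a1 >= 0.85 * n_runs

    def test_json_report_schema(self, noiseless_trace):
        fit = fit_single_flash(noiseless_trace)
        report = json.loads(fit.to_json())
        for key in ("model_id", "params", "ci_low", "ci_high", "r_squared",
                    "rms_nm", "rms_late_nm", "converged", "n_points", "flags"):
            assert key in report
        assert set(report["params"]) == set(report["ci_low"]) == set(report["ci_high"])


class TestWeighting:
    def test_weight_factor_scales_window_contribution(self):
        """Multiplying the factor by k multiplies the contraction window's
        squared-error contribution by exactly k."""
        t = np.arange(-0.1, 1.0, 1 / 400)
        resid = np.ones_like(t)
        for k in (1.0, 2.0, 10.0):
            w = _weight_vector(t, [0.0], 10.0 * k, 0.025)
            w_base = _weight_vector(t, [0.0], 10.0, 0.025)
            window = (t >= 0) & (t <= 0.025)
            contrib = np.sum((w * resid)[window] ** 2)
            base = np.sum((w_base * resid)[window] ** 2)
            assert contrib == pytest.approx(k * base, rel=1e-12)
            outside = ~window
            assert np.all(w[outside] == 1.0)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        t = np.linspace(-0.1, 1.0, 100)
        y = np.sin(t)
        r2, rms, rms_late, degen = goodness_of_fit(t, y, y)
        assert r2 == 1.0 and rms == 0.0 and rms_late == 0.0 and not degen

    def test_constant_residual(self):
        t = np.linspace(-0.1, 1.0, 100)
        y = np.sin(t)
        r2, rms, rms_late, _ = goodness_of_fit(t, y, y - 3.0)
        assert rms == pytest.approx(3.0)
        assert rms_late == pytest.approx(3.0)

    def test_known_residual_vector(self):
        t = np.array([-0.1, 0.0, 0.4, 0.6, 0.8])
        y = np.zeros(5)
        resid = np.array([1.0, -2.0, 2.0, 0.0, -1.0])
        _, rms, rms_late, _ = goodness_of_fit(t, resid, y)
        assert rms == pytest.approx(np.sqrt(10.0 / 5.0))
        assert rms_late == pytest.approx(np.sqrt(1.0 / 2.0))

    def test_constant_trace_flagged(self):
        t = np.linspace(0, 1, 10)
        r2, _, _, degen = goodness_of_fit(t, np.full(10, 2.0), np.full(10, 2.0))
        assert degen and np.isnan(r2)


class TestTwoFlashFit:
    def test_noiseless_round_trip(self, exemplar_params):
        trace = simulate_two_flash_trace(
            exemplar_params, 0.3, SimulationConfig(noise_sigma_nm=0.0)
        )
        fit = fit_two_flash(trace, 0.3)
        assert fit.converged
        expected = {
            **{f"{k}_alpha": v for k, v in trace.meta["alpha"].items()},
            **{f"{k}_beta": v for k, v in trace.meta["beta"].items()},
        }
        for name, value in expected.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-2)

    def test_alpha_only_trace_gives_null_beta(self, exemplar_params):
        tf = TwoFlashParams(
            exemplar_params, ResponseParams(0.0, 0.0, 9.5, 0.07), 0.3
        )
        cfg = SimulationConfig(noise_sigma_nm=5.0, seed=7)
        rng = np.random.default_rng(7)
        clean = eval_two_flash(tf, cfg.t - cfg.onset_s)
        trace = ORGTrace(cfg.t, clean + rng.normal(0, 5.0, cfg.t.shape),
                         cfg.fs, (0.2, 0.5))
        fit = fit_two_flash(trace, 0.3)
        for name in ("a0_beta", "a1_beta"):
            assert fit.ci_low[name] <= 0.0 <= fit.ci_high[name]

    def test_rejects_nonpositive_interval(self, noiseless_trace):
        with pytest.raises(ValueError):
            fit_two_flash(noiseless_trace, 0.0)

    def test_attenuation_ratio_recovered_over_seeds(self, exemplar_params):
        """Mean fitted contraction ratio over 100 noisy paired-flash traces
        falls within 2 standard errors of the generating ratio."""
        t_isi = 0.2
        ratios = []
        for seed in range(100):
            cfg = SimulationConfig(noise_sigma_nm=10.0, seed=seed)
            trace = simulate_two_flash_trace(exemplar_params, t_isi, cfg)
            fit = fit_two_flash(trace, t_isi)
            ratios.append(fit.params["a0_beta"] / fit.params["a0_alpha"])
        ratios = np.asarray(ratios)
        generating = min(1.0, 2.3 * t_isi + 0.31)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - generating) <= 2 * se

    def test_reliability_flags_follow_observation_window(self, exemplar_params):
        # 1 s record: beta flash sees < 1 s, so its a1/tau_a are unreliable
        cfg = SimulationConfig(duration_s=1.0, noise_sigma_nm=0.0)
        trace = simulate_two_flash_trace(exemplar_params, 0.3, cfg)
        fit = fit_two_flash(trace, 0.3)
        rel = fit.flags["reliability"]
        assert not rel["a1_beta"] and not rel["tau_a_beta"]
        assert not rel["tau_b_alpha"]  # < 2.85 s
        assert rel["a0_alpha"] and rel["a0_beta"]


class TestBackgroundFit:
    def test_noiseless_round_trip(self, exemplar_params):
        trace = simulate_background_trace(
            exemplar_params, 20.0, SimulationConfig(noise_sigma_nm=0.0)
        )
        fit = fit_background(trace)
        expected = {**exemplar_params.as_dict(), "m": 20.0}
        for name, value in expected.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-3)

    def test_zero_slope_within_ci(self, exemplar_params):
        trace = simulate_background_trace(
            exemplar_params, 0.0, SimulationConfig(noise_sigma_nm=5.0, seed=2)
        )
        fit = fit_background(trace)
        assert fit.ci_low["m"] <= 0.0 <= fit.ci_high["m"]

    def test_pure_ramp_limit(self):
        flash = ResponseParams(0.0, 0.0, 9.5, 0.07)
        trace = simulate_background_trace(
            flash, 12.5, SimulationConfig(noise_sigma_nm=0.0)
        )
        fit = fit_background(trace)
        assert fit.params["m"] == pytest.approx(12.5, abs=1e-6)

    def test_requires_pre_onset_samples(self, exemplar_params):
        cfg = SimulationConfig(onset_s=0.05, noise_sigma_nm=0.0)
        trace = simulate_background_trace(exemplar_params, 5.0, cfg)
        with pytest.raises(ValueError):
            fit_background(trace)


class TestResponseRatios:
    @staticmethod
    def _fake_two_flash_fit(alpha, beta, sig_alpha, sig_beta):
        from orgmodel import FitResult

        names_a = ("a0_alpha", "a1_alpha", "tau_a_alpha", "tau_b_alpha")
        names_b = ("a0_beta", "a1_beta", "tau_a_beta", "tau_b_beta")
        params = {**{n: alpha for n in names_a}, **{n: beta for n in names_b}}
        ci_low = {n: params[n] - 1.96 * (sig_alpha if n in names_a else sig_beta)
                  for n in params}
        ci_high = {n: params[n] + 1.96 * (sig_alpha if n in names_a else sig_beta)
                   for n in params}
        return FitResult(
            model_id="two_flash", params=params, ci_low=ci_low, ci_high=ci_high,
            r_squared=1.0, rms_nm=0.0, rms_late_nm=0.0, weights_applied="",
            converged=True, n_points=100, flags={},
        )

    def test_equal_parameters_with_relative_sigma(self):
        fit = self._fake_two_flash_fit(10.0, 10.0, 1.0, 1.0)
        for est in response_ratios(fit):
            assert est.ratio == pytest.approx(1.0)
            assert est.sigma == pytest.approx(np.sqrt(2) * 0.1, rel=1e-6)

    def test_zero_uncertainty_gives_zero_sigma(self):
        fit = self._fake_two_flash_fit(10.0, 5.0, 0.0, 0.0)
        for est in response_ratios(fit):
            assert est.sigma == 0.0

    def test_zero_alpha_rejected(self):
        fit = self._fake_two_flash_fit(0.0, 5.0, 0.1, 0.1)
        with pytest.raises(ZeroDivisionError):
            response_ratios(fit)

    def test_sigma_matches_monte_carlo(self):
        """Propagated sigma vs sampling oracle, relative sigma <= 0.1."""
        rng = np.random.default_rng(5)
        alpha, beta = -36.4, -20.0
        for rel_sig in (0.02, 0.05, 0.1):
            fit = self._fake_two_flash_fit(
                alpha, beta, abs(alpha) * rel_sig, abs(beta) * rel_sig
            )
            est = response_ratios(fit)[0]
            a = rng.normal(alpha, abs(alpha) * rel_sig, 200_000)
            b = rng.normal(beta, abs(beta) * rel_sig, 200_000)
            empirical = np.std(b / a)
            assert est.sigma == pytest.approx(empirical, rel=0.10)


class TestRatioTrend:
    def test_exact_line(self):
        t = np.array([0.015, 0.1, 0.2, 0.3])
        trend = ratio_trend(t, 2.3 * t + 0.31)
        assert trend.slope == pytest.approx(2.3)
        assert trend.t_unity == pytest.approx(0.3, rel=1e-9)

    def test_constant_ratios_flagged(self):
        trend = ratio_trend([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert trend.slope == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(trend.t_unity)

    def test_identical_intervals_rejected(self):
        with pytest.raises(ValueError):
            ratio_trend([0.1, 0.1], [0.5, 0.6])

    def test_noisy_line_unbiased(self):
        rng = np.random.default_rng(17)
        t = np.array([0.015, 0.1, 0.2, 0.3])
        slopes = [
            ratio_trend(t, 2.3 * t + 0.31 + rng.normal(0, 0.05, 4)).slope
            for _ in range(1000)
        ]
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 2.3) <= 2 * se


@pytest.fixture(scope="module")
def comparison(exemplar_params):
    cfg = SimulationConfig(duration_s=1.2, onset_s=0.2, noise_sigma_nm=0.0)
    trace = simulate_single_flash_trace(exemplar_params, cfg)
    return compare_models(trace)


class TestCompareModels:
    def test_primary_model_beats_elongation_only(self, comparison):
        assert comparison["magenta"].rms_nm < comparison["red"].rms_nm

    def test_magenta_green_near_equivalent(self, comparison):
        assert abs(comparison["magenta"].rms_nm - comparison["green"].rms_nm) < 0.01

    def test_cyan_nests_red(self, comparison):
        assert comparison["cyan"].rms_nm <= comparison["red"].rms_nm + 1e-9

    def test_contraction_free_models_report_late_rms(self, comparison):
        for mid in ("red", "blue", "cyan"):
            assert np.isfinite(comparison[mid].rms_late_nm)
            assert "uniform" in comparison[mid].weights_applied
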