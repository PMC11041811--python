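import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxcal import (
    CalibrationError,
    CalibrationWindowSummary,
    GroundTruth,
    StimulusParadigm,
    aggregate_calibrations,
    calibrate_gammas,
    calibrate_k,
    calibrate_run,
    co2_response_summary,
    estimate_alpha,
    generate_run,
    model1,
    model2,
    model3,
)


def brute_force_closest_gammas(summary, span=4.0, n=4_000_001):
    """Dense parameterization of the unity-constraint line; closest to (1,1)."""
    f, a, b = summary.rcbf_mean, summary.a_mean, summary.b_mean
    if abs(b) > abs(f * a):
        # parameterize by gammaR, solve gammaT = (f(1 + gR a) - 1)/b
        gr = np.linspace(1.0 - span, 1.0 + span, n)
        gt = (f * (1.0 + gr * a) - 1.0) / b
    else:
        gt = np.linspace(1.0 - span, 1.0 + span, n)
        gr = ((1.0 + gt * b) / f - 1.0) / a
    d2 = (gr - 1.0) ** 2 + (gt - 1.0) ** 2
    i = int(np.argmin(d2))
    return float(gr[i]), float(gt[i])


class TestCalibrateGammas:
    def test_orthogonal_projection_example(self):
        s = CalibrationWindowSummary(rcbf_mean=1.25, a_mean=-0.2, b_mean=0.1)
        gr, gt = calibrate_gammas(s)
        assert gr == pytest.approx(0.6551724138, abs=1e-9)
        assert gt == pytest.approx(0.8620689655, abs=1e-9)
        assert model1(s.rcbf_mean, s.a_mean, s.b_mean, gr, gt) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_one_dimensional_solve_when_a_is_zero(self):
        s = CalibrationWindowSummary(rcbf_mean=1.25, a_mean=0.0, b_mean=0.1)
        assert calibrate_gammas(s) == pytest.approx((1.0, 2.5))

    def test_feasible_anchor_is_returned(self):
        # 1.25 * (1 - 0.12) = 1.1 = 1 + 0.1: (1, 1) already satisfies unity
        s = CalibrationWindowSummary(rcbf_mean=1.25, a_mean=-0.12, b_mean=0.1)
        assert calibrate_gammas(s) == pytest.approx((1.0, 1.0), abs=1e-12)

    def test_degenerate_cases(self):
        assert calibrate_gammas(
            CalibrationWindowSummary(rcbf_mean=1.0, a_mean=0.0, b_mean=0.0)
        ) == (1.0, 1.0)
        with pytest.raises(CalibrationError):
            calibrate_gammas(
                CalibrationWindowSummary(rcbf_mean=1.25, a_mean=0.0, b_mean=0.0)
            )

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_dense_line_search(self, seed):
        rng = np.random.default_rng(seed)
        s = CalibrationWindowSummary(
            rcbf_mean=rng.uniform(1.05, 2.2),
            a_mean=rng.uniform(-0.4, -0.02),
            b_mean=rng.uniform(0.02, 0.3),
        )
        exact = calibrate_gammas(s)
        brute = brute_force_closest_gammas(s)
        assert exact == pytest.approx(brute, abs=1e-6)


class TestCalibrateK:
    def test_zero_when_no_flow_change(self):
        s = CalibrationWindowSummary(rcbf_mean=1.0, a_mean=-0.1, b_mean=0.05,
                                     da620_mean=-0.02)
        assert calibrate_k(s, 0.38) == 0.0

    def test_closed_form_value(self):
        s = CalibrationWindowSummary(rcbf_mean=2.0, a_mean=-0.1, b_mean=0.3,
                                     da620_mean=-0.02)
        assert calibrate_k(s, 0.38) == pytest.approx(17.4664536, abs=1e-6)

    def test_roundtrip_forces_unity(self):
        s = CalibrationWindowSummary(rcbf_mean=1.62, a_mean=-0.2, b_mean=0.18,
                                     da620_mean=-0.013)
        k = calibrate_k(s, 0.41)
        assert model3(s.rcbf_mean, s.da620_mean, k, 0.41) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_infeasible_without_signal(self):
        s = CalibrationWindowSummary(rcbf_mean=1.5, a_mean=0.0, b_mean=0.1,
                                     da620_mean=0.0)
        with pytest.raises(CalibrationError):
            calibrate_k(s, 0.38)


class TestEstimateAlpha:
    def test_logarithm_identity(self):
        assert estimate_alpha(2.0, 2.0**0.38) == pytest.approx(0.38, abs=1e-12)

    def test_equal_ratios_give_one(self):
        assert estimate_alpha(1.7, 1.7) == pytest.approx(1.0)

    def test_unit_flow_is_degenerate(self):
        with pytest.raises(CalibrationError):
            estimate_alpha(1.0, 1.2)
        with pytest.raises(Exception):
            estimate_alpha(-1.0, 1.2)


class TestIdentifiability:
    def test_alpha_recovered_from_grubb_coupled_run(self, plateau_run):
        summary = co2_response_summary(plateau_run).to_calibration_summary()
        alpha = estimate_alpha(summary.rcbf_mean, summary.rchbt_mean)
        assert alpha == pytest.approx(plateau_run.truth.alpha_true, abs=1e-9)

    def test_k_recovered_in_model3_forward_mode(self):
        truth = GroundTruth(seed=5, rcbf_peak=1.8, alpha_true=0.38,
                            k_true=14.32, tau_rise_s=2.0)
        run = generate_run(StimulusParadigm.hypercapnia(), truth)
        summary = co2_response_summary(run).to_calibration_summary()
        k = calibrate_k(summary, truth.alpha_true)
        assert k == pytest.approx(14.32, rel=1e-6)


class TestCalibrateRunUnity:
    def test_all_calibrated_models_return_unity_at_own_summary(self, hypercapnia_run):
        summary = co2_response_summary(hypercapnia_run).to_calibration_summary()
        cal = calibrate_run(summary)
        m1 = model1(summary.rcbf_mean, summary.a_mean, summary.b_mean,
                    cal.gamma_r, cal.gamma_t)
        m2 = model2(summary.a_mean, summary.b_mean, cal.gamma_r, cal.gamma_t,
                    cal.alpha)
        m3 = model3(summary.rcbf_mean, summary.da620_mean, cal.k, cal.alpha)
        m3i = model3(summary.rcbf_mean, summary.a_mean, cal.k_ideal, cal.alpha)
        for m in (m1, m2, m3, m3i):
            assert m == pytest.approx(1.0, abs=1e-9)

    def test_model2_calibration_equals_model1(self, hypercapnia_run):
        # with the run's own Grubb exponent, (1+b)^(1/alpha) equals the flow
        # mean exactly, so models 1 and 2 share one gamma calibration
        summary = co2_response_summary(hypercapnia_run).to_calibration_summary()
        cal = calibrate_run(summary)
        grubb_flow = summary.rchbt_mean ** (1.0 / cal.alpha)
        assert grubb_flow == pytest.approx(summary.rcbf_mean, rel=1e-12)


class TestAggregate:
    def _result(self, gr, gt=1.5, alpha=0.38, k=14.0):
        from oxcal import CalibrationResult

        return CalibrationResult(
            gamma_r=gr, gamma_t=gt, alpha=alpha, k=k, k_ideal=k / 10.0
        )

    def test_single_result_is_itself_with_zero_sd(self):
        r = self._result(0.7)
        agg = aggregate_calibrations([r])
        assert agg.gamma_r == r.gamma_r and agg.gamma_r_sd == 0.0
        assert agg.n == 1

    def test_two_results_sample_statistics(self):
        agg = aggregate_calibrations([self._result(0.6), self._result(0.8)])
        assert agg.gamma_r == pytest.approx(0.7)
        assert agg.gamma_r_sd == pytest.approx(np.std([0.6, 0.8], ddof=1))

    def test_mixed_levels_pooled(self):
        runs = [
            dataclasses.replace(self._result(0.73), co2_level="5%"),
            dataclasses.replace(self._result(0.72), co2_level="8%"),
        ]
        agg = aggregate_calibrations(runs)
        assert agg.co2_level == "pooled"
        assert agg.gamma_r == pytest.approx(0.725)

    def test_empty_errors(self):
        with pytest.raises(CalibrationError):
            aggregate_calibrations([])
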