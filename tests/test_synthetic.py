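import numpy as np
import pytest

from oxcal import (
    GroundTruth,
    ImageStackSpec,
    InvalidParadigmError,
    OxcalError,
    StimulusParadigm,
    co2_response_summary,
    generate_cbf_trace,
    generate_image_stack,
    generate_run,
    invert_model1_for_hbr,
    model1,
    read_run,
    write_run,
)


class TestParadigm:
    def test_defaults(self):
        hc = StimulusParadigm.hypercapnia()
        assert (hc.rest_s, hc.stim_s, hc.recovery_s) == (30.0, 90.0, 270.0)
        wh = StimulusParadigm.whisker()
        assert (wh.stim_s, wh.inter_trial_s, wh.n_trials) == (6.0, 36.0, 12)
        assert len(wh.trial_onsets) == 12 and wh.trial_onsets[-1] == 396.0

    def test_invalid_durations(self):
        with pytest.raises(InvalidParadigmError):
            StimulusParadigm.hypercapnia(stim_s=-1.0)
        with pytest.raises(InvalidParadigmError):
            StimulusParadigm("whisker", 10, 6, 30, n_trials=2, inter_trial_s=5)


class TestCbfTrace:
    def test_null_response_is_identically_one(self):
        trace = generate_cbf_trace(
            StimulusParadigm.hypercapnia(), GroundTruth(seed=0, rcbf_peak=1.0)
        )
        assert np.all(trace.values == 1.0)

    @pytest.mark.parametrize("peak", [1.30, 2.1367])
    def test_plateau_mean_reaches_peak(self, peak):
        # 2.1367 is the strong-CO2 group-mean flow increase used as a setting
        trace = generate_cbf_trace(
            StimulusParadigm.hypercapnia(), GroundTruth(seed=0, rcbf_peak=peak)
        )
        # direct analytic evaluation of the stated shape at the window samples
        t = np.arange(60.0, 90.0, 0.1)
        expected = np.mean(1.0 + (peak - 1.0) * (1.0 - np.exp(-t / 10.0)))
        assert trace.window_mean(60.0, 90.0) == pytest.approx(expected, abs=1e-12)
        assert trace.window_mean(60.0, 90.0) == pytest.approx(peak, abs=2e-3 * peak)

    def test_rest_is_exactly_one(self):
        trace = generate_cbf_trace(
            StimulusParadigm.hypercapnia(), GroundTruth(seed=0, rcbf_peak=1.5)
        )
        assert np.all(trace.window_values(-30.0, 0.0) == 1.0)


class TestInvertModel1:
    def test_identity_point(self):
        assert invert_model1_for_hbr(1.0, 1.0, 0.0, 1.0, 1.0) == 0.0

    def test_hand_value(self):
        a = invert_model1_for_hbr(1.0, 1.25, 0.1, 1.0, 1.0)
        assert a == pytest.approx(-0.12, abs=1e-14)
        assert model1(1.25, a, 0.1) == pytest.approx(1.0, abs=1e-14)

    def test_roundtrip_property(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            rcmro2 = rng.uniform(0.8, 1.3)
            rcbf = rng.uniform(0.9, 2.5)
            b = rng.uniform(-0.1, 0.4)
            gr, gt = rng.uniform(0.3, 1.5), rng.uniform(0.5, 2.5)
            a = invert_model1_for_hbr(rcmro2, rcbf, b, gr, gt)
            assert model1(rcbf, a, b, gr, gt) == pytest.approx(rcmro2, rel=1e-13)

    def test_gamma_r_zero_not_invertible(self):
        with pytest.raises(OxcalError):
            invert_model1_for_hbr(1.0, 1.2, 0.1, 0.0, 1.0)


class TestGenerateRun:
    def test_null_experiment(self):
        run = generate_run(
            StimulusParadigm.hypercapnia(),
            GroundTruth(seed=0, rcbf_peak=1.0, rcmro2_peak=1.0),
        )
        assert np.all(run.intensity_580.values == 1000.0)
        assert np.all(run.intensity_620.values == 1000.0)
        assert np.ptp(run.ldf.values) == 0.0

    def test_rates_and_lengths_follow_paradigm(self, hypercapnia_run):
        par = hypercapnia_run.paradigm
        assert hypercapnia_run.ldf.rate_hz == 100.0
        assert hypercapnia_run.intensity_580.rate_hz == 10.0
        assert len(hypercapnia_run.ldf) == int(par.duration_s * 100)
        assert len(hypercapnia_run.intensity_620) == int(par.duration_s * 10)
        assert np.all(hypercapnia_run.intensity_580.values > 0)

    def test_analysis_roundtrip_recovers_generator_internals(self, hypercapnia_run):
        summary = co2_response_summary(hypercapnia_run)
        for name in ("dc_hbr", "dc_hbt"):
            rec = summary.traces[name].values
            true = hypercapnia_run.truth_traces[name].values
            scale = np.abs(true).max()
            assert np.abs(rec - true).max() <= 1e-10 * scale

    def test_conservation_every_sample(self, hypercapnia_run):
        tt = hypercapnia_run.truth_traces
        assert np.all(tt["dc_hbt"].values == tt["dc_hbo"].values + tt["dc_hbr"].values)

    def test_isometabolic_unity_under_true_gammas(self, hypercapnia_run):
        tt = hypercapnia_run.truth_traces
        truth = hypercapnia_run.truth
        bl = hypercapnia_run.baseline
        r = model1(
            tt["rcbf"].values,
            tt["dc_hbr"].values / bl.c_hbr0_um,
            tt["dc_hbt"].values / bl.c_hbt0_um,
            truth.gamma_r_true,
            truth.gamma_t_true,
        )
        assert np.abs(r - 1.0).max() <= 1e-12

    def test_seed_determinism(self):
        par = StimulusParadigm.whisker()
        t = GroundTruth(seed=42, rcbf_peak=1.15, noise_sd=0.01)
        r1, r2 = generate_run(par, t), generate_run(par, t)
        assert np.array_equal(r1.ldf.values, r2.ldf.values)
        assert np.array_equal(r1.intensity_580.values, r2.intensity_580.values)
        r3 = generate_run(par, GroundTruth(seed=43, rcbf_peak=1.15, noise_sd=0.01))
        assert not np.array_equal(r1.ldf.values, r3.ldf.values)

    def test_excessive_noise_rejected(self):
        with pytest.raises(OxcalError, match="noise"):
            generate_run(
                StimulusParadigm.hypercapnia(),
                GroundTruth(seed=3, rcbf_peak=1.3, noise_sd=2.0),
            )


@pytest.fixture(scope="module")
def short_run():
    return generate_run(
        StimulusParadigm.hypercapnia(rest_s=5, stim_s=10, recovery_s=5),
        GroundTruth(seed=3, rcbf_peak=1.3),
    )


class TestImageStack:

    def test_overlapping_masks_rejected(self):
        mask = np.ones((8, 8), dtype=bool)
        with pytest.raises(OxcalError):
            ImageStackSpec(8, 8, mask, mask)

    def test_static_scene_without_nuisances(self):
        run = generate_run(
            StimulusParadigm.hypercapnia(rest_s=5, stim_s=10, recovery_s=5),
            GroundTruth(seed=3, rcbf_peak=1.0),
        )
        res = generate_image_stack(run, ImageStackSpec.default(24, 24))
        assert np.all(res.stack_580 == res.stack_580[0])
        assert np.all(res.shifts == 0.0) and np.all(res.drift == 0.0)

    def test_control_region_carries_drift_exactly(self, short_run):
        spec = ImageStackSpec.default(24, 24, drift_amplitude=0.02)
        res = generate_image_stack(short_run, spec)
        ctrl = res.stack_580[:, spec.control_mask].mean(axis=1)
        expected = res.pattern[spec.control_mask].mean() * (1.0 + res.drift)
        assert np.allclose(ctrl, expected, rtol=1e-12)

    def test_roi_pixels_follow_intensity_ratio(self, short_run):
        spec = ImageStackSpec.default(24, 24)
        res = generate_image_stack(short_run, spec)
        roi = res.stack_580[:, spec.roi_mask].mean(axis=1)
        i = short_run.intensity_580
        ratio = i.values / i.window_mean(short_run.paradigm.t0_s, 0.0)
        assert np.allclose(roi / roi[0], ratio / ratio[0], rtol=1e-10)


def test_write_read_roundtrip(tmp_path, hypercapnia_run):
    out = write_run(hypercapnia_run, tmp_path / "run")
    assert {(p.name) for p in out.iterdir()} >= {
        "ldf.csv", "ois_580.csv", "ois_620.csv", "truth.json", "paradigm.yaml",
    }
    back = read_run(out)
    assert back.paradigm == hypercapnia_run.paradigm
    assert back.truth == hypercapnia_run.truth
    assert np.allclose(back.ldf.values, hypercapnia_run.ldf.values)
    assert back.ldf.rate_hz == 100.0
    assert np.allclose(
        back.intensity_620.values, hypercapnia_run.intensity_620.values
    )
    assert back.intensity_580.t0_s == pytest.approx(-30.0)
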