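"""Experiment-level orchestration.

Turns raw runs into window summaries, evaluates the nine pre-registered
model scenarios (models 1–3 crossed with their calibration cases), builds
percent-error tables against the Model 1-Cal reference, runs paired tests
across animals, and sweeps the assumed baseline hemoglobin conditions.

Scalar rCMRO2 values are obtained by applying each model to window-mean
signal summaries (the same quantities the calibration constrains), so a
calibrated model evaluated on its own calibration run returns exactly 1;
per-sample rCMRO2 traces are available separately via
:func:`scenario_trace`.
"""
from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    CalibrationResult,
    CalibrationWindowSummary,
    aggregate_calibrations,
    calibrate_run,
)
from .exceptions import CalibrationError, OxcalError
from .mbll import absorbance_change, unmix
from .models import SCENARIOS, ModelScenario, model1, model2, model3
from .optics import BaselineConfig, OpticsTable
from .preprocess import downsample_ldf, normalize_to_baseline
from .synthetic import SyntheticRun
from .trace import SampledTrace

__all__ = [
    "RunSummary",
    "co2_response_summary",
    "whisker_trial_summary",
    "evaluate_scenarios",
    "scenario_trace",
    "percent_error",
    "paired_ttest",
    "TTestResult",
    "cohort_scenario_table",
    "baseline_sensitivity_sweep",
]

CO2_BASELINE_WINDOW = (-30.0, 0.0)
CO2_RESPONSE_WINDOW = (60.0, 90.0)
WHISKER_BASELINE_WINDOW = (-5.0, 0.0)
WHISKER_EPOCH = (-5.0, 30.0)
PEAK_WINDOW_S = 2.0
PEAK_SEARCH_PAD_S = 4.0


@dataclasses.dataclass
class RunSummary:
    """Baseline-normalized traces and response-window means for one run."""

    kind: str
    rcbf_mean: float
    a_mean: float
    b_mean: float
    da580_mean: float
    da620_mean: float
    baseline: BaselineConfig
    optics: OpticsTable
    response_window: tuple[float, float]
    traces: dict[str, SampledTrace] = dataclasses.field(default_factory=dict)
    peak_times: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def rchbt_mean(self) -> float:
        return 1.0 + self.b_mean

    def to_calibration_summary(self) -> CalibrationWindowSummary:
        return CalibrationWindowSummary(
            rcbf_mean=self.rcbf_mean,
            a_mean=self.a_mean,
            b_mean=self.b_mean,
            da620_mean=self.da620_mean,
            window=self.response_window,
        )


def _normalized_signals(
    run: SyntheticRun,
    baseline_window: tuple[float, float],
    baseline: BaselineConfig,
    optics: OpticsTable,
) -> dict[str, SampledTrace]:
    """Normalize LDF + intensities, convert to absorbance and unmix."""
    ldf10 = downsample_ldf(run.ldf, target_hz=run.intensity_580.rate_hz)
    rcbf = normalize_to_baseline(ldf10, baseline_window)
    out: dict[str, SampledTrace] = {"rcbf": rcbf}
    das = []
    for name, intensity in (("580", run.intensity_580), ("620", run.intensity_620)):
        i0 = intensity.window_mean(*baseline_window)
        da = absorbance_change(intensity, i0)
        out[f"da{name}"] = da
        das.append(da)
    hemo = unmix(das[0], das[1], optics)
    out["a"] = hemo.dc_hbr.with_values(
        hemo.dc_hbr.values / baseline.c_hbr0_um, units="fraction"
    )
    out["b"] = hemo.dc_hbt.with_values(
        hemo.dc_hbt.values / baseline.c_hbt0_um, units="fraction"
    )
    out["dc_hbo"] = hemo.dc_hbo
    out["dc_hbr"] = hemo.dc_hbr
    out["dc_hbt"] = hemo.dc_hbt
    return out


def co2_response_summary(
    run: SyntheticRun,
    baseline: BaselineConfig | None = None,
    optics: OpticsTable | None = None,
) -> RunSummary:
    """Window summary of a hypercapnia run.

    Signals are normalized by the 30 s pre-onset baseline and averaged over
    the last 30 s of the 90 s stimulation block ([60, 90) s).
    """
    if run.paradigm.kind != "hypercapnia":
        raise OxcalError("co2_response_summary requires a hypercapnia run")
    baseline = baseline or run.baseline
    optics = optics or run.optics
    if run.intensity_580.times()[-1] < CO2_RESPONSE_WINDOW[1] - 1.0 / run.intensity_580.rate_hz:
        raise OxcalError("trace shorter than the hypercapnia paradigm")
    sig = _normalized_signals(run, CO2_BASELINE_WINDOW, baseline, optics)
    w = CO2_RESPONSE_WINDOW
    return RunSummary(
        kind="hypercapnia",
        rcbf_mean=sig["rcbf"].window_mean(*w),
        a_mean=sig["a"].window_mean(*w),
        b_mean=sig["b"].window_mean(*w),
        da580_mean=sig["da580"].window_mean(*w),
        da620_mean=sig["da620"].window_mean(*w),
        baseline=baseline,
        optics=optics,
        response_window=w,
        traces=sig,
    )


def _epoch_average(trace: SampledTrace, onsets: np.ndarray) -> SampledTrace:
    """Trial-average a trace on the common epoch base, each epoch
    normalized by its own pre-onset baseline."""
    pre, post = WHISKER_EPOCH
    rate = trace.rate_hz
    n_epoch = int(round((post - pre) * rate))
    acc = np.zeros(n_epoch)
    for onset in onsets:
        sl = trace.window_indices(onset + pre, onset + post)
        seg = trace.values[sl]
        if len(seg) != n_epoch:
            raise OxcalError("trace too short for a full stimulation epoch")
        base = np.mean(
            trace.values[trace.window_indices(onset + pre, onset)]
        )
        acc += seg / base
    return SampledTrace(acc / len(onsets), rate, pre, units="ratio")


def _peak_window_mean(
    trace: SampledTrace, search: tuple[float, float], ref: float
) -> tuple[float, float]:
    """Mean over the 2 s window centered on the peak |deviation from ref|.

    Ties broken by earliest time. Returns (mean, peak time)."""
    sl = trace.window_indices(*search)
    seg = trace.values[sl]
    i_pk = int(np.argmax(np.abs(seg - ref)))
    t_pk = trace.t0_s + (sl.start + i_pk) / trace.rate_hz
    half = PEAK_WINDOW_S / 2.0
    return trace.window_mean(t_pk - half, t_pk + half), t_pk


def whisker_trial_summary(
    run: SyntheticRun,
    baseline: BaselineConfig | None = None,
    optics: OpticsTable | None = None,
) -> RunSummary:
    """Trial-averaged peak summary of a whisker-stimulation run.

    Trials are epoch-averaged on a common base (5 s pre to 30 s post
    onset), each epoch normalized by its own 5 s pre-onset baseline. For
    each signal the peak of the averaged trace within [0, stim + 4) s is
    located as the largest absolute deviation from baseline and the scalar
    change is the mean over the 2 s window centered there.
    """
    if run.paradigm.kind != "whisker":
        raise OxcalError("whisker_trial_summary requires a whisker run")
    baseline = baseline or run.baseline
    optics = optics or run.optics
    onsets = run.paradigm.trial_onsets

    ldf10 = downsample_ldf(run.ldf, target_hz=run.intensity_580.rate_hz)
    rcbf = _epoch_average(ldf10, onsets)
    i580 = _epoch_average(run.intensity_580, onsets)
    i620 = _epoch_average(run.intensity_620, onsets)
    da580 = absorbance_change(i580, 1.0)
    da620 = absorbance_change(i620, 1.0)
    hemo = unmix(da580, da620, optics)
    a = hemo.dc_hbr.with_values(hemo.dc_hbr.values / baseline.c_hbr0_um, "fraction")
    b = hemo.dc_hbt.with_values(hemo.dc_hbt.values / baseline.c_hbt0_um, "fraction")

    search = (0.0, run.paradigm.stim_s + PEAK_SEARCH_PAD_S)
    means: dict[str, float] = {}
    peaks: dict[str, float] = {}
    for name, trace, ref in (
        ("rcbf", rcbf, 1.0),
        ("a", a, 0.0),
        ("b", b, 0.0),
        ("da580", da580, 0.0),
        ("da620", da620, 0.0),
    ):
        means[name], peaks[name] = _peak_window_mean(trace, search, ref)

    return RunSummary(
        kind="whisker",
        rcbf_mean=means["rcbf"],
        a_mean=means["a"],
        b_mean=means["b"],
        da580_mean=means["da580"],
        da620_mean=means["da620"],
        baseline=baseline,
        optics=optics,
        response_window=search,
        traces={
            "rcbf": rcbf,
            "a": a,
            "b": b,
            "da580": da580,
            "da620": da620,
            "dc_hbo": hemo.dc_hbo,
            "dc_hbr": hemo.dc_hbr,
            "dc_hbt": hemo.dc_hbt,
        },
        peak_times=peaks,
    )


def _resolve_params(
    scenario: ModelScenario,
    calibrations: dict[str, CalibrationResult],
    alpha_policy: str,
) -> dict:
    """Parameter values a scenario uses, from the calibration set."""
    cal = calibrations.get("cal")
    avg = calibrations.get("avg")

    def _need(which: str) -> CalibrationResult:
        res = calibrations.get(which)
        if res is None:
            raise CalibrationError(
                f"scenario {scenario.name} requires a {which!r} calibration"
            )
        return res

    if alpha_policy == "per_run":
        alpha = _need("cal").alpha
    elif alpha_policy == "avg":
        alpha = _need("avg").alpha
    else:
        raise OxcalError(f"unknown alpha_policy {alpha_policy!r}")

    if scenario.model in (1, 2):
        if scenario.case == "Cal":
            src = _need("cal")
            gam = (src.gamma_r, src.gamma_t)
        elif scenario.case == "Avg":
            src = _need("avg")
            gam = (src.gamma_r, src.gamma_t)
        else:  # One
            gam = (1.0, 1.0)
        return {"gamma_r": gam[0], "gamma_t": gam[1], "alpha": alpha}
    # model 3
    if scenario.case == "Cal":
        k = _need("cal").k
    elif scenario.case == "Avg":
        k = _need("avg").k
    else:  # Ideal
        k = _need("cal").k_ideal
    return {"k": k, "alpha": alpha, "x_source": scenario.hbr_signal_source}


def _scenario_rcmro2(
    scenario: ModelScenario, rcbf, a, b, da620, params: dict
):
    if scenario.model == 1:
        return model1(rcbf, a, b, params["gamma_r"], params["gamma_t"])
    if scenario.model == 2:
        return model2(a, b, params["gamma_r"], params["gamma_t"], params["alpha"])
    x = a if params["x_source"] == "rCHbR" else da620
    return model3(rcbf, x, params["k"], params["alpha"])


def evaluate_scenarios(
    summary: RunSummary,
    calibrations: dict[str, CalibrationResult],
    scenarios: Sequence[ModelScenario] = SCENARIOS,
    alpha_policy: str = "per_run",
    reference: str = "1-Cal",
) -> pd.DataFrame:
    """Scalar rCMRO2 per scenario with percent error against the reference.

    Returns a DataFrame with one row per scenario: the rCMRO2 ratio, the
    change in percent (rCMRO2 - 1), and the percent error of that change
    relative to the reference scenario (NaN where the reference change is
    zero, 0 for the reference row itself).
    """
    rows = []
    for sc in scenarios:
        params = _resolve_params(sc, calibrations, alpha_policy)
        r = _scenario_rcmro2(
            sc, summary.rcbf_mean, summary.a_mean, summary.b_mean,
            summary.da620_mean, params,
        )
        rows.append({"scenario": sc.name, "model": sc.model, "case": sc.case,
                     "rcmro2": float(r), "change_pct": 100.0 * (float(r) - 1.0)})
    df = pd.DataFrame(rows).set_index("scenario")
    if reference in df.index:
        ref_change = df.loc[reference, "change_pct"]
        errs = []
        for name, row in df.iterrows():
            if name == reference:
                errs.append(0.0)
            elif ref_change == 0.0:
                errs.append(float("nan"))
            else:
                errs.append(percent_error(row["change_pct"], ref_change))
        df["pct_error_vs_ref"] = errs
    return df


def scenario_trace(
    summary: RunSummary,
    scenario: ModelScenario,
    calibrations: dict[str, CalibrationResult],
    alpha_policy: str = "per_run",
) -> SampledTrace:
    """Per-sample rCMRO2 trace for one scenario (for plots and inspection)."""
    params = _resolve_params(scenario, calibrations, alpha_policy)
    tr = summary.traces
    vals = _scenario_rcmro2(
        scenario,
        tr["rcbf"].values,
        tr["a"].values,
        tr["b"].values,
        tr["da620"].values,
        params,
    )
    return tr["rcbf"].with_values(vals, units="ratio")


def percent_error(change_model: float, change_ref: float) -> float:
    """Percent error of a change (rCMRO2 - 1) against a reference change."""
    if change_ref == 0.0:
        raise OxcalError("percent error undefined for a zero reference change")
    return 100.0 * abs(change_model - change_ref) / abs(change_ref)


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on matched samples.

    All-zero differences return (t=0, p=1) by convention; zero-variance
    nonzero-mean differences are flagged degenerate (infinite statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise OxcalError("paired test needs two equal-length vectors of length >= 2")
    d = x - y
    if np.all(d == 0.0):
        return TTestResult(0.0, 1.0)
    if np.std(d, ddof=1) == 0.0:
        return TTestResult(math.copysign(math.inf, float(np.mean(d))), 0.0, True)
    res = stats.ttest_rel(x, y)
    return TTestResult(float(res.statistic), float(res.pvalue))


def _summarize_run(
    run: SyntheticRun,
    baseline: BaselineConfig | None,
    optics: OpticsTable | None,
) -> RunSummary:
    if run.paradigm.kind == "hypercapnia":
        return co2_response_summary(run, baseline, optics)
    return whisker_trial_summary(run, baseline, optics)


def cohort_scenario_table(
    calib_runs: Sequence[SyntheticRun],
    stim_runs: Sequence[SyntheticRun],
    baseline: BaselineConfig | None = None,
    optics: OpticsTable | None = None,
    alpha_policy: str = "per_run",
    scenarios: Sequence[ModelScenario] = SCENARIOS,
    reference: str = "1-Cal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal scenario evaluation and the across-animal summary table.

    ``calib_runs[i]`` is animal i's hypercapnia run and ``stim_runs[i]``
    its stimulation run. The average calibration pools all animals. Returns
    ``(per_animal, table)``: per-animal rows of rCMRO2 change, and the
    across-animal table of mean change, mean +/- sd percent error versus
    the reference, and paired t-test statistics.
    """
    if len(calib_runs) != len(stim_runs):
        raise OxcalError("need one calibration run per stimulation run")
    cals = [
        calibrate_run(
            _summarize_run(r, baseline, optics).to_calibration_summary(),
            source=f"animal{i}",
        )
        for i, r in enumerate(calib_runs)
    ]
    avg = aggregate_calibrations(cals)
    per_rows = []
    for i, run in enumerate(stim_runs):
        summ = _summarize_run(run, baseline, optics)
        df = evaluate_scenarios(
            summ, {"cal": cals[i], "avg": avg}, scenarios, alpha_policy, reference
        )
        for name, row in df.iterrows():
            per_rows.append(
                {
                    "animal": i,
                    "scenario": name,
                    "rcmro2": row["rcmro2"],
                    "change_pct": row["change_pct"],
                    "pct_error_vs_ref": row.get("pct_error_vs_ref", float("nan")),
                }
            )
    per_animal = pd.DataFrame(per_rows)

    ref_changes = per_animal[per_animal.scenario == reference].set_index("animal")[
        "change_pct"
    ]
    table_rows = []
    for sc in scenarios:
        sub = per_animal[per_animal.scenario == sc.name].set_index("animal")
        err_mean = float(sub["pct_error_vs_ref"].mean())
        err_sd = (
            float(sub["pct_error_vs_ref"].std(ddof=1)) if len(sub) > 1 else 0.0
        )
        if sc.name == reference or len(sub) < 2:
            t = p = float("nan")
        else:
            t, p, _ = paired_ttest(sub["change_pct"], ref_changes.loc[sub.index])
        table_rows.append(
            {
                "scenario": sc.name,
                "change_pct_mean": float(sub["change_pct"].mean()),
                "change_pct_sd": float(sub["change_pct"].std(ddof=1))
                if len(sub) > 1
                else 0.0,
                "pct_error_mean": err_mean,
                "pct_error_sd": err_sd,
                "t": t,
                "p": p,
            }
        )
    return per_animal, pd.DataFrame(table_rows).set_index("scenario")


def baseline_sensitivity_sweep(
    calib_runs: Sequence[SyntheticRun],
    stim_runs: Sequence[SyntheticRun],
    chbt0_list: Sequence[float],
    s0_list: Sequence[float],
    optics: OpticsTable | None = None,
    alpha_policy: str = "per_run",
    scenarios: Sequence[ModelScenario] = SCENARIOS,
) -> pd.DataFrame:
    """Re-run calibration + scenario evaluation over a baseline grid.

    For every (C_HbT0, S0) pair the calibration coefficients are recomputed
    on the hypercapnia runs and all scenarios re-evaluated on the stimulus
    runs. Returns a tidy frame with the across-animal mean rCMRO2 change
    per scenario and baseline setting.
    """
    if not chbt0_list or not s0_list:
        raise OxcalError("baseline grids must be nonempty")
    rows = []
    for chbt0 in chbt0_list:
        for s0 in s0_list:
            bl = BaselineConfig(c_hbt0_um=chbt0, s0=s0)
            _, table = cohort_scenario_table(
                calib_runs, stim_runs, bl, optics, alpha_policy, scenarios
            )
            for name, row in table.iterrows():
                rows.append(
                    {
                        "c_hbt0_um": chbt0,
                        "s0": s0,
                        "scenario": name,
                        "change_pct_mean": row["change_pct_mean"],
                        "pct_error_mean": row["pct_error_mean"],
                    }
                )
    return pd.DataFrame(rows)
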