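"""Hypercapnia-based model calibration.

Mild hypercapnia raises cerebral blood flow without changing oxygen
metabolism, so an isometabolic run pins rCMRO2 = 1 over its response
window. That single constraint per run determines:

* (γR, γT) for models 1–2 — one linear constraint in the (γR, γT) plane,
  resolved by taking the point on the constraint line closest to (1, 1);
* k for model 3 — the unique value making ``rcbf^(1-α)(1 + k x) = 1``;
* the Grubb exponent α from paired flow/total-hemoglobin window means,
  ``α = ln(rC_HbT) / ln(rCBF)``.

Calibrations from several runs/animals are aggregated by arithmetic mean
with the sample standard deviation recorded.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .exceptions import CalibrationError, OxcalError

__all__ = [
    "CalibrationWindowSummary",
    "CalibrationResult",
    "calibrate_gammas",
    "calibrate_k",
    "calibrate_run",
    "estimate_alpha",
    "aggregate_calibrations",
]


@dataclasses.dataclass(frozen=True)
class CalibrationWindowSummary:
    """Window means of the signals entering calibration.

    ``a_mean``/``b_mean`` are mean fractional deoxy/total hemoglobin
    changes, ``da620_mean`` the mean 620 nm absorbance change over the same
    window (the last 30 s of stimulation by default).
    """

    rcbf_mean: float
    a_mean: float
    b_mean: float
    da620_mean: float = float("nan")
    window: tuple[float, float] = (60.0, 90.0)

    def __post_init__(self) -> None:
        for name in ("rcbf_mean", "a_mean", "b_mean"):
            if not math.isfinite(getattr(self, name)):
                raise OxcalError(f"{name} must be finite")
        if not self.rcbf_mean > 0:
            raise OxcalError("rcbf_mean must be positive")

    @property
    def rchbt_mean(self) -> float:
        return 1.0 + self.b_mean


@dataclasses.dataclass
class CalibrationResult:
    """Calibrated coefficients from one run (or an aggregate of runs).

    ``k`` is calibrated against the 620 nm absorbance change and
    ``k_ideal`` against the true deoxy-hemoglobin ratio signal
    ``rC_HbR - 1``. Standard deviations are zero for single runs and the
    sample (n-1) values for aggregates.
    """

    gamma_r: float
    gamma_t: float
    alpha: float
    k: float = float("nan")
    k_ideal: float = float("nan")
    source: str = ""
    co2_level: str = ""
    n: int = 1
    gamma_r_sd: float = 0.0
    gamma_t_sd: float = 0.0
    alpha_sd: float = 0.0
    k_sd: float = 0.0
    k_ideal_sd: float = 0.0


def calibrate_gammas(summary: CalibrationWindowSummary) -> tuple[float, float]:
    """Solve for (γR, γT) enforcing rCMRO2 = 1 at the window means.

    The isometabolic condition ``rcbf (1 + γR a) = 1 + γT b`` is one linear
    constraint, a line in (γR, γT) space; the solution returned is its
    orthogonal (Euclidean) projection of the anchor point (1, 1), i.e. the
    feasible pair closest to the naive single-compartment values.
    """
    f, a, b = summary.rcbf_mean, summary.a_mean, summary.b_mean
    # constraint: (f*a) γR - b γT = 1 - f
    u = np.array([f * a, -b])
    c = 1.0 - f
    nn = float(u @ u)
    if nn == 0.0:
        if math.isclose(f, 1.0, rel_tol=0.0, abs_tol=1e-12):
            return 1.0, 1.0
        raise CalibrationError(
            "no hemoglobin change in calibration window but rCBF != 1; "
            "the unity constraint is infeasible"
        )
    anchor = np.array([1.0, 1.0])
    gam = anchor + u * ((c - float(u @ anchor)) / nn)
    gamma_r, gamma_t = float(gam[0]), float(gam[1])
    if gamma_r < 0 or gamma_t < 0 or gamma_r > 1.5 or gamma_t > 3.0:
        warnings.warn(
            f"calibrated gammas ({gamma_r:.3g}, {gamma_t:.3g}) fall outside the "
            "usual physiological range; reported as-is",
            stacklevel=2,
        )
    return gamma_r, gamma_t


def calibrate_k(summary: CalibrationWindowSummary, alpha: float, x_mean: float | None = None) -> float:
    """Calibration coefficient k forcing ``rcbf^(1-α)(1 + k x) = 1``.

    ``x_mean`` defaults to the summary's 620 nm absorbance-change mean;
    pass ``a_mean`` for the ideal deoxy-ratio variant. Closed form:
    ``k = (rcbf^(α-1) - 1) / x``.
    """
    if x_mean is None:
        x_mean = summary.da620_mean
    if not math.isfinite(x_mean):
        raise CalibrationError("x_mean is not finite; no 620 nm summary available?")
    f = summary.rcbf_mean
    if x_mean == 0.0:
        if math.isclose(f, 1.0, rel_tol=0.0, abs_tol=1e-12):
            return 0.0
        raise CalibrationError("zero HbR-change signal but rCBF != 1; k is infeasible")
    return (f ** (alpha - 1.0) - 1.0) / x_mean


def estimate_alpha(rcbf_mean: float, rchbt_mean: float) -> float:
    """Grubb exponent ``α = ln(rC_HbT)/ln(rCBF)`` from paired window means."""
    if not (rcbf_mean > 0 and rchbt_mean > 0):
        raise OxcalError("flow and total-hemoglobin ratios must be positive")
    if math.isclose(rcbf_mean, 1.0, rel_tol=0.0, abs_tol=1e-12):
        raise CalibrationError("rCBF = 1: Grubb exponent is undefined")
    return math.log(rchbt_mean) / math.log(rcbf_mean)


def calibrate_run(
    summary: CalibrationWindowSummary,
    alpha: float | None = None,
    source: str = "",
    co2_level: str = "",
) -> CalibrationResult:
    """Full per-run calibration: γ pair, Grubb exponent, and both k variants.

    ``alpha`` overrides the run's own Grubb estimate (e.g. with a
    cross-animal mean) for the model-3 calibration.
    """
    gamma_r, gamma_t = calibrate_gammas(summary)
    alpha_run = estimate_alpha(summary.rcbf_mean, summary.rchbt_mean)
    alpha_used = alpha_run if alpha is None else alpha
    k = calibrate_k(summary, alpha_used)
    k_ideal = calibrate_k(summary, alpha_used, x_mean=summary.a_mean)
    return CalibrationResult(
        gamma_r=gamma_r,
        gamma_t=gamma_t,
        alpha=alpha_run,
        k=k,
        k_ideal=k_ideal,
        source=source,
        co2_level=co2_level,
    )


def aggregate_calibrations(results: list[CalibrationResult]) -> CalibrationResult:
    """Arithmetic mean of coefficients across runs (pooled over CO2 levels).

    Standard deviations use the sample (n-1) formula; a single run yields
    sd 0.
    """
    if not results:
        raise CalibrationError("cannot aggregate an empty list of calibrations")

    def _stats(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(r, attr) for r in results], dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return mean, sd

    gr, gr_sd = _stats("gamma_r")
    gt, gt_sd = _stats("gamma_t")
    al, al_sd = _stats("alpha")
    k, k_sd = _stats("k")
    ki, ki_sd = _stats("k_ideal")
    return CalibrationResult(
        gamma_r=gr,
        gamma_t=gt,
        alpha=al,
        k=k,
        k_ideal=ki,
        source="aggregate",
        co2_level="pooled",
        n=len(results),
        gamma_r_sd=gr_sd,
        gamma_t_sd=gt_sd,
        alpha_sd=al_sd,
        k_sd=k_sd,
        k_ideal_sd=ki_sd,
    )
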