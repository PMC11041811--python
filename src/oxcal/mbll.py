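"""Modified Beer–Lambert conversion between intensities and hemoglobin changes.

Absorbance changes are natural-log: ``dA(t) = -ln(I(t)/I0)``. The
two-wavelength system is solved independently per sample; total hemoglobin
is the sum of the oxy and deoxy components at every sample by construction.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import OxcalError, UnmixingError
from .optics import MAX_CONDITION_NUMBER, BaselineConfig, OpticsTable
from .trace import SampledTrace

__all__ = [
    "HemoTimeCourse",
    "absorbance_change",
    "baseline_concentrations",
    "forward_absorbance",
    "unmix",
]


@dataclasses.dataclass
class HemoTimeCourse:
    """Hemoglobin concentration-change traces (μM) with their absorbances."""

    dc_hbo: SampledTrace
    dc_hbr: SampledTrace
    dc_hbt: SampledTrace
    da: dict[float, SampledTrace]


def absorbance_change(intensity: SampledTrace, i0: float) -> SampledTrace:
    """Absorbance change ``-ln(I(t)/I0)`` of an intensity trace.

    Parameters
    ----------
    intensity : SampledTrace
        Strictly positive intensity trace.
    i0 : float
        Baseline intensity (same units), typically the baseline-window mean.
    """
    if not i0 > 0:
        raise OxcalError(f"baseline intensity must be positive, got {i0}")
    if np.any(intensity.values <= 0):
        raise OxcalError("intensity trace contains non-positive samples")
    return intensity.with_values(-np.log(intensity.values / i0), units="dA")


def baseline_concentrations(baseline: BaselineConfig) -> tuple[float, float]:
    """Baseline (C_HbO0, C_HbR0) in μM from total hemoglobin and saturation."""
    return baseline.c_hbo0_um, baseline.c_hbr0_um


def forward_absorbance(
    dc_hbo: np.ndarray, dc_hbr: np.ndarray, optics: OpticsTable
) -> tuple[np.ndarray, np.ndarray]:
    """Absorbance changes at both wavelengths from concentration changes (μM)."""
    m = optics.matrix
    dc_hbo = np.asarray(dc_hbo, dtype=float)
    dc_hbr = np.asarray(dc_hbr, dtype=float)
    da1 = m[0, 0] * dc_hbo + m[0, 1] * dc_hbr
    da2 = m[1, 0] * dc_hbo + m[1, 1] * dc_hbr
    return da1, da2


def unmix(
    da_1: SampledTrace, da_2: SampledTrace, optics: OpticsTable
) -> HemoTimeCourse:
    """Solve the two-wavelength system per sample for (ΔC_HbO, ΔC_HbR).

    ``da_1``/``da_2`` are the absorbance-change traces at the first and
    second wavelength of ``optics`` (580 and 620 nm by default). Raises
    :class:`UnmixingError` if the spectral matrix is ill-conditioned.
    """
    if len(da_1) != len(da_2):
        raise OxcalError("absorbance traces must have equal length")
    if da_1.rate_hz != da_2.rate_hz or da_1.t0_s != da_2.t0_s:
        raise OxcalError("absorbance traces must share a common clock")
    m = optics.matrix
    if np.linalg.cond(m) > MAX_CONDITION_NUMBER:
        raise UnmixingError("spectral matrix is singular or ill-conditioned")
    sol = np.linalg.solve(m, np.vstack([da_1.values, da_2.values]))
    dc_hbo = da_1.with_values(sol[0], units="uM")
    dc_hbr = da_1.with_values(sol[1], units="uM")
    dc_hbt = da_1.with_values(sol[0] + sol[1], units="uM")
    return HemoTimeCourse(
        dc_hbo=dc_hbo,
        dc_hbr=dc_hbr,
        dc_hbt=dc_hbt,
        da={optics.wavelengths[0]: da_1, optics.wavelengths[1]: da_2},
    )
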