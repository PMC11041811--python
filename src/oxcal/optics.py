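"""Optical constants and baseline physiology.

The two-wavelength spectral system maps hemoglobin concentration changes
(μM) to absorbance changes (natural log) through per-wavelength molar
extinction coefficients and differential pathlength factors::

    dA(λ) = eps_HbO(λ) D(λ) dC_HbO + eps_HbR(λ) D(λ) dC_HbR

Default extinction coefficients come from the standard compiled hemoglobin
absorption tables (molar, base-10, 1/(cm·M)), converted here to natural-log
units of 1/(μM·mm). Pathlength factors are representative literature-scale
values for green/red reflectance imaging of cortex; with them a ~30% flow
increase produces roughly a -4% change at 580 nm and +1.3% at 620 nm.
Downstream analysis is calibrated or round-trip based, so results never
hinge on these particular constants; users can supply their own table.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .exceptions import OxcalError, UnmixingError

__all__ = ["OpticsTable", "BaselineConfig", "DEFAULT_OPTICS", "DEFAULT_BASELINE"]

_LN10 = math.log(10.0)
# 1/(cm·M) -> 1/(mm·μM)
_CM_M_TO_MM_UM = 1e-7

# base-10 molar extinction, 1/(cm·M)
_EPS10_HBO = {580.0: 50104.0, 620.0: 942.0}
_EPS10_HBR = {580.0: 37020.0, 620.0: 6509.6}
# differential pathlength factors, mm
_DPF_MM = {580.0: 0.1, 620.0: 1.5}

MAX_CONDITION_NUMBER = 1e8


@dataclasses.dataclass(frozen=True)
class OpticsTable:
    """Per-wavelength extinction coefficients and pathlength factors.

    ``eps_hbo``/``eps_hbr`` are natural-log extinction coefficients in
    1/(μM·mm) and ``dpf_mm`` the pathlength factors in mm, all keyed by the
    two wavelengths in nm. Set ``log10=True`` if the supplied extinction
    values are base-10; they are converted on construction.
    """

    wavelengths: tuple[float, float] = (580.0, 620.0)
    eps_hbo: tuple[float, float] = (
        _EPS10_HBO[580.0] * _LN10 * _CM_M_TO_MM_UM,
        _EPS10_HBO[620.0] * _LN10 * _CM_M_TO_MM_UM,
    )
    eps_hbr: tuple[float, float] = (
        _EPS10_HBR[580.0] * _LN10 * _CM_M_TO_MM_UM,
        _EPS10_HBR[620.0] * _LN10 * _CM_M_TO_MM_UM,
    )
    dpf_mm: tuple[float, float] = (_DPF_MM[580.0], _DPF_MM[620.0])
    log10: bool = False

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise OxcalError("exactly two wavelengths are required")
        if self.log10:
            object.__setattr__(self, "eps_hbo", tuple(e * _LN10 for e in self.eps_hbo))
            object.__setattr__(self, "eps_hbr", tuple(e * _LN10 for e in self.eps_hbr))
            object.__setattr__(self, "log10", False)
        if self.condition_number() > MAX_CONDITION_NUMBER:
            raise UnmixingError(
                f"spectral matrix is ill-conditioned (cond={self.condition_number():.3g})"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 system matrix; row per wavelength, columns (HbO, HbR)."""
        return np.array(
            [
                [self.eps_hbo[i] * self.dpf_mm[i], self.eps_hbr[i] * self.dpf_mm[i]]
                for i in range(2)
            ]
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def scaled_pathlengths(self, factor: float) -> "OpticsTable":
        """Copy with all pathlength factors multiplied by ``factor``."""
        return dataclasses.replace(
            self, dpf_mm=tuple(d * factor for d in self.dpf_mm)
        )


@dataclasses.dataclass(frozen=True)
class BaselineConfig:
    """Baseline total hemoglobin concentration and oxygen saturation.

    Defaults are 280 μM total hemoglobin at 75% oxygen saturation; the
    compartment baselines follow as ``C_HbO0 = S0*C_HbT0`` and
    ``C_HbR0 = (1-S0)*C_HbT0``.
    """

    c_hbt0_um: float = 280.0
    s0: float = 0.75

    def __post_init__(self) -> None:
        if not self.c_hbt0_um > 0:
            raise OxcalError(f"C_HbT0 must be positive, got {self.c_hbt0_um}")
        if not 0.0 < self.s0 < 1.0:
            raise OxcalError(f"S0 must lie in (0, 1), got {self.s0}")

    @property
    def c_hbo0_um(self) -> float:
        return self.s0 * self.c_hbt0_um

    @property
    def c_hbr0_um(self) -> float:
        return (1.0 - self.s0) * self.c_hbt0_um


DEFAULT_OPTICS = OpticsTable()
DEFAULT_BASELINE = BaselineConfig()
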