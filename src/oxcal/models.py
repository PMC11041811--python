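"""Relative oxygen-metabolism models.

All models compute rCMRO2, the metabolic rate of oxygen consumption as a
ratio to the pre-stimulus baseline, from steady-state Fick's law
``rCMRO2 = rCBF · rOEF``. Inputs are the fractional hemoglobin changes

* ``a = ΔC_HbR / C_HbR0`` (deoxy-hemoglobin),
* ``b = ΔC_HbT / C_HbT0`` (total hemoglobin),

and the flow ratio ``rcbf``. Three families trade measurements for
assumptions:

* Model 1 (two wavelengths + flow):  ``rcbf (1 + γR a) / (1 + γT b)``
* Model 2 (two wavelengths only):    flow replaced by the Grubb estimate
  ``(1 + b)^(1/α)``
* Model 3 (one wavelength + flow):   ``rcbf^(1-α) (1 + k x)`` where x is a
  deoxy-hemoglobin-change surrogate (the 620 nm absorbance change, or
  ``rC_HbR - 1`` in the ideal case) and k a calibration coefficient.

γR and γT weight the measured changes by the venous volume fraction they
occupy; they are 1 in the naive single-compartment model. Every function
accepts scalars or numpy arrays and evaluates per sample.
"""
from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .exceptions import NonPhysicalStateError, OxcalError

__all__ = ["ModelScenario", "SCENARIOS", "roef", "model1", "model2", "model3"]


def _check_positive(x, name: str) -> None:
    if np.any(np.asarray(x) <= 0):
        raise NonPhysicalStateError(f"{name} must be positive everywhere")


def roef(a, b):
    """Relative oxygen extraction fraction ``(1 + a) / (1 + b)``.

    Follows from OEF = C_HbR/C_HbT with a, b the fractional changes of the
    deoxy and total hemoglobin concentrations.
    """
    denom = 1.0 + np.asarray(b, dtype=float)
    _check_positive(denom, "1 + dC_HbT/C_HbT0")
    out = (1.0 + np.asarray(a, dtype=float)) / denom
    return out if out.ndim else float(out)


def model1(rcbf, a, b, gamma_r: float = 1.0, gamma_t: float = 1.0):
    """rCMRO2 from measured flow and both hemoglobin changes.

    ``rcbf (1 + γR a) / (1 + γT b)``; with γR = γT = 1 this is exactly
    flow times relative oxygen extraction.
    """
    _check_positive(rcbf, "rcbf")
    denom = 1.0 + gamma_t * np.asarray(b, dtype=float)
    _check_positive(denom, "1 + gammaT*b")
    out = np.asarray(rcbf, dtype=float) * (1.0 + gamma_r * np.asarray(a, dtype=float)) / denom
    return out if out.ndim else float(out)


def model2(a, b, gamma_r: float = 1.0, gamma_t: float = 1.0, alpha: float = 0.38):
    """rCMRO2 without flow: Grubb-estimated flow ``(1+b)^(1/α)`` times rOEF."""
    if alpha <= 0.0:
        raise OxcalError(f"alpha must be positive, got {alpha}")
    one_plus_b = 1.0 + np.asarray(b, dtype=float)
    _check_positive(one_plus_b, "1 + b")
    return model1(one_plus_b ** (1.0 / alpha), a, b, gamma_r, gamma_t)


def model3(rcbf, x, k: float, alpha: float = 0.38):
    """Single-wavelength rCMRO2: ``rcbf^(1-α) (1 + k x)``.

    ``x`` is the deoxy-hemoglobin-change signal: the 620 nm absorbance
    change in the measured variant, or ``rC_HbR - 1`` in the ideal variant.
    ``k`` absorbs baseline deoxy-hemoglobin concentration, compartment
    weighting and the absorbance-to-concentration scale.
    """
    _check_positive(rcbf, "rcbf")
    out = np.asarray(rcbf, dtype=float) ** (1.0 - alpha) * (
        1.0 + k * np.asarray(x, dtype=float)
    )
    return out if out.ndim else float(out)


Case = Literal["Cal", "Avg", "One", "Ideal"]


@dataclasses.dataclass(frozen=True)
class ModelScenario:
    """A (model, parameter-case) combination.

    ``case`` selects where parameters come from: per-run calibration
    (``Cal``), the cross-animal average (``Avg``), fixed γ = (1, 1)
    (``One``), or, for model 3, the true deoxy-hemoglobin ratio instead of
    the 620 nm surrogate (``Ideal``).
    """

    model: int
    case: Case

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise OxcalError(f"unknown model {self.model}")
        if self.case not in ("Cal", "Avg", "One", "Ideal"):
            raise OxcalError(f"unknown case {self.case}")
        if self.case == "One" and self.model == 3:
            raise OxcalError("case 'One' applies to models 1 and 2 only")
        if self.case == "Ideal" and self.model != 3:
            raise OxcalError("case 'Ideal' applies to model 3 only")

    @property
    def hbr_signal_source(self) -> str:
        """Which deoxy-hemoglobin signal model 3 consumes."""
        return "rCHbR" if self.case == "Ideal" else "dA620"

    @property
    def name(self) -> str:
        label = {"Cal": "Cal", "Avg": "Avg", "One": "1", "Ideal": "Ideal"}[self.case]
        return f"{self.model}-{label}"


#: The nine pre-registered scenarios, reference first.
SCENARIOS: tuple[ModelScenario, ...] = (
    ModelScenario(1, "Cal"),
    ModelScenario(1, "Avg"),
    ModelScenario(1, "One"),
    ModelScenario(2, "Cal"),
    ModelScenario(2, "Avg"),
    ModelScenario(2, "One"),
    ModelScenario(3, "Cal"),
    ModelScenario(3, "Avg"),
    ModelScenario(3, "Ideal"),
)
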