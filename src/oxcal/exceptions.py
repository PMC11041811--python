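"""Exception hierarchy for oxcal."""


class OxcalError(ValueError):
    """Base class for all oxcal errors."""


class InvalidParadigmError(OxcalError):
    """Stimulus paradigm with non-positive durations or inconsistent fields."""


class NonPhysicalStateError(OxcalError):
    """A model denominator or ratio left its physically meaningful domain."""


class CalibrationError(OxcalError):
    """Calibration is infeasible for the given window summary."""


class RegistrationError(OxcalError):
    """Image registration is undefined (e.g. zero-variance frame)."""


class UnmixingError(OxcalError):
    """The spectral system is singular or ill-conditioned."""
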