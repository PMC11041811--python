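"""Uniformly sampled scalar time series.

Time is referenced to stimulus onset: ``t = 0`` is the first stimulus
sample, so baseline windows have negative start times. All windows are
half-open ``[t_start, t_end)``.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import OxcalError

__all__ = ["SampledTrace"]

# slack (in samples) when mapping window times to indices, so that a window
# edge landing exactly on a sample is classified deterministically
_EDGE_EPS = 1e-9


@dataclasses.dataclass
class SampledTrace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : array-like
        Sample values.
    rate_hz : float
        Sampling rate in samples/second; must be positive.
    t0_s : float
        Time of the first sample relative to stimulus onset (seconds).
    units : str
        Free-text unit label (e.g. ``"counts"``, ``"ratio"``, ``"uM"``).
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise OxcalError("trace values must be one-dimensional")
        if not self.rate_hz > 0:
            raise OxcalError(f"rate_hz must be positive, got {self.rate_hz}")
        if not np.all(np.isfinite(self.values)):
            raise OxcalError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SampledTrace":
        """Copy of this trace with new values (same clock)."""
        return SampledTrace(
            np.asarray(values, dtype=float),
            self.rate_hz,
            self.t0_s,
            self.units if units is None else units,
        )

    def window_indices(self, t_start: float, t_end: float) -> slice:
        """Index slice of samples with ``t_start <= t < t_end``."""
        if t_end <= t_start:
            raise OxcalError(f"empty window [{t_start}, {t_end})")
        i0 = int(np.ceil((t_start - self.t0_s) * self.rate_hz - _EDGE_EPS))
        i1 = int(np.ceil((t_end - self.t0_s) * self.rate_hz - _EDGE_EPS))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.values))
        if i1 <= i0:
            raise OxcalError(
                f"window [{t_start}, {t_end}) s does not overlap trace "
                f"[{self.t0_s}, {self.t0_s + self.duration_s}) s"
            )
        return slice(i0, i1)

    def window_values(self, t_start: float, t_end: float) -> np.ndarray:
        return self.values[self.window_indices(t_start, t_end)]

    def window_mean(self, t_start: float, t_end: float) -> float:
        return float(np.mean(self.window_values(t_start, t_end)))
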