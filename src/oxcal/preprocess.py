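"""Signal conditioning for image stacks and flow traces.

Order of operations: sub-pixel rigid registration against the first frame,
control-region illumination correction, ROI time-series extraction; the
flowmetry trace is block-averaged down to the imaging rate and all traces
are normalized by a pre-stimulus baseline window.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from .exceptions import OxcalError, RegistrationError
from .trace import SampledTrace

__all__ = [
    "RigidShift",
    "estimate_translation",
    "register_stack",
    "intensity_correct",
    "extract_roi",
    "downsample_ldf",
    "normalize_to_baseline",
]


@dataclasses.dataclass(frozen=True)
class RigidShift:
    """Translation of a frame relative to the reference, in pixels."""

    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dy) and np.isfinite(self.dx)):
            raise RegistrationError("non-finite shift")

    def as_array(self) -> np.ndarray:
        return np.array([self.dy, self.dx])


def estimate_translation(
    frame: np.ndarray, reference: np.ndarray, upsample: int = 20
) -> RigidShift:
    """Displacement of ``frame`` relative to ``reference``.

    Fourier cross-correlation refined to 1/upsample pixel. The returned
    shift is the translation that was applied to the reference to produce
    the frame; registering the frame means translating it by the negative.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise RegistrationError("frame and reference must have the same shape")
    if upsample < 1:
        raise RegistrationError("upsample must be >= 1")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        raise RegistrationError("registration undefined for a constant image")
    # skimage returns the shift to apply to the moving image to align it
    # with the reference, i.e. the negative of the frame's displacement
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=upsample, normalization=None
    )
    if np.any(np.abs(shift) >= np.array(frame.shape) / 2):
        raise RegistrationError(f"implausible shift {shift} for frame shape {frame.shape}")
    return RigidShift(-float(shift[0]), -float(shift[1]))


def register_stack(
    stack: np.ndarray, reference_index: int = 0, upsample: int = 20
) -> tuple[np.ndarray, list[RigidShift]]:
    """Register every frame to the reference frame by Fourier translation.

    Returns the registered stack and the estimated per-frame shifts. The
    reference frame is returned unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or len(stack) == 0:
        raise OxcalError("stack must be a nonempty (T, H, W) array")
    reference = stack[reference_index]
    registered = np.empty_like(stack)
    shifts: list[RigidShift] = []
    for i, frame in enumerate(stack):
        if i == reference_index:
            shifts.append(RigidShift(0.0, 0.0))
            registered[i] = frame
            continue
        sh = estimate_translation(frame, reference, upsample=upsample)
        shifts.append(sh)
        if sh.dy == 0.0 and sh.dx == 0.0:
            registered[i] = frame
        else:
            registered[i] = np.fft.ifft2(
                fourier_shift(np.fft.fft2(frame), (-sh.dy, -sh.dx))
            ).real
    return registered, shifts


def intensity_correct(stack: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """Regress the control-region mean trace out of every pixel.

    Each pixel's time course is fitted onto ``[1, g(t)]`` where g is the
    mean trace over the control region (skull/head-bar pixels); the g
    component is removed while the pixel's temporal mean is retained, so
    absolute baseline intensity survives for later absorbance computation.
    A (near-)constant control trace makes the regression degenerate and the
    correction a warned no-op.
    """
    stack = np.asarray(stack, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if stack.ndim != 3:
        raise OxcalError("stack must be (T, H, W)")
    if control_mask.shape != stack.shape[1:]:
        raise OxcalError("control mask shape does not match frames")
    if not control_mask.any():
        raise OxcalError("control mask is empty")
    g = stack[:, control_mask].mean(axis=1)
    g_centered = g - g.mean()
    denom = float(g_centered @ g_centered)
    scale = float(g.mean()) ** 2 * len(g)
    if denom <= 1e-24 * max(scale, 1.0):
        warnings.warn(
            "control-region trace is constant; intensity correction skipped",
            stacklevel=2,
        )
        return stack.copy()
    flat = stack.reshape(len(stack), -1)
    beta = (g_centered @ flat) / denom
    corrected = flat - np.outer(g_centered, beta)
    return corrected.reshape(stack.shape)


def extract_roi(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    rate_hz: float = 10.0,
    t0_s: float = 0.0,
    units: str = "counts",
) -> SampledTrace:
    """Per-frame mean over the ROI pixels as a sampled trace."""
    stack = np.asarray(stack, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise OxcalError("roi mask is empty")
    if roi_mask.shape != stack.shape[1:]:
        raise OxcalError("roi mask shape does not match frames")
    return SampledTrace(stack[:, roi_mask].mean(axis=1), rate_hz, t0_s, units)


def downsample_ldf(trace: SampledTrace, target_hz: float = 10.0) -> SampledTrace:
    """Downsample by non-overlapping block means (100 Hz -> 10 Hz typically).

    The rate must be an integer multiple of the target; a trailing partial
    block is dropped with a warning.
    """
    factor_f = trace.rate_hz / target_hz
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise OxcalError(
            f"rate {trace.rate_hz} Hz is not an integer multiple of {target_hz} Hz"
        )
    if factor == 1:
        return trace.with_values(trace.values.copy())
    n_blocks, rem = divmod(len(trace.values), factor)
    if n_blocks == 0:
        raise OxcalError("trace shorter than one downsampling block")
    if rem:
        warnings.warn(
            f"dropping {rem} trailing samples not filling a block", stacklevel=2
        )
    vals = trace.values[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    return SampledTrace(vals, target_hz, trace.t0_s, trace.units)


def normalize_to_baseline(
    trace: SampledTrace, window: tuple[float, float]
) -> SampledTrace:
    """Divide a trace by its mean over the half-open baseline window."""
    m = trace.window_mean(*window)
    if abs(m) < 1e-12 * max(1.0, float(np.max(np.abs(trace.values)))):
        raise OxcalError("baseline-window mean is (near-)zero; cannot normalize")
    return trace.with_values(trace.values / m, units="ratio")
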