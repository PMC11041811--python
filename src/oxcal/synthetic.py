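"""Forward-model generator for two-wavelength imaging + flowmetry runs.

The generator builds a run from physiological ground truth so that every
analysis stage can be checked against known values:

1. a flow ratio trace rCBF(t) rises exponentially to a plateau during
   stimulation and relaxes back afterwards;
2. total hemoglobin follows Grubb coupling ``rC_HbT = rCBF^α``;
3. the deoxy-hemoglobin change is chosen so that the compartment model
   (model 1 with the true γ pair) reproduces the ground-truth rCMRO2
   profile exactly at every sample — or, in model-3 forward mode, so that
   the single-wavelength model with the true k does;
4. concentration changes map to absorbance changes through the spectral
   matrix and to camera intensities via ``I = I0 exp(-dA)``;
5. the flow trace is emitted at 100 Hz and the optical traces at 10 Hz,
   with optional multiplicative Gaussian noise on each.

Hypercapnia runs default to the isometabolic condition (rCMRO2 = 1
throughout); whisker runs scale the same temporal kernel to an injected
metabolic change.
"""
from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import yaml

from .exceptions import InvalidParadigmError, OxcalError
from .mbll import forward_absorbance
from .optics import DEFAULT_BASELINE, DEFAULT_OPTICS, BaselineConfig, OpticsTable
from .trace import SampledTrace

__all__ = [
    "StimulusParadigm",
    "GroundTruth",
    "SyntheticRun",
    "ImageStackSpec",
    "ImageStackResult",
    "generate_cbf_trace",
    "invert_model1_for_hbr",
    "generate_run",
    "generate_image_stack",
    "write_run",
    "read_run",
]

OPTICAL_RATE_HZ = 10.0
LDF_RATE_HZ = 100.0


@dataclasses.dataclass(frozen=True)
class StimulusParadigm:
    """Timing of a stimulation experiment, onset of the first stimulus at t=0.

    Hypercapnia: one long gas block (defaults 30 s rest, 90 s CO2, 270 s
    recovery). Whisker: ``n_trials`` short stimuli (defaults 6 s) repeated
    every ``inter_trial_s`` (default 36 s, 12 trials).
    """

    kind: str
    rest_s: float
    stim_s: float
    recovery_s: float
    n_trials: int = 1
    inter_trial_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("hypercapnia", "whisker"):
            raise InvalidParadigmError(f"unknown paradigm kind {self.kind!r}")
        if min(self.rest_s, self.stim_s, self.recovery_s) <= 0:
            raise InvalidParadigmError("all durations must be positive")
        if self.n_trials < 1:
            raise InvalidParadigmError("n_trials must be >= 1")
        if self.kind == "whisker" and self.inter_trial_s <= self.stim_s:
            raise InvalidParadigmError("inter_trial_s must exceed stim_s")

    @classmethod
    def hypercapnia(cls, rest_s=30.0, stim_s=90.0, recovery_s=270.0) -> "StimulusParadigm":
        return cls("hypercapnia", rest_s, stim_s, recovery_s, n_trials=1)

    @classmethod
    def whisker(
        cls, rest_s=10.0, stim_s=6.0, inter_trial_s=36.0, n_trials=12
    ) -> "StimulusParadigm":
        return cls(
            "whisker",
            rest_s,
            stim_s,
            inter_trial_s - stim_s,
            n_trials=n_trials,
            inter_trial_s=inter_trial_s,
        )

    @property
    def duration_s(self) -> float:
        if self.kind == "hypercapnia":
            return self.rest_s + self.stim_s + self.recovery_s
        return self.rest_s + self.n_trials * self.inter_trial_s

    @property
    def t0_s(self) -> float:
        return -self.rest_s

    @property
    def trial_onsets(self) -> np.ndarray:
        if self.kind == "hypercapnia":
            return np.array([0.0])
        return np.arange(self.n_trials) * self.inter_trial_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of a synthetic run.

    ``rcbf_peak``/``rcmro2_peak`` are plateau ratios (1.0 means no change;
    isometabolic runs use ``rcmro2_peak=1``). ``k_true`` switches the
    generator to model-3 forward mode, in which the 620 nm absorbance is
    derived from the single-wavelength model instead of the compartment
    model. Rise/fall time constants default per paradigm (10/30 s for
    hypercapnia, 1/10 s for whisker). ``noise_sd`` is the fractional
    standard deviation of the multiplicative measurement noise; ``seed`` is
    mandatory and fully determines all random draws.
    """

    seed: int
    rcbf_peak: float = 1.30
    rcmro2_peak: float = 1.0
    alpha_true: float = 0.38
    gamma_r_true: float = 1.0
    gamma_t_true: float = 1.0
    k_true: float | None = None
    tau_rise_s: float | None = None
    tau_fall_s: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.rcbf_peak > 0:
            raise OxcalError("rcbf_peak must be positive")
        if not 0.0 < self.alpha_true < 1.0:
            raise OxcalError("alpha_true must lie in (0, 1)")
        if self.noise_sd < 0:
            raise OxcalError("noise_sd must be non-negative")

    def time_constants(self, paradigm: StimulusParadigm) -> tuple[float, float]:
        if paradigm.kind == "hypercapnia":
            rise, fall = 10.0, 30.0
        else:
            rise, fall = 1.0, 10.0
        return (
            rise if self.tau_rise_s is None else self.tau_rise_s,
            fall if self.tau_fall_s is None else self.tau_fall_s,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticRun:
    """A generated experiment: measured traces plus their ground truth.

    ``truth_traces`` holds the generator's internal noise-free signals on
    the 10 Hz optical clock (rcbf, rcmro2, dc_hbr, dc_hbt, da580, da620),
    for use as test oracles.
    """

    ldf: SampledTrace
    intensity_580: SampledTrace
    intensity_620: SampledTrace
    truth: GroundTruth
    paradigm: StimulusParadigm
    baseline: BaselineConfig
    optics: OpticsTable
    truth_traces: dict[str, SampledTrace] = dataclasses.field(default_factory=dict)


def response_kernel(
    paradigm: StimulusParadigm, t: np.ndarray, tau_rise: float, tau_fall: float
) -> np.ndarray:
    """Normalized response shape in [0, ~1]: 0 at rest, ->1 at plateau.

    Exponential rise during each stimulus, exponential decay afterwards;
    whisker trials superpose additively (tails at the default spacing are
    negligible).
    """
    t = np.asarray(t, dtype=float)
    kappa = np.zeros_like(t)
    for onset in paradigm.trial_onsets:
        tt = t - onset
        during = (tt >= 0) & (tt < paradigm.stim_s)
        after = tt >= paradigm.stim_s
        kappa[during] += 1.0 - np.exp(-tt[during] / tau_rise)
        end_level = 1.0 - np.exp(-paradigm.stim_s / tau_rise)
        kappa[after] += end_level * np.exp(-(tt[after] - paradigm.stim_s) / tau_fall)
    return kappa


def _time_grid(paradigm: StimulusParadigm, rate_hz: float) -> np.ndarray:
    n = int(round(paradigm.duration_s * rate_hz))
    return paradigm.t0_s + np.arange(n) / rate_hz


def generate_cbf_trace(
    paradigm: StimulusParadigm,
    truth: GroundTruth,
    rate_hz: float = OPTICAL_RATE_HZ,
    rng: np.random.Generator | None = None,
) -> SampledTrace:
    """Ground-truth flow-ratio trace rCBF(t).

    Equal to 1 during rest, rising to ``rcbf_peak`` during stimulation with
    the truth's time constants. Multiplicative Gaussian noise of fractional
    sd ``noise_sd`` is added when nonzero (seeded from the truth unless an
    rng is supplied).
    """
    t = _time_grid(paradigm, rate_hz)
    tau_r, tau_f = truth.time_constants(paradigm)
    values = 1.0 + (truth.rcbf_peak - 1.0) * response_kernel(paradigm, t, tau_r, tau_f)
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        values = values * (1.0 + truth.noise_sd * rng.standard_normal(len(values)))
    return SampledTrace(values, rate_hz, paradigm.t0_s, units="ratio")


def invert_model1_for_hbr(rcmro2, rcbf, dhbt_frac, gamma_r: float, gamma_t: float):
    """Fractional deoxy-hemoglobin change reproducing a target rCMRO2.

    Algebraic inverse of the compartment model: the returned
    ``a = ΔC_HbR/C_HbR0`` satisfies
    ``rcbf (1 + γR a) / (1 + γT b) = rcmro2`` exactly.
    """
    if gamma_r == 0:
        raise OxcalError("gamma_r = 0: compartment model is not invertible for HbR")
    rcbf = np.asarray(rcbf, dtype=float)
    if np.any(rcbf <= 0):
        raise OxcalError("rcbf must be positive")
    denom = 1.0 + gamma_t * np.asarray(dhbt_frac, dtype=float)
    if np.any(denom <= 0):
        raise OxcalError("1 + gammaT*b must be positive")
    out = (np.asarray(rcmro2, dtype=float) / rcbf * denom - 1.0) / gamma_r
    return out if out.ndim else float(out)


def generate_run(
    paradigm: StimulusParadigm,
    truth: GroundTruth,
    baseline: BaselineConfig = DEFAULT_BASELINE,
    optics: OpticsTable = DEFAULT_OPTICS,
    i0_counts: tuple[float, float] = (1000.0, 1000.0),
    ldf0: float = 250.0,
) -> SyntheticRun:
    """Generate a complete synthetic run with stored ground truth.

    Noise draws (when ``noise_sd > 0``) come from a single generator seeded
    with ``truth.seed`` in the fixed order LDF, 580 nm, 620 nm, so equal
    seeds give bit-identical runs.
    """
    rng = np.random.default_rng(truth.seed)
    t10 = _time_grid(paradigm, OPTICAL_RATE_HZ)
    t100 = _time_grid(paradigm, LDF_RATE_HZ)
    tau_r, tau_f = truth.time_constants(paradigm)
    kap10 = response_kernel(paradigm, t10, tau_r, tau_f)
    kap100 = response_kernel(paradigm, t100, tau_r, tau_f)
    rcbf10 = 1.0 + (truth.rcbf_peak - 1.0) * kap10
    rcbf100 = 1.0 + (truth.rcbf_peak - 1.0) * kap100
    rcmro2 = 1.0 + (truth.rcmro2_peak - 1.0) * kap10

    # Grubb-coupled blood volume -> total hemoglobin
    rchbt = rcbf10 ** truth.alpha_true
    b = rchbt - 1.0
    dc_hbt = b * baseline.c_hbt0_um

    m = optics.matrix
    if truth.k_true is None:
        a = invert_model1_for_hbr(rcmro2, rcbf10, b, truth.gamma_r_true, truth.gamma_t_true)
        dc_hbr = a * baseline.c_hbr0_um
        dc_hbo = dc_hbt - dc_hbr
        dc_hbt = dc_hbo + dc_hbr  # re-sum so conservation is bitwise exact
        da580, da620 = forward_absorbance(dc_hbo, dc_hbr, optics)
    else:
        # model-3 forward mode: the 620 nm absorbance satisfies the
        # single-wavelength model with the true k
        da620 = (rcmro2 * rcbf10 ** (truth.alpha_true - 1.0) - 1.0) / truth.k_true
        if m[1, 1] == m[1, 0]:
            raise OxcalError("optics cannot separate HbO from HbR at 620 nm")
        dc_hbr = (da620 - m[1, 0] * dc_hbt) / (m[1, 1] - m[1, 0])
        dc_hbo = dc_hbt - dc_hbr
        dc_hbt = dc_hbo + dc_hbr
        da580 = m[0, 0] * dc_hbo + m[0, 1] * dc_hbr

    ldf_vals = ldf0 * rcbf100
    i580 = i0_counts[0] * np.exp(-da580)
    i620 = i0_counts[1] * np.exp(-da620)
    if truth.noise_sd > 0:
        ldf_vals = ldf_vals * (1.0 + truth.noise_sd * rng.standard_normal(len(ldf_vals)))
        i580 = i580 * (1.0 + truth.noise_sd * rng.standard_normal(len(i580)))
        i620 = i620 * (1.0 + truth.noise_sd * rng.standard_normal(len(i620)))
    if np.any(i580 <= 0) or np.any(i620 <= 0):
        raise OxcalError("noise too large: generated a non-positive intensity")

    t0 = paradigm.t0_s
    mk = lambda v, rate, units: SampledTrace(v, rate, t0, units)  # noqa: E731
    return SyntheticRun(
        ldf=mk(ldf_vals, LDF_RATE_HZ, "perfusion-units"),
        intensity_580=mk(i580, OPTICAL_RATE_HZ, "counts"),
        intensity_620=mk(i620, OPTICAL_RATE_HZ, "counts"),
        truth=truth,
        paradigm=paradigm,
        baseline=baseline,
        optics=optics,
        truth_traces={
            "rcbf": mk(rcbf10, OPTICAL_RATE_HZ, "ratio"),
            "rcmro2": mk(rcmro2, OPTICAL_RATE_HZ, "ratio"),
            "dc_hbr": mk(dc_hbr, OPTICAL_RATE_HZ, "uM"),
            "dc_hbt": mk(dc_hbt, OPTICAL_RATE_HZ, "uM"),
            "dc_hbo": mk(dc_hbo, OPTICAL_RATE_HZ, "uM"),
            "da580": mk(da580, OPTICAL_RATE_HZ, "dA"),
            "da620": mk(da620, OPTICAL_RATE_HZ, "dA"),
        },
    )


@dataclasses.dataclass(frozen=True)
class ImageStackSpec:
    """Geometry and nuisance amplitudes for toy image stacks.

    ``roi_mask`` marks the responding tissue, ``control_mask`` a region
    (skull/head-bar analogue) that carries only common-mode illumination
    drift; the two must be disjoint and nonempty.
    """

    height: int
    width: int
    roi_mask: np.ndarray
    control_mask: np.ndarray
    motion_amplitude_px: float = 0.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 60.0
    motion_period_s: float = 45.0

    def __post_init__(self) -> None:
        for name in ("roi_mask", "control_mask"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            object.__setattr__(self, name, mask)
            if mask.shape != (self.height, self.width):
                raise OxcalError(f"{name} shape does not match frame size")
            if not mask.any():
                raise OxcalError(f"{name} is empty")
        if (self.roi_mask & self.control_mask).any():
            raise OxcalError("roi and control masks overlap")

    @classmethod
    def default(
        cls, height: int = 48, width: int = 48, **kwargs
    ) -> "ImageStackSpec":
        """Centered oval ROI with a control strip along the top edge."""
        yy, xx = np.mgrid[:height, :width]
        roi = ((yy - height / 2) / (height / 5)) ** 2 + (
            (xx - width / 2) / (width / 4)
        ) ** 2 <= 1.0
        control = np.zeros((height, width), dtype=bool)
        control[2:6, 4:-4] = True
        return cls(height, width, roi, control, **kwargs)


@dataclasses.dataclass
class ImageStackResult:
    """Generated stacks plus the injected nuisance ground truth."""

    stack_580: np.ndarray
    stack_620: np.ndarray
    shifts: np.ndarray  # (T, 2) true (dy, dx) of each frame
    drift: np.ndarray  # (T,) common-mode multiplicative drift g(t)
    pattern: np.ndarray  # baseline spatial pattern


def generate_image_stack(run: SyntheticRun, spec: ImageStackSpec) -> ImageStackResult:
    """Render a run as two toy image stacks with known motion and drift.

    Each frame is a smooth baseline pattern whose ROI pixels follow the
    run's temporal intensity ratio, multiplied everywhere (control region
    included) by ``1 + drift(t)``, then translated by a smooth sub-pixel
    trajectory of the requested amplitude. The first frame is unshifted so
    it can serve as the registration reference.
    """
    from scipy.ndimage import fourier_shift, gaussian_filter

    rng = np.random.default_rng(run.truth.seed + 1)
    h, w = spec.height, spec.width
    pattern = 1.0 + 0.15 * gaussian_filter(rng.standard_normal((h, w)), sigma=4)
    pattern = np.clip(pattern, 0.5, None)

    t = run.intensity_580.times()
    n = len(t)
    drift = spec.drift_amplitude * np.sin(2 * np.pi * (t - t[0]) / spec.drift_period_s)
    ph = 2 * np.pi * (t - t[0]) / spec.motion_period_s
    shifts = spec.motion_amplitude_px * np.column_stack([np.sin(ph), np.cos(ph) - 1.0])

    stacks = []
    for intensity, i0 in (
        (run.intensity_580, run.intensity_580.values[0]),
        (run.intensity_620, run.intensity_620.values[0]),
    ):
        ratio = intensity.values / intensity.window_mean(run.paradigm.t0_s, 0.0)
        stack = np.empty((n, h, w))
        for i in range(n):
            frame = pattern * (1.0 + (ratio[i] - 1.0) * spec.roi_mask)
            frame = frame * (1.0 + drift[i])
            if shifts[i].any():
                frame = np.fft.ifft2(
                    fourier_shift(np.fft.fft2(frame), shifts[i])
                ).real
            stack[i] = frame
        stacks.append(stack)
    return ImageStackResult(
        stack_580=stacks[0],
        stack_620=stacks[1],
        shifts=shifts,
        drift=drift,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# run directory I/O


def _write_trace_csv(path: pathlib.Path, trace: SampledTrace, value_col: str) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": trace.times(), value_col: trace.values}).to_csv(
        path, index=False
    )


def _read_trace_csv(path: pathlib.Path, value_col: str, units: str) -> SampledTrace:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return SampledTrace(df[value_col].to_numpy(), round(rate, 6), float(t[0]), units)


def write_run(run: SyntheticRun, out_dir: str | pathlib.Path) -> pathlib.Path:
    """Write a run as a directory of CSV/JSON/YAML files."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_trace_csv(out / "ldf.csv", run.ldf, "value")
    _write_trace_csv(out / "ois_580.csv", run.intensity_580, "intensity")
    _write_trace_csv(out / "ois_620.csv", run.intensity_620, "intensity")
    truth = run.truth.to_dict()
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    with open(out / "paradigm.yaml", "w") as fh:
        yaml.safe_dump(run.paradigm.to_dict(), fh)
    with open(out / "baseline.json", "w") as fh:
        json.dump({"c_hbt0_um": run.baseline.c_hbt0_um, "s0": run.baseline.s0}, fh)
    return out


def read_run(run_dir: str | pathlib.Path) -> SyntheticRun:
    """Reconstruct a run written by :func:`write_run` (without truth traces)."""
    d = pathlib.Path(run_dir)
    with open(d / "truth.json") as fh:
        truth = GroundTruth(**json.load(fh))
    with open(d / "paradigm.yaml") as fh:
        paradigm = StimulusParadigm(**yaml.safe_load(fh))
    baseline = DEFAULT_BASELINE
    if (d / "baseline.json").exists():
        with open(d / "baseline.json") as fh:
            bl = json.load(fh)
        baseline = BaselineConfig(**bl)
    return SyntheticRun(
        ldf=_read_trace_csv(d / "ldf.csv", "value", "perfusion-units"),
        intensity_580=_read_trace_csv(d / "ois_580.csv", "intensity", "counts"),
        intensity_620=_read_trace_csv(d / "ois_620.csv", "intensity", "counts"),
        truth=truth,
        paradigm=paradigm,
        baseline=baseline,
        optics=DEFAULT_OPTICS,
    )
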