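# Methods

## Physiological model

Oxygen delivery and consumption are taken to be in steady-state balance
(Fick): `rCMRO₂ = rCBF · rOEF`, all quantities ratios to the pre-stimulus
baseline. With all blood oxygen hemoglobin-bound, the oxygen extraction
fraction equals `C_HbR/C_HbT`, so

    rOEF = (1 + a) / (1 + b),   a = ΔC_HbR/C_HbR,0,   b = ΔC_HbT/C_HbT,0.

Concentration changes come from per-sample modified Beer–Lambert unmixing
of the absorbance changes `ΔA_λ = −ln(I_λ(t)/I_λ,0)` at 580 nm
(total-hemoglobin-sensitive) and 620 nm (deoxy-sensitive). The three model
families and their parameters:

* **Model 1** (2 wavelengths + flow): `rCBF (1 + γ_R a)/(1 + γ_T b)`.
  γ_R, γ_T are dimensionless venous-volume-fraction weights, default 1.
* **Model 2** (2 wavelengths): flow replaced by the Grubb estimate
  `(1 + b)^(1/α)` from the flow–volume power law `rCBV = rCBF^α`.
* **Model 3** (1 wavelength + flow): `rCBF^(1−α) (1 + k x)`, with `x` the
  620 nm absorbance change (measured variant) or `rC_HbR − 1` (ideal
  variant). k (units 1/absorbance or 1/ratio, respectively) absorbs the
  baseline deoxy-hemoglobin concentration, compartment weighting and the
  absorbance-to-concentration scale.

Assumptions inherited from this model class: fully saturated arterial
blood, no net tissue oxygen storage, all oxygen hemoglobin-bound, a single
homogeneous compartment per ROI.

## Calibration

Mild hypercapnia is treated as isometabolic, pinning rCMRO₂ = 1 over the
calibration window (the last 30 s of the 90 s gas block). The constraint is
imposed on the *window means* of the signals — one linear constraint per
run — matching the convention of reporting a single coefficient set per
run; non-uniqueness of (γ_R, γ_T) arises exactly because one constraint
defines a line in the plane. "Closest to (1, 1)" is implemented as the
Euclidean orthogonal projection of (1, 1) onto that line (the metric is a
design choice; a dense line search verifies the projection in the tests).
Note that with hypercapnia-signed inputs (a < 0, b > 0) the projection
moves γ_R and γ_T to the same side of 1 for any single run; per-animal
group means on real data can still straddle 1.

Closed forms used:

    α  = ln(rC_HbT,mean) / ln(rCBF_mean)
    k  = (rCBF_mean^(α−1) − 1) / x_mean
    (γ_R, γ_T) = argmin ‖γ − (1,1)‖  s.t.  rCBF(1 + γ_R a) = 1 + γ_T b

Because α is estimated from the same window means, the Grubb flow estimate
`(1 + b)^(1/α)` equals `rCBF_mean` *exactly*, so Model 2 calibration yields
identical γ values to Model 1 — an algebraic identity here, not an
approximation. Model 3's per-run k is computed for both x-signals (620 nm
absorbance, and the ideal deoxy-ratio variant used by the 3-Ideal
scenario). Aggregation across runs/animals is the arithmetic mean with the
sample (n−1) standard deviation, pooling CO₂ levels.

Scalar rCMRO₂ values are obtained by applying the models to the
window-mean summaries — the same quantities calibration constrains — so a
calibrated model evaluated on its own run returns 1 to machine precision.
Per-sample rCMRO₂ traces (for plots, or trace-level checks) are computed
separately; their window means agree with the scalar values to second
order in the within-window signal variation.

Percent error between scenarios is defined on the *change* (rCMRO₂ − 1),
not the ratio; model comparisons use two-sided paired t-tests across
animals against the Model 1-Cal reference, with no multiple-testing
correction. Whether models 2–3 use each animal's own α or the cross-animal
mean is a config switch (`alpha_policy`), defaulting to per-run.

## Synthetic-data generator

The generator is the package's test bed: it emulates the two experiment
types with known ground truth.

* **Paradigms.** Hypercapnia: 30 s rest, 90 s gas, 270 s recovery, one
  block. Whisker: 6 s stimulation every 36 s, 12 trials, 10 s initial rest
  (the pre-trial baseline window is 5 s, so any rest ≥ 5 s works).
* **Response shape.** Exponential rise to a plateau during stimulation and
  exponential relaxation afterwards. Time constants: 10 s rise / 30 s fall
  for hypercapnia, 1 s rise / 10 s fall for whisker — chosen once to mirror
  the plateau-type gas responses and the few-second evoked responses of
  awake-mouse imaging. The rCMRO₂ ground-truth profile shares the same
  temporal kernel, scaled to its own peak (the simplest coupling consistent
  with evoked data); hypercapnia runs default to rCMRO₂ ≡ 1.
* **Hemodynamics.** Default flow plateaus: 1.30 for the mild-CO₂ condition
  (a ~30% increase; ~114% emulates the strong condition) and 1.14–1.17 for
  whisker runs. Total hemoglobin is Grubb-coupled, `rC_HbT = rCBF^α` with
  α = 0.38 by default. The deoxy change is obtained by inverting Model 1
  at the true (γ_R, γ_T) — default (1, 1), a single-compartment truth — so
  the generated data satisfy the compartment model exactly at every sample.
  A model-3 forward mode (`k_true` set) instead derives the 620 nm
  absorbance from the single-wavelength model, for k-identifiability tests.
* **Optics.** Natural-log extinction coefficients from the standard
  compiled hemoglobin absorption tables; pathlength factors 0.1 mm at
  580 nm and 1.5 mm at 620 nm, representative literature-scale values that
  place synthetic signal changes in realistic ranges (≈ −4% at 580 nm and
  ≈ +1% at 620 nm for a 30% flow increase). No analysis result depends on
  the specific constants: unmixing tests are round-trip based and users can
  supply their own table (with a base-10 conversion flag).
* **Emission.** Intensities `I_λ = I₀ e^(−ΔA_λ)` at 10 Hz (I₀ = 1000
  counts), LDF at 100 Hz (baseline 250 arbitrary units) so the downsampling
  path is always exercised. Noise is multiplicative Gaussian, independent
  across samples, fractional sd `noise_sd` (default 0); all draws come from
  one seeded generator in a fixed order, so equal seeds give bit-identical
  runs. The generator rejects noise levels producing non-positive
  intensities.
* **Image stacks.** A smooth random baseline pattern whose ROI pixels
  follow the run's intensity ratio, multiplied everywhere by a sinusoidal
  common-mode drift (the control region carries it exactly), translated by
  a smooth sub-pixel trajectory; shifts and drift are stored as ground
  truth for registration and illumination-correction tests.

What the generator does *not* emulate: spatially heterogeneous hemodynamics
(one active compartment), vascular-compartment separation beyond the γ
coefficients, physiological (pulsatile, vasomotor) noise, capnometry, or
nonlinear neurovascular coupling. Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to real-data violations of it.

## Numerical and design choices

* Windows are half-open `[t_start, t_end)` with t = 0 at stimulus onset;
  hypercapnia baseline [−30, 0) s and response [60, 90) s; whisker baseline
  [−5, 0) s per trial, epochs −5 to +30 s, peak search [0, stim + 4) s, and
  the scalar change is the mean over the 2 s window centered on the peak of
  each signal's absolute deviation from baseline (ties broken earliest).
  Because a rise-and-decay response spends part of the centered window
  below its instantaneous peak, the reported whisker change sits slightly
  below the injected peak (≈ 5.6% for a 6% peak under the default kernel);
  estimator correctness is asserted against the ground-truth trace
  summarized with the identical statistic.
* Registration: Fourier phase correlation, default refinement 1/20 px;
  frames are corrected by the negative estimated shift in the frequency
  domain. Constant images are rejected as undefined.
* Illumination correction regresses each pixel onto an intercept plus the
  control-region mean trace, removing only the control component and
  retaining the pixel's temporal mean so absolute baselines survive for
  absorbance computation. A (near-)constant control trace makes the
  regression degenerate; the correction is then a warned no-op.
* LDF downsampling uses non-overlapping block means (averaging as
  anti-aliasing); rates must divide evenly and trailing partial blocks are
  dropped with a warning.
* Unmixing solves the 2×2 system per sample with no temporal
  regularization; matrices with condition number above 1e8 are rejected.
* Model domain violations (non-positive denominators or flow ratios) raise
  errors rather than clipping — such states indicate noise incompatible
  with the model. Calibrated coefficients outside the usual physiological
  range are reported as-is with a warning, never clipped. The Grubb
  exponent re-estimated under a deliberately mis-assumed baseline
  concentration may legitimately exceed 1 (it does in the baseline sweep),
  so models accept any positive α.
* Baseline sensitivity: the sweep re-runs calibration and scenario
  evaluation over a (C_HbT,0 × S₀) grid (defaults 280/140/70 μM ×
  75/65/55%). Model 3 never touches the Beer–Lambert baselines, so its
  rows are invariant to S₀; the calibrated Model 1 change varies several
  times less across C_HbT,0 than the uncalibrated γ = 1 variant on the
  synthetic cohorts.
* Test problem sizes: cohorts of 7 animals (one hypercapnia + one whisker
  run each); the noisy-recovery check averages 20 seeded cohorts at 1%
  measurement noise. The full suite runs in well under a minute.

## Known limitations

* The single-run γ calibration constrains only the calibration operating
  point; transferring γ to a different stimulus is exact only insofar as
  the compartment weights are stimulus-independent (the model's own
  assumption).
* The 620 nm surrogate in Model 3 carries oxy-hemoglobin crosstalk; when
  the oxy/deoxy balance differs between calibration and test conditions
  (as it does between gas and evoked responses), Model 3 inherits a bias —
  visibly larger on the synthetic cohorts than the flow-informed models,
  consistent with its higher reported variability in vivo.
* No support for more than two wavelengths (the 2×2 system is structural),
  and no statistical comparison against external modalities.
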