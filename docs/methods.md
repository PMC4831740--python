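# Methods

This note documents the models, detector conventions, synthetic-data
assumptions and numerical choices behind `ctstain`.

## Staining kinetics

**Saturation model.** Intensity at a fixed depth is modelled as
`I(t) = I0 + (Imax − I0)(1 − e^(−k t))` with `0 ≤ I0 < Imax` and `k > 0`
(1/days). The exponent is negative by construction: a positive exponent
diverges and cannot describe saturation, and only the decaying form is
consistent with published fitted constants for I2KI/PTA/PMA staining
(with those constants the model reproduces the reported 99/87/98% of
`Imax` after four days; `tests/test_kinetics.py` asserts this). Fits use
unweighted Levenberg–Marquardt/trust-region least squares
(`scipy.optimize.curve_fit`) with initialisation `I0 ← I(first day)`,
`Imax ← max(I)`, `k ← 1/day` and bounds `[0, 1.5]` on the intensities.
A constant series raises a fit error (`k` unidentifiable) rather than
returning an arbitrary rate.

**Saturation level.** A level `f` (default 0.90/0.95/0.99) refers to
`f·Imax` of *absolute* intensity, not a fraction of the span
`Imax − I0`. Consequently `saturation_time` returns 0 (with a warning)
when `f·Imax ≤ I0` and raises when `f·Imax ≥ Imax`. The closed-form
inverse `t = −(1/k)·ln(1 − (f·Imax − I0)/(Imax − I0))` is the exact
inverse of the forward curve (round-trip property-tested).

**Staining-time model.** Per-depth saturation times are fitted with
`t_stain(x) = A·e^(c x)` by nonlinear least squares on the linear scale,
initialised from the log-linear regression `ln t = ln A + c·x`. Fitting
on the linear scale weights the (larger, deeper) times more than a
log-scale fit would; both views are mathematically equivalent at the
optimum for noise-free data, and the linear-scale choice keeps residuals
in days. A constant offset in the depth origin (e.g. a systematic edge
bias) multiplies `A` but leaves `c` untouched, which is why `c` is the
robust summary of depth dependence.

**Front model.** Front depths over time are fitted with
`x(t) = C(1 − e^(−K t))`, initialised at `C = 1.2 × max depth`,
`K = 1/mean(t)`. Days with no detectable front are recorded as missing
and excluded from the fit, never as zeros. The asymptote `C` is reported
as the maximum penetration depth. (Some summary tables print the rate
constant under the header `D`; this package uses `K` throughout.)

**Confidence intervals.** All fits report per-parameter 95% intervals
from the linearised covariance with a Student-t quantile on `n − p`
degrees of freedom. They are honest small-sample approximations: in a
200-replicate simulation at noise σ = 0.01 the nominal-95% interval on
`k` covers the truth ≈ 95% of the time (asserted ≥ 90%).

## Profile detectors

**Extraction and normalisation.** A line profile is the mean over a
10-pixel-wide band through the slice centre. All profiles of a cohort
are divided by one global maximum, so intensities are comparable across
samples, stains and days; per-stain normalisation is available via
configuration. Normalisation is idempotent and scale-invariant
(property-tested).

**Edge detection.** On the σ = 4 px Gaussian-filtered profile (kernel
truncated at 4σ, edge replication), the global maximum of the gradient
marks the rising boundary and the global minimum the falling one; each
edge is the next point toward the sample centre where |gradient| falls
below 0.01. The opposing-edge rule is implemented as the mirror of the
first-edge rule (walking outward-to-inward from the gradient minimum).

**Threshold units.** The 0.01 and 0.2 thresholds are interpreted per
millimetre of the position axis on the normalised filtered profile. At
7.5 µm spacing a per-pixel reading would make the −0.2 front trigger
unreachable (a full 0→1 step over one ramp would still be ≲ 0.01/px),
so per-mm is the only self-consistent choice; the units are
configurable.

**Zero-gradient walks.** Because profiles are finely sampled, the
|gradient| < 0.01 band can fall entirely between two adjacent samples on
noise-free data. The walks therefore also terminate at an exact sign
change of the gradient, taking whichever neighbouring sample is closer
to zero. On real, noisier data the sub-tolerance band is wide and this
fallback is rarely exercised.

**Front location convention.** The detected front edge is the
zero-gradient point *inward* of the steep drop, i.e. the inner end of
the transition ramp. On a phantom with ramp width `w` the detected depth
is `d_true + w/2` plus a small smoothing offset — within `w` of truth,
which is the accuracy claimed and tested. Front depth is measured
independently from the left and right edges and the two sides averaged;
side-resolved values are retained. A front that reaches the sample
half-width is capped there and flagged.

**Depth series.** Intensities are read off every 0.1 mm from each
detected edge on the 0.1 mm-neighbourhood-averaged profile (boxcar,
truncated at the profile ends; half-width `floor((window/2)/Δ)`
samples). Depths beyond a day's half-width are missing values.

## Synthetic phantoms

The generator emulates a near-cylindrical sample as a disc with radial
symmetry (the real samples are near-cylindrical and all measurements are
1D line profiles). Depth is Euclidean distance from the (shrunk) disc
boundary.

* **Saturating mode** applies the saturation model pointwise with a
  depth-decaying rate `k(x) = k0·e^(−c_k x)`. This makes the time to any
  fixed saturation level grow exactly as `e^(c_k x)`, so the
  staining-time exponent is recoverable and the end-to-end recovery test
  has an exact target.
* **Front mode** uses a linear ramp of width `w` (default 0.3 mm)
  between stained rim and unstained core, centred on
  `d(t) = C(1 − e^(−K t))`. The ramp shape is a free choice (no
  published front profile exists); its width parameterises the detector
  tolerance.
* **Shrinkage** is uniform radial scaling
  `R(t) = R0(1 − s(1 − e^(−λt)))` with default λ = 2.5/day, putting
  ~92% of the shrinkage in day 1 — the early-shrinkage/plateau pattern
  seen in stained ligament areas. `s = 0.0513` yields the ~10%
  steady-state area loss typical of I2KI; front-type agents shrink more.
* **Noise** is additive Gaussian on normalised intensity, clipped to
  [0, 1], seeded per (spec, timepoint) for reproducibility. Default
  phantom defaults follow the study conditions: 7.5 µm pixels, five
  daily timepoints with day 0 unstained, radii of a few mm.

Not emulated: beam hardening, ring/streak reconstruction artefacts,
inhomogeneous bending, partial-volume blur, and any real unstained-tissue
texture. The background level (default 0.02, below `I0`) is a choice —
real backgrounds depend on the mounting medium — and is configurable.
Passing tests on phantoms therefore demonstrate the correctness of the
detectors and fits under the stated geometry and noise model, not
robustness to reconstruction artefacts.

## Morphometry

Segmentation thresholds the slice (Otsu by default; fixed threshold for
reproducibility), keeps the largest connected component and fills holes
— stained samples have bright rims and dim cores that naive thresholding
hollows out, and isolated noise pixels must not count as tissue. Area is
pixel count × pixel size²; discretisation keeps the error below 2% for
radii ≥ 50 px. Normalised area divides by the day-0 area, which is 1.0
exactly by construction.

## Statistics

The two-way ANOVA (day × stain) uses the exact closed-form mean
decomposition for balanced designs; with one observation per cell — the
design of a typical staining study — the additive (no-interaction) model
is fitted, since the interaction is not estimable. With replicates the
interaction term is included. Unbalanced designs fall back to a Type-II
least-squares decomposition (statsmodels OLS) and are flagged. Under a
simulated Gaussian null the factor F-tests reject at 5.0 ± 1% at
α = 0.05 (calibration asserted within [3%, 7%] over 2000 simulations).

Tukey HSD uses the studentized-range distribution with the pooled
within-group mean square and the Tukey–Kramer standard error for unequal
group sizes; results match `statsmodels.pairwise_tukeyhsd` and a direct
formula oracle.

## Pipeline conventions

Cohort filenames encode (sample, stain, day) so the global normalisation
maximum is computed in one pass before per-sample analysis. Every
detector decision (edge positions, front found/missing, fit convergence)
is logged. Samples failing a stage propagate as flagged-missing values.
Both analysis paths run on every sample: the per-depth saturation route
and the front route; saturating samples naturally report no fronts, and
front-type samples contribute no front model unless fronts are found on
at least three days.

## Problem sizes

The test suite and examples use phantoms of 0.9–3 mm radius at the full
7.5 µm resolution (images up to ~880² px), five daily timepoints, 200
Monte-Carlo fit replicates and 2000 ANOVA null simulations — sizes
chosen so the whole suite runs in well under a minute of compute per
module while keeping every statistical assertion comfortably powered.

## Known limitations

* Thresholds are tuned for the 7.5 µm / σ = 4 px regime; substantially
  different resolutions warrant re-examining `zero_tol` and `drop_tol`.
* The front-depth estimate carries a systematic +w/2 offset by
  convention; comparisons across stains with similar front widths are
  unaffected, absolute depths are slight overestimates (conversely,
  zero-gradient edge detection places edges slightly inside the true
  boundary, so depths measured from edges are slight underestimates).
* Confidence bands for derived quantities (e.g. predicted staining
  times) are not propagated; only per-parameter intervals are reported.
* No mechanistic (Fickian) diffusion model is fitted; `k`, `c`, `C`, `K`
  are empirical summaries.
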