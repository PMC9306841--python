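# Methods

This note documents the models, numerical choices and limitations behind
`fishchroma`. It is written for users who want to know what the package
actually computes, what the synthetic generator does and does not emulate,
and where genuinely open design choices were resolved.

## Scientific setting

Atlantic mackerel (*Scomber scombrus*) skin shifts from green towards blue
under crowding stress. The dorsal surface carries alternating dark and
light stripes; the colour signal of interest lives in the light
("coloured section") stripes and is quantified as the CIELAB b* component
(blue −, yellow +) of calibrated photographs. The package implements the
three stages needed to study this response quantitatively: calibrated
photographic colourimetry, crowding-density estimation from cage geometry,
and variance-structured regression linking colour to crowding exposure,
physiology and post-mortem time. Because no field imagery is distributed,
every stage is exercised against a synthetic generator whose ground truth
is known exactly.

## Colour measurement chain

Processing order per photograph:

1. **sRGB decode.** 8-bit pixel values are mapped to linear RGB with the
   standard IEC 61966-2-1 piecewise transfer function. Encode/decode are
   exact inverses (tested to 1e-12).
2. **Exposure normalisation.** Flash output varies between shots. The mean
   linearised *green* value of a rectangle of the white background is
   compared to that background's known reference value and the whole image
   is rescaled by the ratio. Green is used as the intensity proxy because
   it carries most of the luminance signal and matches the green plane used
   later for stripe masking. A background mean ≥ 0.99 is flagged as
   saturated; the gain is then unreliable and the measurement is marked so.
3. **Matrix correction.** A 3×3 linear-RGB matrix fitted by least squares
   to the 24 chart patch pairs (measured vs. reference) maps camera colour
   to reference colour. The fit has no offset term, consistent with
   flash-lit, black-level-subtracted capture; chart patch means are
   exposure-normalised against the brightest neutral patch before fitting
   so the matrix is independent of the chart frame's own flash gain.
4. **CIELAB conversion.** Linear RGB → XYZ (sRGB/D65 primaries) → CIELAB
   with the D65 white point, per pixel. D65 is used throughout because it
   is the native white of the sRGB pipeline; the white point is an explicit
   argument everywhere it matters.
5. **ROI and stripe mask.** A 530 × 53 px strip along the dorsal axis is
   cropped without resampling. Otsu's threshold on the green plane of the
   strip separates dark stripes from the light coloured section; pixels
   strictly above the threshold are kept. Otsu was chosen because it is
   automatic and parameter-free; a fixed threshold can be supplied instead,
   and the threshold actually used is recorded with each measurement.
6. **Averaging.** Each kept pixel is converted to CIELAB first and the
   arithmetic mean of L*, a*, b* is taken afterwards (per-pixel conversion
   then averaging — order matters for nonlinear transforms). The per-channel
   values are sorted before summation so the mean is bit-identical under
   pixel reordering. Fewer than 50 kept pixels flags the measurement
   unreliable.

## Synthetic camera and scene model

The renderer draws a white background (L* 95), a rectangular fish region
with vertical stripes (dark L* 20, duty fraction 0.4 of a 24 px period) and
a light-stripe colour set by the experiment, converts the scene to linear
RGB, applies the camera model — exposure gain times a 3×3 matrix, clipping,
sRGB encoding, 8-bit quantisation — and returns the exact light-pixel mask
as ground truth. The camera matrix is near-identity (entries perturbed by
up to ±4%); exposure gain is drawn uniformly from [0.7, 1.1] per image. The
upper gain bound is a deliberate photographic choice: the white background
sits near linear 0.88, and gains above ~1.13 would clip it in an 8-bit
container, destroying the very signal the exposure correction relies on —
a real workflow exposes to protect its highlights. The chart reference
lattice (8 sub-gamut cube corners, a 6-step grey ramp, 10 fixed mid-tones,
values capped at 0.85) leaves the same headroom.

What the renderer does **not** emulate: fish curvature, scales, fins,
specular highlights (removed optically in the field with crossed
polarisers), RAW sensor data, demosaicing, or noise beyond quantisation.
Passing the recovery tests therefore demonstrates the correctness of the
calibration mathematics and segmentation logic, not robustness to the full
optical complexity of real photographs.

## Crowding density

The experimental sea cage is a 5 × 5 × 5 m box over a pyramidal bottom
with total volume 149.17 m³; the pyramid depth is not published and is
back-derived as 3·(149.17 − 125)/25 = 2.9004 m. During crowding the school
occupies the pyramidal tip; its volume is area·depth/3 (identical for a
right cone and a pyramid), with depth obtained by similar-shape scaling:
linear scale k = √(area/base area), depth = k · pyramid depth. The
similarity model is an explicit stand-in — the original trigonometric
derivation is not recoverable — and published per-trial densities are
treated as given inputs, never as recomputation targets. Density is
biomass/volume in kg m⁻³, with biomass either given or n·mean weight.

## Statistical models

All estimators are implemented from first principles in `fishchroma.stats`;
`statsmodels` and `lme4` appear only as independent oracles in the test
suite.

**Wilson score intervals** for mortality proportions, exact at the
boundaries (upper bound z²/(n+z²) for zero events).

**GLS with per-group variance ratios ("VarIdent").** y = Xβ + ε with
Var(ε_i) = σ²δ²_{g(i)}, δ fixed at 1 for the reference level (first level
alphabetically; categorical terms use treatment contrasts with the same
convention). β and σ are profiled analytically; the REML criterion is
maximised over log δ. With one group the fit collapses exactly to OLS.

**LME with nested random intercepts.** One or two grouping factors (the
second nested in the first, e.g. monitoring period within trial, or fish
identity for repeated post-mortem measures). The marginal relative
covariance C = D + Σ (τ_k/σ)² Z_k Z_kᵀ is handled through the Woodbury
identity so all linear algebra runs in the q-dimensional random-effects
space; β and σ are profiled, and log(τ_k/σ) (clipped to ±8, so singular
fits surface as τ̂ ≈ 0 rather than errors) is optimised numerically.

**Penalized cubic regression spline ("GAMM-style") models.** The smooth is
a cubic B-spline basis with knots at covariate quantiles and an integrated
squared-second-derivative penalty. The penalty's null space (constant and
linear functions) joins the fixed effects; the penalized range is whitened
so the spline wiggles enter as iid Gaussian random effects whose variance —
the inverse smoothing parameter — is estimated by REML together with any
random intercepts. The basis dimension is selected by ML AIC using
effective degrees of freedom (trace of the influence matrix), not raw basis
size, over candidates (4, 5, 6, 8, 10, 12). The optional "VarPower"
residual structure Var(ε_i) = σ²|μ̂_i|^{2δ} is estimated by iterating the
variance optimisation against the fitted mean (|μ̂| floored at 1e-6; outer
loop capped at 10 iterations, convergence at a 1e-5 relative change in
fitted values). Reported smooth edf counts 1 for the linear part plus the
trace of the wiggle block, so a shrunk-to-linear smooth reports edf ≈ 1.

**Testing.** Fixed-effect significance uses Wald F tests for GLS fits
(F(q, n−p) reference) and likelihood-ratio tests otherwise. LRTs always
compare ML criteria; REML criteria are never compared across different
fixed-effect structures. The "vitality" style term-dropping rule refits
without a term whenever its p ≥ 0.05 and records the decision in an audit
record. Temporal autocorrelation structures are deliberately absent.

**Optimisation.** All variance parameters are optimised on the log scale by
Nelder-Mead simplex restarted from three fixed displacements (0, ±0.7),
with tolerances 1e-6 (parameters) and 1e-8 (criterion). On small instances
the optimum matches a dense brute-force (σ, τ) grid to better than 1e-3 in
log-likelihood, and nested fits reproduce lme4's REML criterion to 4
decimals on a frozen dataset.

## Generator defaults (the study conditions)

Trajectories: b* = b0 + rate·t + ε, t uniform on [0, min(duration,
window)], ε ~ N(0, σ²) with σ = 2.0 b* units. Per-trial rates are the
fitted values of the crowding model: −0.25 (Low), −0.82 (High), −0.20
(High & Prolonged) and +0.30 (Moderate) b* units per minute; controls are
flat. All baselines default to the control mean b* = 17.17 (trial-specific
baselines are plausible but unpublished, so the control value is reused).
Densities and durations follow the trial table (0.76–182.75 kg m⁻³;
13–112 min).

Cohort: b* = f(lactate) + u_trial + u_period(trial) + ε with a logistic
decreasing link from plasma lactate (upper asymptote 17.17, lower 6.0,
midpoint 6 mmol L⁻¹, steepness 0.8 — higher lactate, bluer skin), random
intercept SDs 1.0 and residual SD 2.0. Glucose and cortisol are generated
independent of colour, mirroring their lack of predictive value.

Post-mortem: fish baselines N(17.17, 1.0²); from 1 h after death the colour
has dropped by 5 b* units and stays level through 24 h; storage (light vs
dark) contributes nothing by default; residual SD 1.0 b* units. The drop
magnitude and the SDs are plausible values consistent with the reported
figure spreads; none is used as an acceptance truth.

Mortality: Binomial(n, p) draws per trial.

All generators are driven by a single integer seed and are bit-reproducible.

## Problem sizes

The packaged defaults keep every computation desk-scale: rate-recovery
experiments use 10 replicates of 40 fish per trial sampled over 15 min;
type-I calibration suites use 500 null replicates; the post-mortem
calibration uses 100 replicates of 15 fish × 4 timepoints; the CLI demo
renders 6 images per trial at 640 × 360 px. These sizes give Monte-Carlo
standard errors comfortably inside the tolerances being checked.

## Known limitations

* The colour pipeline assumes an sRGB-like capture chain; ICC profiles,
  chromatic adaptation between illuminants and RAW processing are out of
  scope.
* The 3×3 correction has no offset term; severe flare or black-level error
  would need the affine variant.
* The spline model supports one smooth covariate per fit and Gaussian
  responses only; no crossed random effects; no autocorrelation.
* VarIdent and VarPower are not combined within a single spline fit.
* The published field F/LRT statistics cannot be reproduced because the
  underlying field data are not distributed; recovery experiments on
  synthetic cohorts pinned to the published effect sizes stand in for them.
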