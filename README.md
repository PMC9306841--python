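# fishchroma

Calibrated photographic skin colourimetry and crowding-stress inference for
pelagic fish.

Atlantic mackerel (*Scomber scombrus*) shift skin colour from green towards
blue under crowding stress — a candidate real-time welfare indicator for
purse-seine fisheries. `fishchroma` provides the full quantitative pipeline
for studying this response:

* **Colour measurement** — sRGB decoding, exposure normalisation against
  the white photographic background, 3×3 colour-correction matrices fitted
  to a 24-patch calibration chart, CIE L\*a\*b\* conversion (D65), dorsal
  ROI extraction and Otsu masking of the dark stripes, and masked mean
  colour with audit fields. The blueness axis is b\* (blue −, yellow +).
* **Crowding density** — school volume from surface area by cone/pyramid
  geometry (V = A·d/3, depth by similar-shape scaling) and biomass/volume
  density in kg m⁻³ for a 149.17 m³ sea cage.
* **Inference** — from-scratch Wilson score intervals, GLS with per-group
  variance ratios (VarIdent), random-intercept LMEs (optionally nested),
  penalized cubic-regression-spline mixed models with power-of-mean
  variance (VarPower), REML/ML estimation, Wald-F and likelihood-ratio
  tests. The crowding model is b\* ~ trial × exposure; its per-trial slopes
  are the rates of colour change per minute of crowding.
* **Synthetic study generator** — striped dorsal scenes with known
  ground-truth CIELAB colour imaged through a distorting camera/flash
  model, calibration charts, b\* trajectories, physiology cohorts with a
  decreasing lactate→b\* link, post-mortem series and mortality counts, all
  seeded and bit-reproducible, so the whole pipeline is testable without
  any field data.

## Worked example

Simulate a study, measure every photograph and fit the full model suite:

```sh
fishchroma report --out demo --seed 11 --n-per-trial 6
```

This renders a chart and 30 fish images (5 trials × 6 fish), calibrates,
measures and writes `demo/report.json`. Key numbers from this exact run:

```text
trial          slope (b*/min)   SE
Control              +0.037   0.210
Low                  -0.092   0.192
Moderate             -0.023   0.204
High                 -0.963   0.175
HighProlonged        -0.441   0.236

trial x exposure Wald F = 5.03 (df 4), p = 0.0057
post-mortem: 1 h vs 0 h contrast = -5.24 b* units, time LRT p < 1e-19,
             storage LRT p = 0.37 (no storage effect)
mortality (Low trial, 0/231): Wilson 95% CI (0.00, 0.02)
```

The fitted High-trial slope (−0.96 ± 0.18) brackets the generating rate of
−0.82 b\*/min; a 6-fish-per-trial demo has wide slope SEs, which is why the
Low and Moderate slopes are indistinguishable from zero here. The
post-mortem model recovers the simulated 5-unit blue shift within an hour
of death and correctly finds no storage effect. Library use mirrors the
CLI:

```python
import fishchroma as fc

df = fc.simulate_trajectories(fc.default_scenarios().values(), 40, 15.0, seed=1)
spec = fc.DesignSpec(data=df, response="b",
                     fixed=("trial", "exposure_min", "trial:exposure_min"),
                     variance_groups="trial")
fc.trial_slopes(fc.fit_gls(spec))
```

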