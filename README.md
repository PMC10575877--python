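# thermocog

Bayesian spatiotemporal analysis of how monthly ambient temperature relates
to cognitive-function scores (MMSE) in older adults.

Epidemiological panel surveys of the elderly — the motivating case is a
Chinese longitudinal survey whose microdata are restricted — record each
subject's cognitive examination in a county and a calendar month. Linking
those examinations to county-month exposures (mean temperature,
precipitation, PM2.5) lets one ask how much cognition varies with ambient
temperature after the spatial and temporal structure of the data is
accounted for. This package implements that analysis end to end for
researchers in environmental epidemiology and spatial biostatistics, plus a
synthetic-data generator with known ground truth that stands in for the
restricted survey data.

## The model

For subject *i* examined in county *c*, study month *t* (month-of-year *m*),
the score is Gaussian with mean

```
score = α₀ + β₀·time + f(temp_ct)
      + (a_c + b_c·time)          # BYM county intercept (ICAR + iid), county slope
      + (a_m + b_m·time)          # cyclic RW1 month-of-year intercept and slope
      + (ζ_cm + ψ_cm·time)        # county × month interaction
      + ν_t                       # RW1 over the full study-month index
      + β₁·precip + β₂·PM2.5 + ε,   ε ~ N(0, σ²_ε)
```

* `f` is one of four candidate temperature-response bases — polynomial,
  cubic B-spline, natural cubic spline with 3 or 5 knots — compared by DIC
  (`D̄ + p_D`); the winner is re-used for the five sub-domain scores.
* The fitted `f` is reported as a **deviation-from-reference curve**
  `f(T) − f(T_ref)` (default reference −7 °C, the score optimum), with
  draw-wise 95 % credible bands that are exactly zero-width at the
  reference.
* **Interval effects**: within each temperature band (one cold band below
  the reference, four hot bands above) the model is refit with a linear
  temperature term; the per-1 °C score *decline* is signed so positive
  always means "worse as temperature moves away from the reference".
* **Displacement effects**: the temperatures of up to three preceding (lag)
  or following (lead) months enter jointly; the *overall effect* is the
  draw-wise sum of the current- and previous-month declines.
* **Heterogeneity**: subgroup overall effects `Q̂ ± SE` are compared with
  the indicator `|Q̂₁−Q̂₂| / √(SE₁+SE₂)` (≥ 2 ⇒ significant), implemented
  both as printed (`as_printed`) and in the conventional Wald form
  (`squared`); a sensitivity grid refits the overall effects under varied
  confounder combinations.

Inference: conditional on its variance components the model is a Gaussian
linear mixed model, so the package ships two engines — an empirical-Bayes
Gaussian approximation (`laplace`, default; analytic marginal-likelihood
gradients, optional hyperparameter integration) and a conjugate blocked
Gibbs sampler (`mcmc`). Structured blocks (ICAR, cyclic/linear RW1,
interactions) carry exact sum-to-zero constraints via null-space
reparameterization.

## Worked example

```
python analysis/01_simulate.py --seed 1       # synthetic study -> results/data/
python analysis/02_fit_curves.py --seed 1     # DIC selection + response curves
python analysis/03_interval_effects.py --seed 1
python analysis/04_displacement.py --seed 1
python analysis/05_heterogeneity.py --seed 1  # subgroups + sensitivity grid
```

`01_simulate.py` generates 2000 examinations across 40 counties (5×8 rook
lattice) and 36 months from an inverse-U response peaked at −7 °C, and
prints the descriptive quartile table:

```
 quartile  t_low  t_high  mean_score   n
        1 -13.45   -1.03       22.72 495
        2  -1.03    8.95       22.76 502
        3   8.95   17.69       22.18 503
        4  17.69   31.00       20.73 500
```

— scores are about 2 points lower in the hottest temperature quartile than
near the optimum. `03_interval_effects.py` then quantifies the per-degree
decline of the global score in each band:

```
  [ -13.5,   -7.0) cold  -0.007 (95% CI -0.359 to +0.345, n=161)
  [  -7.0,    5.0) hot   -0.033 (95% CI -0.147 to +0.081, n=670)
  [   5.0,   15.0) hot   +0.006 (95% CI -0.106 to +0.118, n=512)
  [  15.0,   25.0) hot   +0.275 (95% CI +0.150 to +0.400, n=559)
  [  25.0,   31.0) hot   +0.722 (95% CI +0.158 to +1.286, n=98)
```

The hot-side declines grow with temperature, as the concave generating
response implies: in the hottest band each additional °C costs ~0.7 score
points, while effects near the optimum are indistinguishable from zero.
`04_displacement.py` adds the lag structure (hot-regime overall effect
+0.61 per °C, 95 % CI −0.02 to +1.24 on this seed) and confirms that no
lead offset has a CI excluding zero — the generator contains no
anticipatory effect.

The library surface mirrors those steps: `generate_linked`,
`select_basis`, `curve_from_fit`, `interval_profile`, `displacement_fit`,
`subgroup_effects`, `heterogeneity_test`, `sensitivity_grid`. A single CLI
subcommand, `thermocog simulate --seed N --out-dir DIR`, exposes the
generator to the shell.

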