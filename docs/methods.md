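# Methods

## Model

One record is one MMSE examination of one subject, located in a county `c`
and a calendar month. The observation model is Gaussian:

```
y_i = η_i + ε_i,   ε_i ~ N(0, σ²_ε)
η_i = α₀ + β₀·time_i + f(T_ci,ti) + a_c + b_c·time_i + a_m + b_m·time_i
    + ζ_cm + ψ_cm·time_i + ν_t + β₁·precip + β₂·PM2.5
```

with `time` the study-month index centered at mid-study (so intercepts and
slopes decorrelate), `m` the month-of-year (1–12), and `t` the full study
month. Priors on the random-effect blocks:

| block | structure | constraint |
|---|---|---|
| county intercept | BYM: ICAR (Q = degree − adjacency) + iid | sum-to-zero per island; iid block overall |
| county slope | iid | sum-to-zero |
| month intercept/slope | cyclic RW1 over 12 months (December adjacent to January) | sum-to-zero |
| county×month interaction (ζ, ψ) | iid over all county×month pairs, row-major indexed | sum-to-zero |
| ν (global time) | linear RW1 over the study-month index | sum-to-zero |

Every precision (including 1/σ²_ε) carries a Gamma(1, 5·10⁻⁵) prior — the
weakly informative convention of hierarchical disease mapping; both shape
and rate are configurable (`HyperConfig`). Fixed effects are flat.

The *over-dispersion* term of the score model is the Gaussian residual
itself: with an identity link and Gaussian likelihood a record-level iid
Gaussian effect is not identifiable from observation noise, so σ²_ε plays
both roles. The `overdispersion` flag is accepted and recorded in
provenance but adds no second block.

Sum-to-zero constraints are imposed by reparameterization: each constrained
block `u = A v` with `A` an orthonormal basis of the zero-sum subspace
(per connected component for the ICAR block; singleton islands are pinned
to zero, their variation being absorbed by the iid component). The free
precision `A'QA` is nonsingular, so the joint conditional posterior of all
coefficients is a proper Gaussian. Reported block means therefore sum to
zero to machine precision.

## Inference engines

Conditional on the log precisions θ = (log σ², log τ₁, …) the model is a
Gaussian linear mixed model with closed-form conditional posterior
N(m(θ), P(θ)⁻¹), P = W'W/σ² + blockdiag(τ_b A'Q_bA).

**laplace (default).** Empirical Bayes: θ is set to the mode of the
marginal posterior (marginal likelihood × Gamma priors), found by L-BFGS-B
with analytic gradients (∂/∂τ_b uses tr(P⁻¹S̃_b) and the quadratic form in
m; one Cholesky plus one inverse per evaluation). Draws are taken from the
conditional Gaussian at the mode using *antithetic pairs* (m ± L⁻ᵀz), so
the sample mean equals the analytic posterior mean exactly — degenerate
checks (noiseless recovery, OLS equivalence) hold to machine precision
rather than Monte-Carlo tolerance. With `integrate_hyper=True` the engine
additionally propagates hyperparameter uncertainty: a finite-difference
Hessian at the mode gives a Gaussian approximation on the log scale, and
the posterior is an equal-weight mixture of conditional Gaussians at
sampled θ — improving interval calibration for weakly identified effects
at roughly 2× the cost. Bounds of ±12 on the log scale keep the
factorization well conditioned; a relative jitter retry guards the extremes.

**mcmc.** Blocked Gibbs with conjugate updates — (β, v) jointly Gaussian
given precisions, each τ_b Gamma given its block, σ² via its conjugate
update — warmup 300, 800 draws by default, a split-half stationarity check
on the noise chain reported in diagnostics. It is the fully Bayesian
reference for the empirical-Bayes engine and is cross-checked against it in
the tests.

Both engines are bit-reproducible given the seed, and both expose draws, so
every downstream quantity (curve bands, overall-effect sums, subgroup SEs)
is computed draw-wise; sums of correlated coefficients get their correlation
priced into the interval for free.

**DIC** is computed from draws: `D̄` the posterior-mean Gaussian deviance,
`p_D = D̄ − D(posterior means)`, `DIC = D̄ + p_D`.

## Temperature-response bases

Four candidates, all excluding the intercept column (absorbed by α₀) and
centered on the construction grid with the centering constants stored, so
curves re-evaluate the same affine columns on any grid:

* polynomial (default degree 3) — raw powers;
* cubic B-spline — boundary knots at the data range (so the span includes
  all linear functions over the observed temperatures), interior knots at
  the {5, 50, 95}% quantiles, first basis function dropped;
* natural cubic splines with 3 or 5 knots at equally spaced quantiles
  spanning the 5th–95th percentiles — built as cardinal natural
  interpolating splines with explicit linear continuation beyond the
  boundary knots, which makes the linear-tail property exact by
  construction (k knots → k−1 columns after dropping the redundant
  cardinal).

Degrees and knot placement are configurable; the fitted spec and centers
are recorded in `FitResult.provenance`.

## Effect summaries

*Response curve.* `deviation(T) = g(T) − g(T_ref)` computed draw-wise; the
reference row is taken out of the same matrix product, so the zero at the
reference (and its zero-width band) is exact, and pairwise contrasts are
reference-invariant to rounding error. The default reference is −7 °C for
every outcome; a second preset carries the per-outcome values printed in
the source study's results (−6, −2, −5, −3, −6 °C — five values for six
outcomes, with the global-score value also disagreeing with the methods'
−7 °C; both presets ship as published, the missing sixth value falling
back to −7 °C, and the discrepancy is not resolved here).

*Interval effects.* Bands are half-open `[low, high)` with the topmost
closed; membership is by current-month temperature; the full random-effect
structure is retained in each within-band refit (subset refitting, not a
constrained global model). Sign convention: hot side `decline = −β`, cold
side `decline = +β`, CIs transformed draw-wise, so a positive decline
always means scores worsen moving away from the reference.

*Displacement.* Offsets enter jointly (a distributed-lag design, not
one-at-a-time); lag and lead are separate models. The regime restriction
applies to the current-month temperature only. Default overall-effect
offsets are {0, 1} — current plus previous month — with the full 0..3 sum
available; the overall CI comes from summed draws. A collinearity warning
fires when offset temperatures correlate beyond 0.99.

*Heterogeneity.* Subgroup overall effects use the same displacement
machinery per level, SE = posterior sd of the summed decline draws. The
`as_printed` comparison rule √(SE₁+SE₂) sums standard errors unsquared —
dimensionally inconsistent, hence not scale-invariant — and is kept verbatim
as the default with a warning; the Wald rule √(SE₁²+SE₂²) is implemented
alongside and both appear in the outputs. No multiplicity correction is
applied across subgroup pairs. Age bands default to 65–80, 80–95, >95;
education and income use the generator's coarse low/medium/high levels; all
cut points are configuration.

## Synthetic data

The generator emulates the statistical structure the model assumes, not the
geography of any real survey:

* counties on a rook-adjacency lattice (connected, degree ≤ 4);
* monthly temperature = county gradient (3 °C per lattice row) + seasonal
  sinusoid (amplitude 16 °C, July peak) + N(0, 2²), affinely rescaled so
  the empirical range equals −14…31 °C, the span the source study reports;
  exposures extend 3 buffer months beyond the study span on each side so
  lag/lead windows are always complete;
* precipitation = 60 + 3·T + N(0, 15²) mm and PM2.5 = 55 − 0.8·T +
  N(0, 10²) µg/m³ — positive and negative temperature couplings
  respectively (continental winter pollution), unclipped so linear
  recovery checks are exact;
* subjects allocated to counties by a Dirichlet-weighted multinomial
  (concentration 1 → markedly uneven coverage), exam months uniform;
  covariates from fixed mixtures (55 % female, 60 % rural, 92 % Han, ages
  ~N(86, 8²) clipped to 65–110);
* scores from the model's own linear predictor. Default truth: α₀ = 24,
  β₀ = −0.005/month, response −0.003·(T+7)² (≈ −4.3 score at 31 °C versus
  the −7 °C optimum, the magnitude the source study reports), β_precip =
  −0.004/mm, β_pm25 = −0.01 per µg/m³; random-effect sds 0.5/0.3 (county
  structured/iid), 0.3 (month), 0.15 (interaction), 0.2 (ν), small nonzero
  time slopes, σ_ε = 3 (MMSE-scale individual variation). Structured
  effects are drawn exactly on their sum-to-zero subspaces via the
  eigenbasis of the constrained structure precision.
* Scores stay continuous by default; `clamp_scores=True` rounds and clips
  to 0–30 (with domain scores re-apportioned to preserve the sum) for
  realism demonstrations only, since clamping breaks the Gaussian model.
  Domain scores are a convex split (weights .2/.15/.25/.2/.2) of the global
  latent plus zero-sum noise, so they always sum to the global score.
* Alternative truth forms: piecewise-linear slopes (for interval
  sign-convention checks) and distributed lag weights (default 60/40 over
  offsets 0/1, for displacement recovery).

What passing tests therefore show: the estimators recover the parameters of
data that satisfy the model's own assumptions, at realistic scales and
noise levels, with calibrated intervals. What they cannot show: robustness
to features of the real survey the generator omits — bounded discrete
scores, informative missingness and attrition, survey weighting, real
county geography and migration, measurement error in the exposure linkage.

## Problem sizes and numerical choices

Replicated experiments use 40 counties × 36 months × 2000 records (the
recovery and coverage experiments; 50 replicates) and 20 counties × 24
months × 1500–2000 records (displacement and selection experiments; 10–30
replicates) — sizes chosen so a full experiment completes in minutes on one
CPU while keeping per-coefficient posterior sds a few times smaller than
the effects under test. Default draws 300–800. Quartile bins and interval
bands are left-closed/right-open with the last bin closed; basis-selection
ties break toward fewer columns, then declaration order; quantiles use
linear interpolation between order statistics.

One honest negative finding: at the source study's effect scale
(curvature −0.003) and MMSE-level noise (σ_ε ≈ 3), the four candidate
bases approximate one another to within ~0.04–0.13 score RMS over the
observed range, so the expected deviance gap (n·err²/σ² ≈ 1–3 even at
n ≈ 18,000) never dominates the parameter-count penalty: DIC selection
among them is statistically undetermined, and any winner is effectively
arbitrary. The basis-selection experiment in the test suite is therefore
powered a priori — curvature −0.01, σ_ε = 1.5, n = 2000, chosen from the
least-squares approximation errors so the expected gap (~15) is decisive —
and demonstrates that the selector prefers a quadratic-nesting basis when
the data can tell the candidates apart.

## Known limitations

* The Laplace engine is empirical Bayes; without `integrate_hyper` its
  intervals ignore hyperparameter uncertainty and can be slightly narrow
  for variance-dominated contrasts.
* β₀ (global linear time trend) and the RW1 ν block are softly confounded:
  a random walk can drift linearly, so only the sum constraint separates
  them and β₀'s posterior is wide by construction.
* The interaction uses independent pairs (the weakest structure consistent
  with a county-month interaction); spatially or temporally structured
  interaction types are out of scope.
* Inference assumes the Gaussian observation model; bounded/discrete score
  effects (ceiling at 30) are not modeled.
* The per-item MMSE weighting (six 2-point items in the attention domain,
  the rest 1 point) is a declared stand-in convention, not the survey
  instrument's actual scoring sheet.
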