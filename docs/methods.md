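# Methods

This note documents the statistical model, the numerical choices behind it,
what the synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The count model

Per lattice cell `i` (a 10 × 10 km square by default; the cell is the
analysis unit):

    O_i ~ Poisson(mu_i)
    log mu_i = x_i' beta + u_i + v_i

No exposure offset is used by default: cells are equal-area, and sampling
effort per cell is assumed equal (an optional log-offset column is
supported through `ModelData.offset`). Counts are modelled raw.

**Design.** Topographic (slope, hillshade, elevation) and proximity
(distance to urban areas, roads, railroads) covariates enter as empirical
quantile categories — quintiles by default, quartiles for aspect — with the
first category as reference; intervals are right-closed so boundary ties
fall in the lower category, deterministically. Land use is an 8-level
categorical (reference "other": urban, beaches, bare rock, burnt areas,
water) obtained by recoding a 22-class cover product through a mapping
table; the default table covers codes 1–22 and is configurable because
cover products differ. Temperature-variation covariates stay continuous
(there is no indication they should be categorized).

**Structured effect `u`.** A stationary smoothness-1 Matérn field
represented as a GMRF via the SPDE/finite-element construction. The mesh is
the lattice itself (nodes at cell centroids, squares split into right
triangles) — the analysis unit is the cell, so a finer mesh would only add
projector bookkeeping. The mass matrix is lumped (diagonal), giving the
standard sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G),
    kappa = sqrt(8)/rho,  sigma^2 = 1 / (4 pi kappa^2 tau^2).

`rho` is the distance at which correlation falls to ~0.14
(`r(d) = kappa d K_1(kappa d)`). The lattice is padded with 2 rings of
ghost nodes so boundary variance inflation stays off the real cells; the
test suite checks interior marginal variance within [0.85, 1.15] of nominal
and implied correlations within 0.05 of the closed form at rho/2, rho and
2 rho on a 40 × 40 lattice.

**Unstructured effect `v`.** iid Gaussian, capturing cell-specific
heterogeneity (unobserved time-invariant confounders without spatial
pattern).

**Priors.** PC priors throughout: on the field, `P(rho < rho_0) = 0.5`
with `rho_0` = one fifth of the lattice diameter and `P(sigma > 1) = 0.01`;
on the iid sd, exponential with `P(sd > 1) = 0.01`. Coefficients get
independent N(0, 5²) priors on the log scale (weakly informative — a ±10
fold effect sits within one prior sd). All are configurable; the defaults
are deliberately conservative because PC priors shrink toward the simpler
no-field / no-heterogeneity base model.

**Identifiability.** The intercept and the field mean are confounded, so a
soft sum-to-zero constraint (mean of `u` over real cells ~ N(0, 0.001²))
pins the field level. Consequence: the fitted intercept absorbs the
*realized* mean of the generating field in simulations, and almost no cell
sits in the reference category of every covariate simultaneously, which
leaves a weakly-identified "level versus dummy blocks" direction. Recovery
checks therefore assess contrast coefficients against truth directly, and
the level through the mean linear predictor (which the counts identify
sharply).

## 2. Inference

Default (`method="laplace"`) is a nested Laplace approximation in the
spirit of INLA:

1. For fixed hyperparameters `theta = (rho, sigma, sd_iid)` the latent
   vector `(beta, u, v)` has a log-concave conditional posterior; its mode
   is found by damped Newton iterations (step-halving line search, linear
   predictor clipped at |log mu| = 30) and the Gaussian approximation at
   the mode is used for latent draws.
2. The Laplace-approximated marginal posterior of `theta` is maximised on
   the log scale (Nelder–Mead; warm-started inner Newton). Hyperparameter
   spread is reported from a finite-difference curvature at the mode
   (log-normal approximation); if the curvature is not positive definite a
   point mass is reported and flagged in the diagnostics.

`method="mcmc"` replaces step 2 with an independence Metropolis sampler:
a multivariate-t proposal (df 4, scale = 1.5 × the curvature-based
covariance) centred at the mode. An independence sampler is used rather
than a random walk because the 3-dimensional hyperparameter posterior is
smooth but has a heavy-tailed range direction and a
"field-absorbs-overdispersion" ridge on small lattices, where random-walk
chains mix an order of magnitude more slowly. Split-chain R-hat is
computed per hyperparameter and the fit **fails loudly** above 1.05. One
latent draw is taken per retained `theta`, so latent posteriors include
hyperparameter uncertainty under this method. The test suite checks that
both methods agree on synthetic data within Monte-Carlo error.

Factorisations are dense (Cholesky): at the package's target sizes (a few
thousand latent dimensions) dense solves are faster than sparse machinery,
and the sparse precision is still built and exposed (Markov structure is
tested and exportable). This bounds practical lattice sizes at roughly
60 × 60; beyond that a sparse Cholesky would be needed.

**Reported quantities.** Relative risks are summarised draw-wise
(`mean(exp(draws))`, never `exp(mean)`), with 2.5/5/50/95/97.5% quantiles —
the 5/95% pair supports 90%-interval statements. The excess surface is the
draw-wise posterior of `exp(u_i + v_i)`.

## 3. Temperature statistic, trend, and interpolation

* **Variation statistic:** difference from the same calendar day one year
  earlier; Feb 29 is dropped (it has no previous-year counterpart); missing
  values are skipped, not imputed. Averages are reported per meteorological
  season (MAM/JJA/SON/DJF — month-based strata) and annually, with pair
  counts.
* **Trend model:** `temperature = station intercept + one annual harmonic
  pair (configurable) + linear trend + iid noise`, fit as an exact
  conjugate Bayesian linear regression under the Jeffreys reference prior;
  the trend's marginal posterior is Student-t, so credible intervals are
  closed-form. Trends are reported in °C/yr and °C/5 yr only; "annualized
  percentage" formulations are not computed because their baseline is not
  well defined.
* **Kriging:** Gaussian-process prediction under a smoothness-1 Matérn
  covariance plus nugget, with the constant mean estimated by GLS and then
  treated as fixed (simple kriging on residuals). This keeps the
  conditional sd at 0 on stations when the nugget is 0 and never above the
  prior sd. Hyperparameters are user-supplied or maximum-likelihood
  estimated (Nelder–Mead on the log marginal likelihood).

## 4. Synthetic-data generator

The generator produces data with exactly the structure the inference
assumes — which is the point: it makes every stage testable with known
truth, and it defines the conditions of the recovery experiments.

Defaults (one global seed split into named substreams so stages regenerate
independently and runs are byte-reproducible):

| quantity | default | rationale |
|---|---|---|
| stations | 190, uniform over the lattice box | study network size; no station geometry is prescribed |
| period | 2007-01-01 – 2011-12-31 daily | study period (1826 days) |
| trends | 0.159 / 0.332 °C per 5 yr (max/min) | the published 5-year magnitudes, used as injection values |
| seasonal cycle | single annual harmonic, amplitude 8 °C, peak mid-July | Mediterranean annual swing; monthly heterogeneity is not modelled |
| station field | Matérn, range 60 km, sd 1.5 °C | smooth regional differences between stations |
| daily noise | iid 2.0 °C | residual day-to-day variability after season and station level |
| lattice | 20 × 20 cells at 10 km | study cell size |
| covariates | slope half-normal(8°), aspect/hillshade uniform [0,360), elevation gamma(2, 300 m), distances lognormal, land use categorical with forest-heavy shares | only the quantile boundaries matter downstream; shapes chosen to look like Mediterranean terrain summaries |
| count model | intercept log 150; field range 30 km, sd 0.5; iid sd 0.2 | ~150 species/cell across the four vertebrate groups; moderate clustering and heterogeneity |

What the generator does **not** emulate: real geography (station clustering
in valleys, coastal gradients), spatially correlated covariates, land-use
spatial contiguity, observation effort differences between cells, temporal
change in counts, and space–time interaction in temperatures. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions — not robustness to the ways
real survey data violate them.

## 5. Recovery experiments and their noise floor

The acceptance surface is parameter recovery: published magnitudes are
injected as generating values and must be recovered within posterior
uncertainty (3 posterior sds), with interval-coverage checks over
replicates (≥ 18/20 for the trend model, ≥ 24/30 for the count model on
10 × 10 replicates).

Single-realization recoveries have an irreducible Monte-Carlo spread worth
stating explicitly (the script reports one realization per target, as the
protocol prescribes):

* Trend, 40 stations × 5 years, daily noise 2 °C → posterior sd ≈ 0.026 °C
  per 5 years. Recovered values typically land within ±0.05 of the
  injected 0.332 / 0.159.
* Land-use contrast on a 20 × 20 lattice with field sd 0.5 and iid sd 0.2
  → posterior sd ≈ 8–11 percentage points on the excess scale. A recovered
  "38.4%" effect can honestly read anywhere in roughly 25–50% for a single
  seed; the 4.2% proximity deficit is small relative to this floor, so its
  recovered value is dominated by realization noise even though it stays
  within the stated 3-posterior-sd criterion.

## 6. Numerical details and degenerate inputs

* Quantile categorization requires ≥ k distinct values; constant input is a
  degenerate-input error, ties collapsing a boundary likewise.
* `GeneratorConfig` validates sds ≥ 0, spacing > 0, ≥ 4 cells, date order;
  |log mu| > 30 during generation raises a generation error (pathological
  coefficients).
* Kriging with duplicate station coordinates and zero nugget raises a
  conditioning error (singular covariance), as does a non-SPD assembled
  precision.
* The trend design is checked for rank deficiency (condition number of the
  normal equations); single-day data fail it.
* Newton iterations: relative step tolerance 1e-8, ≤ 60 iterations, ≤ 30
  step halvings; Nelder–Mead on hyperparameters: xatol 0.01 on the log
  scale, default ≤ 150 evaluations.

## 7. Known limitations

* Dense factorisation bounds lattice size (~60 × 60 practical on one CPU).
* Empirical-Bayes Laplace (the default) conditions latent draws on the
  hyperparameter mode; coefficient intervals can be slightly narrow when
  hyperparameters are poorly identified (the `mcmc` method propagates that
  uncertainty; calibration is tested).
* Smoothness is fixed at nu = 1; no irregular meshes, no non-stationarity.
* The aspect variable is treated in degrees throughout. Source tables that
  mix units for slope/aspect thresholds (percent vs degrees, and a
  metre-valued aspect threshold) cannot be reproduced verbatim; quantile
  boundaries are always computed from the data at hand.
* Seasonal variation covariates can be kriged per season
  (`krige: seasonal: true`) or annually; which feeds the regression is a
  config choice, not a recommendation.
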