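# ecolattice

Bayesian spatial ecological regression of species counts on a regular
lattice, together with the station-temperature analysis that feeds it:
a year-over-year daily temperature-variation statistic, a multi-year trend
model, and kriging of station summaries onto lattice cells.

The package is aimed at ecologists and spatial epidemiologists who model
species richness (or other counts) per grid cell against land use,
topography, proximity-to-anthropic-areas and climate covariates, while
adjusting for spatial clustering from unobserved confounders.

## The model

For cell *i* of a regular lattice, the observed species count is

    O_i ~ Poisson(mu_i),    log mu_i = x_i' beta + u_i + v_i

* `x_i` — intercept, quantile-categorized covariates (quintiles by
  default, quartiles for aspect; first category is the reference), an
  8-level land-use categorical, and optional continuous temperature
  covariates;
* `u` — spatially **structured** random effect: a smoothness-1 Matérn
  Gaussian Markov random field constructed with the SPDE/finite-element
  approach on the lattice itself (precision
  `Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)`, `kappa = sqrt(8)/rho`),
  with penalised-complexity (PC) priors on its range `rho` and marginal
  standard deviation `sigma`;
* `v` — **unstructured** iid Gaussian heterogeneity with a PC
  (exponential) prior on its standard deviation.

Inference is a nested Laplace approximation (optionally an independence
Metropolis sampler over the hyperparameters with conditional Gaussian
latent draws). Effects are reported as relative risks `rr = exp(beta)` with
2.5/5/50/95/97.5% credible quantiles, plus a per-cell excess surface
`exp(u_i + v_i)` (1 = as many species as the covariates predict).

The temperature side defines the variation statistic for day *k* of year
*t* as `T(k,t) - T(k,t-1)` (same calendar day one year earlier, Feb 29
dropped), averaged per season and annually, and fits
`temperature = station intercept + annual harmonic + linear trend` as an
exact conjugate Bayesian regression, reporting the trend in °C per year
and per 5 years with credible intervals.

## Worked example

```python
import numpy as np
from ecolattice import simulate, model

cfg = simulate.GeneratorConfig(
    lattice_nx=20, lattice_ny=20,
    beta={"intercept": float(np.log(150)),
          "landuse8[dense_forest]": float(np.log(1.384))},
    seed=3,
)
cells = simulate.generate_lattice(cfg)
counts, truth = simulate.generate_species_counts(cells, cfg)
cells["species_count"] = counts.to_numpy()

data, schemes = model.model_data_from_cells(cells)
fitted = model.fit(data, model.ModelSpec(n_draws=1000, seed=1))
rr = model.relative_risks(fitted)
print(rr[rr.category == "dense_forest"]
      [["rr_mean", "rr_q2.5", "rr_q97.5", "excess_pct"]].round(3).to_string(index=False))
```

prints

```
 rr_mean  rr_q2.5  rr_q97.5  excess_pct
   1.495    1.291     1.732      49.464
```

i.e. cells under dense forest hold an estimated 49% (CrI 29%–73%) more
species than reference-land-use cells — the generating value was 38.4%,
within one posterior standard deviation of the estimate for this
realization. The same `fitted` object yields the hyperparameter posteriors
(`fitted.hyper`), the per-cell excess surface (`model.excess_surface`),
and convergence diagnostics (`fitted.diagnostics`).

The same pipeline is scriptable from the shell:

```bash
ecolattice simulate --config config.yaml --seed 7 --out sim/
ecolattice temp-trend --stations sim/stations.csv --out trend/
ecolattice interpolate --stations sim/stations.csv --cells sim/cells.csv --out interp/
ecolattice fit --cells sim/cells.csv --config config.yaml --out fit/
ecolattice report --fit-dir fit/
```

Every output CSV carries the seed and config hash of the run that produced
it, and each stage writes a plain-text manifest.

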