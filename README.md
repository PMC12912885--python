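# flywaybench

Benchmarking population-size and trend estimation for incomplete
site × year count panels, as produced by large citizen-science waterbird
censuses.

Counts from such schemes are hard to model: most site-years are zero, the
variance dwarfs the mean, nearby sites are correlated, and 7–26% of cells
are missing — often *not at random*, because whether a site is surveyed can
depend on how many birds it holds. Analysts nevertheless need two numbers
per species: an annual population size index and its trend. This package
provides, as a tested library,

- a **synthetic panel generator** with known ground truth (trend,
  dispersion, zero inflation, spatial field, missingness),
- four **sampling-design perturbations** mimicking realistic monitoring
  biases (drop the largest 10% of sites, the smallest 10%, or shift effort
  between them over time),
- four **modeling approaches**: a simple Poisson mixed model; an
  *optimized* mixed model that selects among ten count families and five
  spatial structures by residual diagnostics; a TRIM-style log-linear
  imputation model with quasi-Poisson overdispersion σ² and serial
  correlation ρ; and LORI, a nuclear-norm-penalized low-rank Poisson
  matrix model with multiple imputation,
- the **diagnostics** (simulation-based dispersion and zero-inflation
  tests, Pearson overdispersion χ², observed-vs-expected-zeros χ², Moran's
  I on site-level residuals), and
- the **outputs**: annual index with 95% CI, OLS trend (absolute and per
  1000 individuals, slope standardized as 1000·slope/mean index), RRMSE,
  and a design × method comparison report.

The mixed models are fitted by an in-house Laplace-approximation engine
(site random intercept plus optional grid-cell intercept, 2-D coordinate
smooth, or a knot-based Gaussian random field with estimated range/SD and
an optional physical barrier). LORI CIs use Rubin's rules over m
imputations: V = W + (1 + 1/m)·B, CI = estimate ± 1.96·√V.

## Worked example

```python
import numpy as np
import flywaybench as fb

sites = fb.generate_sites(60, seed=8)
panel, _ = fb.generate_counts(sites, beta0=np.log(20.0), beta_year=0.02,
                              site_sd=0.6, family_id="nb2", dispersion=0.5,
                              seed=9)

from flywaybench.diagnostics import dispersion_test_sim, zero_inflation_test_sim
for family in ("poisson", "nb2"):
    fit = fb.fit_glmm(panel, family)
    od = dispersion_test_sim(fit, panel, n_sims=250, seed=10)
    zi = zero_inflation_test_sim(fit, panel, n_sims=250, seed=11)
    print(family, round(od.statistic, 2), round(od.p_value, 3),
          round(zi.statistic, 2), round(zi.p_value, 3))
```

prints

```
poisson 40.45 0.008 118.47 0.008
nb2 0.99 0.908 0.99 0.813
```

The dispersion statistic is the ratio of observed to expected
Pearson-residual variance and the zero-inflation statistic the ratio of
observed to expected zero counts (1 = perfect agreement): the Poisson fit
on this overdispersed panel is off by a factor 40 (dispersion) and 118
(zeros), both significant, while the NB2 fit of the same data sits at 0.99
with large p-values — exactly the signal the optimized-model selection
uses to walk its family list. The `examples/` directory has one short
script per capability (generation, designs, fitting and diagnostics,
two-stage selection, TRIM totals, LORI imputation, the full benchmark),
each printing what it computes and what the numbers mean.

A thin CLI wraps the orchestration for shell use:

```bash
flywaybench generate --n-sites 60 --family nb2 --seed 1 --out panel_out
flywaybench run --config config.yaml --seed 1 --out run_out
```

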