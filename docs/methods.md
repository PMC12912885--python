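# Methods

`flywaybench` benchmarks four ways of estimating wintering-waterbird
population sizes and trends from incomplete site × year count panels. This
note records the models, the numerical choices, and what the synthetic data
do and do not emulate.

## The data problem

Mid-winter census panels (one count per site per year) have four structural
features that break naive count models: a large fraction of zeros (the
median count per site is 0 for many species), extreme overdispersion (count
SD an order of magnitude above the mean), spatial dependence along the
flyway, and 7–26% missing site-year cells — with the worrying missingness
being *not at random* (whether a site is surveyed can depend on how many
birds it holds). Panels obey a zero-generation rule: zeros exist only at
sites where the species was seen at least once, and sites with fewer than 15
surveys in the 26-year window are dropped before analysis.

## Synthetic panels

The generator draws

```
log mu_it = beta0 + beta_year (t - t_bar) + u_i + s(lon_i, lat_i)
u_i ~ N(0, site_sd^2),   s ~ GP(0, spatial_sd^2 exp(-d / spatial_range))
```

and counts from one of {Poisson, NB1, NB2, Tweedie, zero-inflated NB2}
around `mu_it`; structural zeros are injected per cell with probability
`zi_prob`; cells are masked MCAR at `mcar_rate`; sites that never record a
positive are dropped (zero-generation rule re-enforced after masking).
`TruthRecord` stores the generating parameters and the realized expected
yearly totals `sum_i E[count_it]`, which real data cannot provide and which
make recovery and coverage tests possible.

Defaults: a 10° × 40° lon/lat band (flyway-shaped elongation), 26 annual
occasions (1995–2020), site counts in the tens to low hundreds. The spatial
field is drawn exactly by dense Cholesky (O(n³); intended for ≤ ~2000
sites). Tweedie counts use the compound Poisson–Gamma construction rounded
to integers, because panels are integer-valued by contract.

What the generator does *not* emulate: observer effort and detectability,
habitat covariates, temporally autocorrelated abundance beyond the linear
trend, non-stationary spatial structure, and the real network's irregular
site geometry. Tests passing on these panels therefore demonstrate
correctness of the estimators under their own assumptions, not performance
on real census data.

## Sampling designs

Four panel → panel transforms mimic realistic monitoring biases: `raw`
(identity), `larger_out` / `smaller_out` (remove the `floor(0.10 n)` sites
with the highest / lowest mean observed counts; ties broken by site id),
and `unbalanced` (convert to missing `round(0.20 × eligible)` observed cells
of high-mean sites — mean above the 0.75 quantile, type-7 interpolation,
strict inequality — in the early half of the series, and of low-mean sites
below the 0.25 quantile in the late half). The 20% conversion is pooled
across eligible cells by default; a `per_site` flag stratifies it within
sites, since either reading of "20% of the counts" is defensible. Transforms
never create counts: surviving observed cells are bit-identical to input.

## The four modeling approaches

**Simple GLMM.** Poisson log-link with year (numeric, standardized
internally) as fixed effect and a site random intercept — the first model an
ecologist would try.

**Optimized GLMM.** The same backbone with (stage 1) the count family chosen
from a fixed priority order — Poisson, NB1 (Var = φμ), NB2 (Var = μ +
μ²/θ), Tweedie (power p ∈ (1,2)), then six hurdle variants (lognormal,
Gamma, truncated NB1, truncated NB2, and the two Poisson-link forms) — and
(stage 2) a spatial structure from: none, 100-km grid-cell random
intercept, a 2-D coordinate smooth, a Gaussian random field (mesh cutoffs
0.5° then 1.0°), and the field with a physical barrier. Stage 1 keeps the
first converged family whose dispersion and zero-inflation tests are both
non-significant at α = 0.05; if none, the fallback ranks converged
candidates by distance of the dispersion ratio from 1, then the
zero-inflation ratio (statistics, not p-values — scale-free and
monotone in the violation), ties broken by priority order. Stage 2 keeps
`none` if Moran's I is already non-significant, else the first structure
that makes it so, else the minimal |I|. The final model is re-diagnosed,
because adding a spatial term can reintroduce dispersion or zero problems.

*Estimation.* Random effects are integrated out by a Laplace approximation:
an inner Newton solve profiles the random-effect vector (sparse design,
dense Cholesky of the q × q curvature), and L-BFGS-B optimizes the outer
parameters (fixed effects, log random-effect SDs, dispersion, spatial
range), followed by up to four damped Newton polish steps on
central-difference derivatives — quasi-Newton with numerical gradients
stops on function change and can leave a sizeable score, and the polish
also yields the outer Hessian used for standard errors and index CIs.
Hurdle families are fitted as two parts (presence, then positives); the
Poisson-link variants use a complementary-log-log presence model whose
linear predictor enters the positive part as an offset via the mean
rescaling μ⁺ = n·w/p, so the expected count is n·w. A joint two-part
estimation would share information between stages but is not needed for the
contracts here. Tweedie densities are evaluated by the compound
Poisson–Gamma series in log space with adaptive truncation (relative
tolerance 1e-8), with the power bounded to [1.1, 1.9]: near p → 1 the
series needs unboundedly many terms while the family degenerates to
quasi-Poisson. Tweedie inner steps use the exponential-dispersion-family
score and Fisher weights.

*Sanity checks.* A fit reports gradient_ok (max |outer score| < 1e-3,
tunable), hessian_pd / se_finite (finite-difference Hessian invertible with
positive diagonal), and params_in_bounds (no variance or dispersion pinned
at an optimizer bound). `converged` is deliberately weaker than
`sanity.passed`; selection skips non-converged candidates and records them.

*Spatial structures.* Grid cells come from a local equirectangular
projection at the panel's mean latitude (the cell size is stated in km but
no projection is canonical). The coordinate smooth is a low-rank Gaussian
radial basis at ~30 farthest-point knots whose coefficients are iid random
effects — the standard smoothing-penalty ↔ random-effect equivalence, with
the penalty weight estimated by marginal likelihood instead of GCV. The
Gaussian field is a knot-based (predictive-process) approximation with
exponential covariance; knots are a greedy thinning of site coordinates at
the mesh cutoff; range and SD are estimated. The barrier variant removes
knot-graph edges that cross the barrier polyline and replaces euclidean by
graph-geodesic distances; since a geodesic exponential kernel need not be
positive definite, the spectrum is clipped at a small floor.

**TRIM-core.** Log-linear Poisson model with site and year-factor effects
(first year fixed at 0), optionally relaxed to quasi-Poisson (Var = σ²μ, σ²
estimated as Pearson X²/df) and lag-1 serial correlation within sites
(working AR(1) correlation ρ^|Δt|, ρ from pooled adjacent-year Pearson
residual products; pairs with a missing member skipped), iterated
estimating equations to relative change < 1e-8 (≤ 200 iterations). Missing
cells are imputed with fitted means; time totals sum fits over all sites,
with delta-method SEs from the model-based covariance times σ̂². The
two-step rule fits with both options on, then disables overdispersion if
σ̂² < 1 and/or serial correlation if ρ̂ < 0.2 and refits. An optional region
map adds region-specific year effects (region × year interaction — a region
main effect alone would be absorbed by the site effects).

**LORI-core.** Penalized Poisson model for the full matrix: intercept, row
and column main effects, covariates (standardized year, longitude,
latitude), and a site × year interaction matrix Θ under a nuclear-norm
penalty, with ridge (default; L1 not implemented — the proximal step stays
closed-form) on mains and covariates. Proximal gradient descent with
backtracking guarantees a monotone objective; the Θ-step is singular-value
soft-thresholding. Stopping: relative objective change < 1e-8 or 500
iterations; because the first-order method can be slow near the optimum, a
completed monotone descent is treated as usable downstream even when the
tolerance was not hit. Penalty selection offers K-fold cross-validation on
masked observed cells and a null-quantile rule (0.95 quantile of the
spectral norm of the interaction gradient under mains-only simulation).
Missing cells are completed by multiple imputation: each of m imputations
reweights observed cells by a nonparametric bootstrap, refits (warm-started)
and draws missing cells from the fitted Poisson; observed cells are never
altered. Rubin's rules combine per-year totals: V = W + (1 + 1/m)·B, 95% CI
= estimate ± 1.96·√V. The bootstrap perturbation is this package's choice of
between-imputation variability generator; it is distribution-free and
testable, but not asserted to reproduce any particular reference
implementation's CI widths.

## Diagnostics

*Dispersion and zero inflation* are simulation-based ratio tests: the
statistic is observed/expected Pearson-residual variance (respectively zero
count), the p-value the two-sided Monte-Carlo rank among n_sims = 250
replicates with the (r+1)/(n+1) tie convention. Replicates are a parametric
bootstrap: every random-effect block is redrawn from its fitted
distribution, responses simulated from the fitted family, and the
conditional modes *re-predicted* on the replicate (fixed effects and
dispersion held), so replicate statistics undergo the same shrinkage as the
observed one. Conditioning instead on the estimated modes over-rejects
(observed data carry random-effect prediction error that such replicates
lack; measured 12.5% at α = 5%). The zero-inflation p-value uses the
excess-zero pivot — zeros minus their model expectation under the
(re)fitted means — because raw zero counts are not exchangeable between the
data and plug-in replicates (measured 0% rejection). With these
constructions both tests sit at 4–5% rejection under the null with full
power against θ = 0.3 overdispersion and 50% structural zeros.

*Moran's I* uses inverse great-circle-distance weights (zero diagonal;
coincident sites capped at the smallest positive distance), the analytic
expectation −1/(n−1) and the randomization variance with a normal
approximation; a numerically degenerate variance (n = 3 equal weights)
reports p = 1. For the mixed models the per-site residual input averages
observed-minus-expected where the expectation redraws the iid site
intercepts while conditioning on fitted spatial terms: conditioning on the
estimated intercepts would absorb an unmodeled field into them and blind
the test (measured p ≈ 0.67 under a strong field), whereas redrawing keeps
the spatially structured signal visible until a structure captures it
(measured false-positive rate 3% without a field). For TRIM and LORI the
input is the plain per-site mean of observed minus fitted.

*For the imputation models*, overdispersion uses the Pearson chi-square
(X²/df against χ²_df) and zero inflation the 2×2 zero/non-zero
cross-tabulation of observed data against rounded fitted data
(1-df chi-square, 0.5 continuity guard on degenerate margins). The exact
2×2 construction is this package's documented choice; other tabulations of
"observed vs expected zeros" exist.

## Indices, trends, errors

The population index is the per-year sum of expected counts over all sites
(missing cells included). Mixed-model CIs draw the outer parameters from
N(θ̂, Ĥ⁻¹) per part and recompute totals with random effects held at their
conditional modes — re-predicting modes per draw would be more complete but
is out of desk-scale budget; TRIM CIs are delta-method; LORI CIs come from
Rubin's rules. The trend is unweighted OLS of the index on calendar year
with a t-based 95% CI; the standardized slope is 1000·slope/mean(index)
("annual change per 1000 individuals" — the normalization by the mean index
is this package's definition). RRMSE is RMSE over observed cells divided by
the mean observed count (switchable to SD normalization); it is 0 iff the
fit reproduces every observed cell.

## Problem sizes

The test-suite and acceptance-script simulations run at: diagnostic
calibration 200 panels (suite) / 100 panels (script) of 50 sites × 26
years; selection 50 / 30 seeds; spatial mitigation 25 / 15 seeds at 80
sites; TRIM σ² recovery 50 / 30 seeds at 40 sites; design effects one
80-site panel × 4 methods × 3 designs; trend recovery 50 / 30 seeds at 100
sites × 26 years. These are the package's chosen desk-scale study
conditions; rates and tolerance bands are fixed independently of them.

## Known limitations

- The Laplace approximation is not exact for small per-site information;
  with 26 occasions per site its bias is negligible here, but very sparse
  panels would need quadrature.
- Hurdle parts are estimated sequentially, not jointly; standard errors of
  the positive part ignore presence-part uncertainty.
- The Gaussian-field approximation is low-rank; very short-range fields
  (below the knot spacing) are under-resolved by construction.
- The index CI for mixed models propagates outer-parameter uncertainty
  only; random-effect re-prediction uncertainty is omitted, so coverage can
  dip below nominal for panels dominated by few sites.
- Quasi-likelihood families, random year slopes, nonlinear (smooth) year
  effects, detectability correction and environmental covariates are out of
  scope.
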