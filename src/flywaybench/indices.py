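"""Population-size indices, trend estimates, and error metrics.

The population size index of a fitted model is the per-year sum of
site-level expected abundances over *all* sites (missing cells contribute
their model value).  The trend is the ordinary-least-squares slope of the
annual index on calendar year, reported both in individuals per year and
standardized per 1000 individuals (1000 x slope / mean index).  Model error
is summarized by the relative root mean squared error (RRMSE): RMSE over
observed cells divided by the mean observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glmm import FitResult, _expected_grid, _outer_covariance
from .panel import CountPanel

__all__ = ["AnnualIndex", "TrendEstimate", "MetricValue", "glmm_index",
           "trend_from_index", "rrmse", "percent_difference", "compare_methods",
           "BenchmarkReport"]

log = logging.getLogger(__name__)


@dataclass
class AnnualIndex:
    """Per-year estimated total population with 95% CI."""

    method_id: str
    years: np.ndarray
    totals: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    ci_available: bool = True

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.totals = np.asarray(self.totals, float)
        self.lo95 = np.asarray(self.lo95, float)
        self.hi95 = np.asarray(self.hi95, float)
        if not (len(self.years) == len(self.totals) == len(self.lo95) == len(self.hi95)):
            raise ValueError("years, totals and CI bounds must be aligned")
        fin = np.isfinite(self.lo95) & np.isfinite(self.hi95)
        if fin.any() and not np.all((self.lo95[fin] <= self.totals[fin] + 1e-9)
                                    & (self.totals[fin] <= self.hi95[fin] + 1e-9)):
            raise ValueError("CI bounds must bracket the point totals")


@dataclass(frozen=True)
class TrendEstimate:
    """OLS trend of the annual index on calendar year."""

    slope: float
    slope_se: float
    ci95: tuple[float, float]
    slope_per_1000: float
    intercept: float

    def __post_init__(self) -> None:
        if np.isfinite(self.ci95[0]) and not self.ci95[0] <= self.slope <= self.ci95[1]:
            raise ValueError("ci95 must contain the slope")


@dataclass(frozen=True)
class MetricValue:
    metric_id: str
    value: float
    n_cells: int


def glmm_index(fit: FitResult, panel: CountPanel, n_draws: int = 500,
               seed: int = 0) -> AnnualIndex:
    """Annual index from a mixed-model fit, with parameter-draw 95% CI.

    Totals sum the fitted expected counts over all sites.  The CI draws the
    outer parameters (fixed effects, log-SDs, dispersion) of each model part
    from their approximate Gaussian sampling distribution, holding the random
    effects at their conditional modes, and takes 2.5/97.5 percentiles of the
    recomputed totals.
    """
    if not fit.converged:
        raise ValueError("index requires a converged fit")
    totals = fit.fitted_means.sum(axis=0)
    rng = np.random.default_rng(seed)
    fid = fit.family.family_id
    covs = []
    ok = True
    for part, objective in zip(fit.parts, fit.objectives):
        cov = part.cov
        if cov is None:
            cov = _outer_covariance(part, objective)
            part.cov = cov
        if not np.all(np.isfinite(np.diag(cov))):
            ok = False
        covs.append(cov)
    if not ok:
        log.warning("glmm_index: singular information; CI flagged unavailable")
        nan = np.full_like(totals, np.nan)
        return AnnualIndex("glmm", fit.years.copy(), totals, nan, nan, ci_available=False)

    draws = np.empty((n_draws, len(fit.years)))
    saved = [p.theta.copy() for p in fit.parts]
    chols = []
    for cov in covs:
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        chols.append(v @ np.diag(np.sqrt(np.clip(w, 0, None))))
    for d in range(n_draws):
        for part, th0, L in zip(fit.parts, saved, chols):
            part.theta = th0 + L @ rng.standard_normal(len(th0))
        mu = _expected_grid(fid, fit.parts, fit._grids)
        draws[d] = mu.reshape(fit.panel_shape).sum(axis=0)
    for part, th0 in zip(fit.parts, saved):
        part.theta = th0
    lo = np.quantile(draws, 0.025, axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    return AnnualIndex("glmm", fit.years.copy(), totals,
                       np.minimum(lo, totals), np.maximum(hi, totals))


def trend_from_index(index: AnnualIndex) -> TrendEstimate:
    """Unweighted OLS of totals on calendar year with a t-based 95% CI."""
    years = index.years.astype(float)
    y = index.totals
    n = len(years)
    if n < 3:
        raise ValueError("need >= 3 years for a trend")
    if years.var() == 0:
        raise ValueError("zero variance in years")
    xbar, ybar = years.mean(), y.mean()
    sxx = float(np.sum((years - xbar) ** 2))
    slope = float(np.sum((years - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * years)
    s2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    tq = stats.t.ppf(0.975, n - 2)
    return TrendEstimate(
        slope=slope, slope_se=se, ci95=(slope - tq * se, slope + tq * se),
        slope_per_1000=1000.0 * slope / ybar, intercept=intercept,
    )


def rrmse(panel: CountPanel, fitted_means: np.ndarray) -> MetricValue:
    """RMSE over observed cells normalized by the mean observed count."""
    mask = panel.observed_mask
    y = panel.counts[mask]
    mu = np.asarray(fitted_means, float)
    mu = mu[mask] if mu.shape == panel.counts.shape else mu
    if y.size == 0:
        raise ValueError("no observed cells")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("RRMSE undefined: all observed counts are zero")
    rmse = float(np.sqrt(np.mean((y - mu) ** 2)))
    return MetricValue("rrmse", rmse / ybar, int(y.size))


def percent_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to reference ``b``: 100 (a-b)/b,
    reported to one decimal."""
    if b == 0:
        raise ValueError("zero reference value")
    return round(100.0 * (a - b) / b, 1)


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per design x method results of a comparison run."""

    rows: list = field(default_factory=list)

    def to_index_frame(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            idx = r.get("index")
            if idx is None:
                continue
            for t in range(len(idx.years)):
                recs.append({"design": r["design"], "method": r["method"],
                             "year": int(idx.years[t]), "total": idx.totals[t],
                             "lo95": idx.lo95[t], "hi95": idx.hi95[t]})
        return pd.DataFrame(recs)

    def summary(self) -> dict:
        out = {}
        for r in self.rows:
            key = f"{r['design']}/{r['method']}"
            entry = {"converged": r["converged"]}
            if r.get("trend") is not None:
                entry["slope"] = r["trend"].slope
                entry["slope_per_1000"] = r["trend"].slope_per_1000
            if r.get("rrmse") is not None:
                entry["rrmse"] = r["rrmse"].value
            for tag in ("od", "zi", "sa"):
                tr = r.get(tag)
                if tr is not None:
                    entry[tag] = {"statistic": tr.statistic, "p_value": tr.p_value,
                                  "significant": tr.significant}
            if "trend_bias" in r:
                entry["trend_bias"] = r["trend_bias"]
                entry["trend_covers_truth"] = r["trend_covers_truth"]
            out[key] = entry
        return out


def _truth_columns(panel: CountPanel, trend: TrendEstimate | None) -> dict:
    if panel.truth is None or trend is None or panel.truth.true_totals.size == 0:
        return {}
    true_idx = AnnualIndex("truth", panel.years, panel.truth.true_totals,
                           panel.truth.true_totals, panel.truth.true_totals)
    true_slope = trend_from_index(true_idx).slope
    return {"trend_bias": trend.slope - true_slope,
            "trend_covers_truth": bool(trend.ci95[0] <= true_slope <= trend.ci95[1])}


def compare_methods(panel: CountPanel, design_specs, method_list, seed: int = 0,
                    n_sims: int = 100, m_imputations: int = 30,
                    alpha: float = 0.05, controls=None,
                    include_barrier: bool = False) -> BenchmarkReport:
    """Fit every method on every design and collect diagnostics, index, trend
    and RRMSE; non-converged combinations are reported blank."""
    from .designs import apply_design
    from .diagnostics import (glmm_moran_values, morans_i_test, od_zi_tests,
                              pearson_od_test, residuals_for_moran, zeros_chisq_test)
    from .glmm import fit_glmm
    from .lori import lori_annual_index
    from .selection import optimized_glmm
    from .trim import trim_time_totals, trim_two_step

    valid = {"simple_glmm", "optimized_glmm", "trim", "lori"}
    if not set(method_list) <= valid:
        raise ValueError(f"methods must be within {valid}")
    report = BenchmarkReport()
    for spec in design_specs:
        designed = apply_design(panel, spec)
        for method in method_list:
            row = {"design": spec.design_id, "method": method, "converged": False,
                   "index": None, "trend": None, "rrmse": None,
                   "od": None, "zi": None, "sa": None}
            try:
                if method in ("simple_glmm", "optimized_glmm"):
                    if method == "simple_glmm":
                        fit = fit_glmm(designed, "poisson", controls=controls)
                    else:
                        fit, _, _ = optimized_glmm(designed, controls=controls, seed=seed,
                                                   n_sims=n_sims, alpha=alpha,
                                                   include_barrier=include_barrier)
                    row["converged"] = fit.converged
                    if fit.converged:
                        row["od"], row["zi"] = od_zi_tests(fit, designed, n_sims, seed + 1, alpha)
                        vals = glmm_moran_values(fit, designed, min(n_sims, 100), seed + 3)
                        row["sa"] = morans_i_test(vals, designed.coords(), alpha)
                        idx = glmm_index(fit, designed, seed=seed + 4)
                        idx.method_id = method
                        row["index"] = idx
                        row["trend"] = trend_from_index(idx)
                        row["rrmse"] = rrmse(designed, fit.fitted_means)
                elif method == "trim":
                    fit = trim_two_step(designed)
                    row["converged"] = fit.converged
                    if fit.converged:
                        y_obs = designed.counts[designed.observed_mask]
                        mu_obs = fit.fitted_at_observed(designed)
                        row["od"] = pearson_od_test(y_obs, mu_obs, fit.n_params, alpha)
                        row["zi"] = zeros_chisq_test(y_obs, mu_obs, alpha)
                        row["sa"] = morans_i_test(residuals_for_moran(designed, fit.fitted_means),
                                                  designed.coords(), alpha)
                        idx = trim_time_totals(fit)
                        row["index"] = idx
                        row["trend"] = trend_from_index(idx)
                        row["rrmse"] = rrmse(designed, fit.fitted_means)
                else:  # lori
                    idx, base = lori_annual_index(designed, m=m_imputations, seed=seed + 5)
                    # proximal gradient is monotone; a completed descent is
                    # usable even when the tolerance was not hit within the cap
                    usable = bool(np.all(np.diff(base.objective_path) <= 1e-9))
                    row["converged"] = usable
                    if usable:
                        y_obs = designed.counts[designed.observed_mask]
                        mu_obs = base.fitted_at_observed(designed)
                        n_par = min(base.n_params, y_obs.size - 1)
                        row["od"] = pearson_od_test(y_obs, mu_obs, n_par, alpha)
                        rng = np.random.default_rng(seed + 6)
                        sim_zeros = (rng.poisson(mu_obs[None, :].repeat(n_sims, 0)) == 0).sum(axis=1)
                        obs_zeros = float((y_obs == 0).sum())
                        mean_sim = max(sim_zeros.mean(), 1e-12)
                        from .diagnostics import TestResult, _mc_two_sided_p
                        row["zi"] = TestResult("zi_sim", obs_zeros / mean_sim,
                                               _mc_two_sided_p(obs_zeros, sim_zeros), alpha, n_sims)
                        row["sa"] = morans_i_test(residuals_for_moran(designed, base.fitted_means),
                                                  designed.coords(), alpha)
                        row["index"] = idx
                        row["trend"] = trend_from_index(idx)
                        row["rrmse"] = rrmse(designed, base.fitted_means)
            except Exception as exc:  # failures recorded per cell, never fatal
                log.warning("compare_methods %s/%s failed: %s", spec.design_id, method, exc)
                row["error"] = str(exc)
            row.update(_truth_columns(designed, row.get("trend")))
            report.rows.append(row)
    return report
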