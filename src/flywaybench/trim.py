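"""TRIM-like log-linear imputation model for count panels.

The model is a Poisson log-linear model with site and year-factor effects::

    log mu_it = a_i + b_t            (first year effect fixed at 0)

optionally relaxed to quasi-Poisson (Var Y = sigma^2 * mu) and to lag-1
serial correlation within sites (cor(f_it, f_i,t+1) = rho), both estimated by
estimating equations: the regression parameters solve generalized estimating
equations with a working covariance ``sigma^2 * sqrt(mu) R(rho) sqrt(mu)``
(AR(1)-type within-site correlation), sigma^2 is the Pearson statistic over
its degrees of freedom, and rho is the pooled lag-1 autocorrelation of
Pearson residuals.  Missing cells are imputed with their fitted means, so
yearly *time totals* sum observed-model fits over all sites.

An optional region map adds region-specific year effects (region x year
interaction), the estimable analogue of coarse geographical-region factors:
a region main effect alone would be absorbed by the site effects.

The canonical two-step usage mirrors common practice: fit with both options
on, then disable overdispersion if sigma^2 < 1 and/or serial correlation if
rho < 0.2, and refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .panel import CountPanel

__all__ = ["TrimFit", "fit_trim", "trim_two_step", "trim_time_totals"]

log = logging.getLogger(__name__)


@dataclass
class TrimFit:
    """A fitted TRIM-style model."""

    site_effects: np.ndarray          # a_i, one per site
    year_effects: np.ndarray          # b_{t,r}, shape (n_years, n_regions); b_0r = 0
    regions: list
    region_of_site: np.ndarray        # region index per site
    sigma2: float
    rho: float
    overdisp_on: bool
    serialcor_on: bool
    fitted_means: np.ndarray          # mu_hat for all cells incl. missing
    converged: bool
    n_params: int
    years: np.ndarray
    site_ids: np.ndarray
    cov_beta: np.ndarray = field(repr=False, default=None)
    design_info: dict = field(repr=False, default_factory=dict)
    steps: list = field(default_factory=list)  # two-step trace

    def fitted_at_observed(self, panel: CountPanel) -> np.ndarray:
        return self.fitted_means[panel.observed_mask]

    def to_json_dict(self) -> dict:
        """Option flags and estimating-equation parameters, JSON-ready."""
        return {
            "sigma2": float(self.sigma2), "rho": float(self.rho),
            "overdisp_on": bool(self.overdisp_on), "serialcor_on": bool(self.serialcor_on),
            "converged": bool(self.converged), "n_params": int(self.n_params),
            "regions": list(self.regions),
            "steps": [[s[0]] + [float(x) if isinstance(x, float) else bool(x) if isinstance(x, bool) else x
                                for x in s[1:]] for s in self.steps],
        }


def _region_indices(panel: CountPanel, region_map: pd.DataFrame | dict | None):
    if region_map is None:
        return ["all"], np.zeros(panel.n_sites, int)
    if isinstance(region_map, pd.DataFrame):
        mapping = dict(zip(region_map["site_id"], region_map["region"]))
    else:
        mapping = dict(region_map)
    labels = [mapping[s] for s in panel.site_ids]
    regions = sorted(set(labels))
    idx = np.array([regions.index(r) for r in labels])
    return regions, idx


def _build_design(panel: CountPanel, region_idx: np.ndarray):
    """Sparse-ish dense design: columns = site effects + (year>0) x region."""
    n, T = panel.n_sites, panel.n_years
    R = region_idx.max() + 1
    mask = panel.observed_mask
    rows = np.argwhere(mask)
    n_obs = len(rows)
    n_params = n + (T - 1) * R
    X = np.zeros((n_obs, n_params))
    site_col = rows[:, 0]
    X[np.arange(n_obs), site_col] = 1.0
    t = rows[:, 1]
    r = region_idx[site_col]
    nonfirst = t > 0
    X[np.flatnonzero(nonfirst), n + (t[nonfirst] - 1) * R + r[nonfirst]] = 1.0
    return X, rows, n_params


def fit_trim(panel: CountPanel, region_map=None, overdisp: bool = True,
             serialcor: bool = True, max_iter: int = 200, tol: float = 1e-8) -> TrimFit:
    """Fit the log-linear site + year-factor model by estimating equations."""
    mask = panel.observed_mask
    if (mask.sum(axis=0) == 0).any():
        raise ValueError("a year with no observations makes year effects inestimable")
    if (mask.sum(axis=1) == 0).any():
        raise ValueError("a site with no observations makes its effect inestimable")
    regions, region_idx = _region_indices(panel, region_map)
    X, rows, n_params = _build_design(panel, region_idx)
    y = panel.counts[mask]
    n_obs = len(y)
    if n_obs <= n_params:
        raise ValueError("more parameters than observed cells")

    # start from log site means / zero year effects
    beta = np.zeros(n_params)
    site_means = np.clip(panel.site_mean_counts(), 0.5, None)
    beta[: panel.n_sites] = np.log(site_means)

    sigma2, rho = 1.0, 0.0
    site_of_obs = rows[:, 0]
    year_of_obs = rows[:, 1]
    # per-site observation slices (rows are in site-major, year-ascending order)
    site_slices = {}
    for i in range(panel.n_sites):
        idx = np.flatnonzero(site_of_obs == i)
        site_slices[i] = idx

    converged = False
    info = None
    for it in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))

        # --- scoring step with working covariance ---
        if serialcor and abs(rho) > 1e-12:
            A = np.zeros((n_params, n_params))
            b_vec = np.zeros(n_params)
            for i, idx in site_slices.items():
                ti = year_of_obs[idx]
                mui = mu[idx]
                Ri = rho ** np.abs(ti[:, None] - ti[None, :])
                sq = np.sqrt(mui)
                Vi = sq[:, None] * Ri * sq[None, :]
                Di_Xi = mui[:, None] * X[idx]       # dmu/dbeta rows
                Vi_inv = linalg.inv(Vi)
                W = Di_Xi.T @ Vi_inv
                A += W @ Di_Xi
                b_vec += W @ (y[idx] - mui)
        else:
            w = mu  # Poisson scoring weights
            Xw = X * w[:, None]
            A = X.T @ Xw
            b_vec = X.T @ (y - mu)
        A[np.diag_indices_from(A)] += 1e-10 * max(1.0, np.trace(A) / n_params)
        try:
            step = linalg.solve(A, b_vec, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(A, b_vec)[0]
        beta_new = beta + step
        rel = np.max(np.abs(step)) / (1.0 + np.max(np.abs(beta_new)))

        beta = beta_new
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        pearson = (y - mu) / np.sqrt(mu)

        if overdisp:
            sigma2 = float(np.sum(pearson**2) / (n_obs - n_params))
        if serialcor:
            num = den = 0.0
            for i, idx in site_slices.items():
                ti = year_of_obs[idx]
                ri = pearson[idx]
                adjacent = np.flatnonzero(np.diff(ti) == 1)
                if len(adjacent):
                    num += float(np.sum(ri[adjacent] * ri[adjacent + 1]))
                    den += len(adjacent)
            rho = float(np.clip(num / den / max(sigma2, 1e-12), -0.95, 0.95)) if den else 0.0

        if rel < tol:
            converged = True
            info = A
            break
        info = A

    n, T = panel.n_sites, panel.n_years
    R = len(regions)
    b_full = np.zeros((T, R))
    b_full[1:] = beta[n:].reshape(T - 1, R)
    # b for site i, year t is b_full[t, region_idx[i]]
    eta_full = beta[:n][:, None] + b_full[:, region_idx].T
    fitted = np.exp(np.clip(eta_full, -30, 30))

    scale = sigma2 if overdisp else 1.0
    try:
        cov_beta = scale * linalg.inv(info)
    except linalg.LinAlgError:
        cov_beta = np.full((n_params, n_params), np.nan)

    return TrimFit(
        site_effects=beta[:n].copy(), year_effects=b_full, regions=regions,
        region_of_site=region_idx, sigma2=float(sigma2) if overdisp else 1.0,
        rho=float(rho) if serialcor else 0.0,
        overdisp_on=overdisp, serialcor_on=serialcor,
        fitted_means=fitted, converged=converged, n_params=n_params,
        years=panel.years.copy(), site_ids=panel.site_ids.copy(),
        cov_beta=cov_beta,
        design_info={"region_idx": region_idx, "n_sites": n, "n_years": T, "n_regions": R},
    )


def trim_two_step(panel: CountPanel, region_map=None) -> TrimFit:
    """Two-step fit: both options on, then disable per the warning rules.

    Overdispersion is disabled when the step-1 ``sigma^2 < 1`` and serial
    correlation when ``rho < 0.2``; the refit (if any) is returned with the
    step-1 fit retained in ``steps``.
    """
    step1 = fit_trim(panel, region_map, overdisp=True, serialcor=True)
    keep_od = step1.sigma2 >= 1.0
    keep_sc = step1.rho >= 0.2
    if keep_od and keep_sc:
        step1.steps = [("step1", step1.sigma2, step1.rho, True, True)]
        return step1
    log.info("trim_two_step: refitting with overdisp=%s serialcor=%s "
             "(sigma2=%.3f, rho=%.3f)", keep_od, keep_sc, step1.sigma2, step1.rho)
    step2 = fit_trim(panel, region_map, overdisp=keep_od, serialcor=keep_sc)
    step2.steps = [("step1", step1.sigma2, step1.rho, True, True),
                   ("step2", step2.sigma2, step2.rho, keep_od, keep_sc)]
    return step2


def trim_time_totals(fit: TrimFit):
    """Yearly imputed time totals with delta-method 95% CIs.

    ``total_t = sum_i mu_hat_it`` over all sites (missing cells use the model
    value); the SE propagates the estimating-equation covariance of the
    parameters, which already carries the sigma^2 inflation when the
    overdispersion option is on.
    """
    from .indices import AnnualIndex  # deferred: indices imports nothing from here

    if not fit.converged:
        raise ValueError("time totals require a converged fit")
    n = fit.design_info["n_sites"]
    T = fit.design_info["n_years"]
    R = fit.design_info["n_regions"]
    region_idx = fit.design_info["region_idx"]
    mu = fit.fitted_means
    totals = mu.sum(axis=0)
    se = np.zeros(T)
    ok = np.all(np.isfinite(fit.cov_beta))
    for t in range(T):
        g = np.zeros(n + (T - 1) * R)
        g[:n] = mu[:, t]
        if t > 0:
            for r in range(R):
                g[n + (t - 1) * R + r] = mu[region_idx == r, t].sum()
        se[t] = np.sqrt(max(g @ fit.cov_beta @ g, 0.0)) if ok else np.nan
    return AnnualIndex(
        method_id="trim", years=fit.years.copy(), totals=totals,
        lo95=totals - 1.96 * se, hi95=totals + 1.96 * se,
    )
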