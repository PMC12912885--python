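"""Low-rank-interactions penalized Poisson model for incomplete count panels.

The model for the site x year matrix of counts is::

    log mu_it = m + a_i + b_t + x_i' c_row + z_t' c_col + Theta_it

with ridge-penalized main effects and covariate coefficients (covariates:
numeric year for columns, longitude and latitude for rows, standardized
internally) and a nuclear-norm penalty on the interaction matrix Theta that
drives it toward low rank.  The objective

    sum_observed [mu - y log mu]  +  (lam_main/2) ||mains, covs||^2
                                  +  lam_nuclear ||Theta||_*

is minimized by proximal gradient descent with backtracking: a gradient step
on all parameters followed by singular-value soft-thresholding (SVT) of
Theta.  Backtracking guarantees a monotone objective.

Missing cells are completed by multiple imputation: each imputation refits
the model on a nonparametric bootstrap of the observed cells and draws the
missing cells from the fitted Poisson, and Rubin's rules combine the m
completed datasets into a point estimate and a total variance
``V = W + (1 + 1/m) B`` per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import CountPanel

__all__ = ["LoriFit", "RubinSummary", "svt", "fit_lori", "select_penalties",
           "multiple_impute", "rubin_combine", "lori_annual_index"]

log = logging.getLogger(__name__)


def svt(mat: np.ndarray, threshold: float) -> np.ndarray:
    """Singular-value soft-thresholding: shrink singular values by ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    return (u * s) @ vt


@dataclass
class LoriFit:
    """A fitted low-rank-interactions Poisson model."""

    intercept: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    cov_coefs: dict
    theta: np.ndarray
    lambda_main: float
    lambda_nuclear: float
    fitted_means: np.ndarray
    objective: float
    objective_path: np.ndarray
    converged: bool
    years: np.ndarray
    site_ids: np.ndarray
    design: dict = field(repr=False, default_factory=dict)

    @property
    def rank(self) -> int:
        if self.theta.size == 0:
            return 0
        s = np.linalg.svd(self.theta, compute_uv=False)
        return int(np.sum(s > 1e-7 * max(s.max(), 1.0)))

    def fitted_at_observed(self, panel: CountPanel) -> np.ndarray:
        return self.fitted_means[panel.observed_mask]

    @property
    def n_params(self) -> int:
        """Effective parameter count: mains + covariates + rank-adjusted Theta."""
        n, T = self.theta.shape
        r = self.rank
        return 1 + n + T + len(self.cov_coefs) + r * (n + T - r)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _covariate_design(panel: CountPanel):
    """Row covariates (lon, lat) and column covariate (year), standardized."""
    coords = panel.coords()
    return {
        "lon": _standardize(coords[:, 0]),
        "lat": _standardize(coords[:, 1]),
        "year": _standardize(panel.years.astype(float)),
    }


def fit_lori(panel: CountPanel, covariates: dict | None = None,
             lambda_main: float = 1e-3, lambda_nuclear: float = 1.0,
             max_iter: int = 500, tol: float = 1e-8,
             weights: np.ndarray | None = None,
             warm: "LoriFit | None" = None) -> LoriFit:
    """Fit by proximal gradient with backtracking line search.

    ``weights`` are optional per-observed-cell multiplicities (used by the
    bootstrap); ``warm`` restarts from a previous fit's parameters.
    """
    if lambda_main < 0 or lambda_nuclear < 0:
        raise ValueError("penalties must be >= 0")
    mask = panel.observed_mask
    if not mask.any():
        raise ValueError("all-missing matrix")
    y = np.where(mask, np.nan_to_num(panel.counts), 0.0)
    n, T = panel.counts.shape
    cov = covariates if covariates is not None else _covariate_design(panel)
    lon, lat, yr = cov["lon"], cov["lat"], cov["year"]
    w_cell = np.zeros((n, T))
    if weights is None:
        w_cell[mask] = 1.0
    else:
        w_cell[mask] = weights

    if warm is not None:
        m0 = warm.intercept
        a = warm.row_effects.copy()
        b = warm.col_effects.copy()
        c = np.array([warm.cov_coefs["lon"], warm.cov_coefs["lat"], warm.cov_coefs["year"]])
        theta = warm.theta.copy()
    else:
        ybar = max(y[mask].mean(), 0.1)
        m0 = float(np.log(ybar))
        a = np.zeros(n)
        b = np.zeros(T)
        c = np.zeros(3)
        theta = np.zeros((n, T))

    def eta_of(m0, a, b, c, theta):
        return (m0 + a[:, None] + b[None, :] + c[0] * lon[:, None]
                + c[1] * lat[:, None] + c[2] * yr[None, :] + theta)

    def smooth_obj(m0, a, b, c, theta):
        eta = eta_of(m0, a, b, c, theta)
        mu = np.exp(np.clip(eta, -30, 30))
        nll = float(np.sum(w_cell * (mu - y * eta)))
        ridge = 0.5 * lambda_main * (a @ a + b @ b + c @ c)
        return nll + ridge

    def nuclear(theta):
        return float(np.linalg.svd(theta, compute_uv=False).sum())

    obj = smooth_obj(m0, a, b, c, theta) + lambda_nuclear * nuclear(theta)
    path = [obj]
    step = 1.0 / max(w_cell.sum() / mask.sum() * max(y[mask].mean(), 1.0), 1.0)
    converged = False
    for it in range(max_iter):
        eta = eta_of(m0, a, b, c, theta)
        mu = np.exp(np.clip(eta, -30, 30))
        G = w_cell * (mu - y)                    # d nll / d eta, observed cells
        g_m = float(G.sum())
        g_a = G.sum(axis=1) + lambda_main * a
        g_b = G.sum(axis=0) + lambda_main * b
        g_c = np.array([float((G * lon[:, None]).sum()),
                        float((G * lat[:, None]).sum()),
                        float((G * yr[None, :]).sum())]) + lambda_main * c
        accepted = False
        for _bt in range(40):
            m0_n = m0 - step * g_m
            a_n = a - step * g_a
            b_n = b - step * g_b
            c_n = c - step * g_c
            theta_n = svt(theta - step * G, step * lambda_nuclear)
            new_obj = smooth_obj(m0_n, a_n, b_n, c_n, theta_n) + lambda_nuclear * nuclear(theta_n)
            if new_obj <= obj + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        m0, a, b, c, theta = m0_n, a_n, b_n, c_n, theta_n
        rel = (obj - new_obj) / (1.0 + abs(obj))
        obj = new_obj
        path.append(obj)
        step *= 1.3  # gentle step growth keeps backtracking cheap
        if 0 <= rel < tol:
            converged = True
            break

    eta = eta_of(m0, a, b, c, theta)
    fitted = np.exp(np.clip(eta, -30, 30))
    return LoriFit(
        intercept=m0, row_effects=a, col_effects=b,
        cov_coefs={"lon": float(c[0]), "lat": float(c[1]), "year": float(c[2])},
        theta=theta, lambda_main=lambda_main, lambda_nuclear=lambda_nuclear,
        fitted_means=fitted, objective=obj, objective_path=np.array(path),
        converged=converged, years=panel.years.copy(), site_ids=panel.site_ids.copy(),
        design={"covariates": cov},
    )


def select_penalties(panel: CountPanel, covariates: dict | None = None,
                     method: str = "cv", seed: int = 0, k_folds: int = 5,
                     grid_nuclear: np.ndarray | None = None,
                     lambda_main: float = 1e-3) -> tuple[float, float, dict]:
    """Choose (lambda_main, lambda_nuclear).

    ``cv`` masks observed cells in K folds and scores held-out Poisson
    deviance over a nuclear-penalty grid.  ``qut`` simulates panels from the
    mains-only null fit and takes the 0.95 quantile of the spectral norm of
    the interaction gradient at Theta = 0 (the smallest penalty that keeps a
    null interaction at zero).
    """
    if method not in ("cv", "qut"):
        raise ValueError("method must be 'cv' or 'qut'")
    rng = np.random.default_rng(seed)
    mask = panel.observed_mask
    cells = np.argwhere(mask)
    cov = covariates if covariates is not None else _covariate_design(panel)

    # mains-only null fit: a huge nuclear penalty pins Theta at zero
    null_fit = fit_lori(panel, cov, lambda_main=lambda_main, lambda_nuclear=1e12,
                        max_iter=300)

    if method == "qut":
        mu0 = null_fit.fitted_means
        norms = []
        for _ in range(30):
            y_sim = rng.poisson(np.where(mask, mu0, 0.0))
            G = np.where(mask, y_sim - mu0, 0.0)
            norms.append(np.linalg.norm(G, 2))
        lam = float(np.quantile(norms, 0.95))
        return lambda_main, lam, {"method": "qut", "norms": norms}

    if len(cells) < k_folds:
        raise ValueError("panel too small for the requested folds")
    if grid_nuclear is None:
        G0 = np.where(mask, np.nan_to_num(panel.counts) - null_fit.fitted_means, 0.0)
        lam_max = np.linalg.norm(G0, 2)
        grid_nuclear = lam_max * np.array([0.5, 0.2, 0.1, 0.05, 0.02])
    fold = rng.permutation(len(cells)) % k_folds
    scores = np.zeros(len(grid_nuclear))
    for g, lam in enumerate(grid_nuclear):
        dev = 0.0
        for f in range(k_folds):
            hold = cells[fold == f]
            counts = panel.counts.copy()
            counts[hold[:, 0], hold[:, 1]] = np.nan
            sub = CountPanel(sites=panel.sites, years=panel.years, counts=counts)
            fit = fit_lori(sub, cov, lambda_main=lambda_main, lambda_nuclear=lam, max_iter=300)
            mu = fit.fitted_means[hold[:, 0], hold[:, 1]]
            yv = panel.counts[hold[:, 0], hold[:, 1]]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(yv > 0, yv * np.log(yv / mu) - (yv - mu), mu)
            dev += float(2 * term.sum())
        scores[g] = dev
    best = int(np.argmin(scores))
    return lambda_main, float(grid_nuclear[best]), {
        "method": "cv", "grid": np.asarray(grid_nuclear), "scores": scores}


def multiple_impute(panel: CountPanel, covariates: dict | None = None, m: int = 100,
                    seed: int = 0, lambda_main: float = 1e-3,
                    lambda_nuclear: float = 1.0, boot_iter: int = 150):
    """Multiple imputation of the missing cells.

    Each of the ``m`` imputations reweights the observed cells by a
    nonparametric bootstrap, refits (warm-started from the full-data fit),
    and draws missing cells from the fitted Poisson.  Observed cells are
    never altered.  Returns ``(completed, totals, within_vars, base_fit)``
    where ``completed`` is (m, n_sites, n_years), ``totals`` (m, n_years) the
    per-imputation annual totals and ``within_vars`` (m, n_years) the
    within-imputation variance of each total (the Poisson variance of the
    imputed cells; zero when the panel is complete).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    mask = panel.observed_mask
    n_obs = int(mask.sum())
    base = fit_lori(panel, covariates, lambda_main, lambda_nuclear)
    rng = np.random.default_rng(seed)
    completed = np.empty((m, panel.n_sites, panel.n_years))
    totals = np.empty((m, panel.n_years))
    within = np.empty((m, panel.n_years))
    any_missing = not mask.all()
    for k in range(m):
        if any_missing:
            w = rng.multinomial(n_obs, np.full(n_obs, 1.0 / n_obs)).astype(float)
            fit_k = fit_lori(panel, covariates, lambda_main, lambda_nuclear,
                             max_iter=boot_iter, weights=w, warm=base)
            mu_miss = fit_k.fitted_means[~mask]
            draws = rng.poisson(mu_miss)
        filled = np.where(mask, panel.counts, 0.0)
        if any_missing:
            filled[~mask] = draws
        completed[k] = filled
        totals[k] = filled.sum(axis=0)
        wv = np.zeros(panel.n_years)
        if any_missing:
            miss_by_year = ~mask
            mu_grid = fit_k.fitted_means
            wv = np.where(miss_by_year, mu_grid, 0.0).sum(axis=0)
        within[k] = wv
    return completed, totals, within, base


@dataclass(frozen=True)
class RubinSummary:
    """Rubin's-rules combination of m imputed totals for one year."""

    m: int
    estimate: float
    W: float
    B: float

    @property
    def V_total(self) -> float:
        return self.W + (1.0 + 1.0 / self.m) * self.B

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * np.sqrt(self.V_total)
        return (self.estimate - half, self.estimate + half)


def rubin_combine(per_imputation_totals: np.ndarray,
                  per_imputation_variances: np.ndarray) -> list[RubinSummary]:
    """Combine per-imputation totals/variances into per-year summaries.

    ``V = W + (1 + 1/m) B`` with W the mean within-imputation variance and B
    the between-imputation sample variance (denominator m - 1).
    """
    totals = np.atleast_2d(np.asarray(per_imputation_totals, float))
    wvars = np.atleast_2d(np.asarray(per_imputation_variances, float))
    if totals.shape != wvars.shape:
        raise ValueError("totals and variances must be aligned (m x n_years)")
    m = totals.shape[0]
    if m < 2:
        raise ValueError("need m >= 2 imputations")
    out = []
    for t in range(totals.shape[1]):
        out.append(RubinSummary(
            m=m, estimate=float(totals[:, t].mean()),
            W=float(wvars[:, t].mean()),
            B=float(totals[:, t].var(ddof=1)),
        ))
    return out


def write_rubin_csv(summaries, years, path) -> None:
    """Per-year Rubin combination as ``year,estimate,W,B,V,lo95,hi95``."""
    import pandas as pd

    rows = []
    for yr, r in zip(years, summaries):
        lo, hi = r.ci95
        rows.append((int(yr), r.estimate, r.W, r.B, r.V_total, lo, hi))
    pd.DataFrame(rows, columns=["year", "estimate", "W", "B", "V", "lo95", "hi95"]
                 ).to_csv(path, index=False)


def lori_annual_index(panel: CountPanel, covariates: dict | None = None, m: int = 100,
                      seed: int = 0, lambda_main: float = 1e-3, lambda_nuclear: float = 1.0):
    """Annual population index from multiple imputation + Rubin's rules."""
    from .indices import AnnualIndex

    _, totals, within, base = multiple_impute(panel, covariates, m=m, seed=seed,
                                              lambda_main=lambda_main,
                                              lambda_nuclear=lambda_nuclear)
    combined = rubin_combine(totals, within)
    est = np.array([r.estimate for r in combined])
    lo = np.array([r.ci95[0] for r in combined])
    hi = np.array([r.ci95[1] for r in combined])
    return AnnualIndex(method_id="lori", years=panel.years.copy(),
                       totals=est, lo95=lo, hi95=hi), base
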