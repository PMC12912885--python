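"""Residual diagnostics: dispersion, zero inflation, overdispersion chi-square,
observed-vs-expected-zeros chi-square, and Moran's I spatial autocorrelation.

The dispersion and zero-inflation tests are simulation-based in the style of
randomized-quantile residual checking: the observed statistic is ranked among
statistics of replicate datasets simulated from the fitted model, giving a
two-sided Monte-Carlo p-value.  The Pearson chi-square overdispersion test and
the zeros chi-square are the analytic diagnostics used for the log-linear
imputation models, which cannot provide cheap simulations.  Moran's I uses
inverse great-circle-distance weights on per-site mean residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glmm import FitResult
from .panel import CountPanel

__all__ = ["TestResult", "dispersion_test_sim", "zero_inflation_test_sim",
           "od_zi_tests", "pearson_od_test", "zeros_chisq_test", "morans_i_test",
           "residuals_for_moran", "great_circle_km", "moran_weights"]

log = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    """One diagnostic outcome at significance level ``alpha``."""

    test_id: str
    statistic: float
    p_value: float
    alpha: float = ALPHA_DEFAULT
    n_sims: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _mc_two_sided_p(observed: float, simulated: np.ndarray) -> float:
    """Two-sided Monte-Carlo p with the (r + 1)/(n + 1) tie convention."""
    n = len(simulated)
    p_hi = (np.sum(simulated >= observed) + 1) / (n + 1)
    p_lo = (np.sum(simulated <= observed) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def _pearson_stat(y: np.ndarray, mu: np.ndarray) -> float:
    """Variance of Pearson residuals (Poisson-scale denominator)."""
    r = (y - mu) / np.sqrt(np.clip(mu, 1e-12, None))
    return float(np.var(r, ddof=1))


def _dispersion_from_sims(fit, panel, sims, mus, alpha, n_sims) -> TestResult:
    mu = fit.fitted_at_observed(panel)
    y = panel.counts[panel.observed_mask]
    obs_stat = _pearson_stat(y, mu)
    sim_stats = np.array([_pearson_stat(s, m) for s, m in zip(sims, mus)])
    denom = sim_stats.mean()
    ratio = obs_stat / denom if denom > 0 else 1.0
    return TestResult("dispersion_sim", float(ratio),
                      _mc_two_sided_p(obs_stat, sim_stats), alpha, n_sims)


def _zi_from_sims(fit, panel, sims, mus, alpha, n_sims) -> TestResult:
    from .glmm import zero_prob_from_means

    y = panel.counts[panel.observed_mask]
    obs_zeros = float(np.sum(y == 0))
    sim_zeros = np.sum(sims == 0, axis=1).astype(float)
    mean_sim = sim_zeros.mean()
    if obs_zeros == 0 and mean_sim == 0:
        log.info("zero_inflation_test_sim: no zeros observed or simulated; statistic := 1")
        return TestResult("zi_sim", 1.0, 1.0, alpha, n_sims)
    stat = obs_zeros / mean_sim if mean_sim > 0 else np.inf
    # p from the excess-zero pivot (zeros minus their model expectation under
    # the refitted means): removes the plug-in dependence of raw zero counts
    # on the fitted parameters, which otherwise makes the test conservative
    e0 = zero_prob_from_means(fit, fit.fitted_at_observed(panel))
    if e0 is not None:
        obs_t = obs_zeros - float(e0.sum())
        sim_t = np.array([nz - float(zero_prob_from_means(fit, m).sum())
                          for nz, m in zip(sim_zeros, mus)])
        p = _mc_two_sided_p(obs_t, sim_t)
    else:
        p = _mc_two_sided_p(obs_zeros, sim_zeros)
    return TestResult("zi_sim", float(stat), p, alpha, n_sims)


def od_zi_tests(fit: FitResult, panel: CountPanel, n_sims: int = 250,
                seed: int = 0, alpha: float = ALPHA_DEFAULT) -> tuple[TestResult, TestResult]:
    """Dispersion and zero-inflation tests from one shared replicate set.

    Equivalent to calling the two tests separately but at half the
    simulation cost, which dominates selection and calibration runs.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    from .glmm import simulate_with_refitted_means

    sims, mus = simulate_with_refitted_means(fit, panel, n_sims, seed=seed)
    return (_dispersion_from_sims(fit, panel, sims, mus, alpha, n_sims),
            _zi_from_sims(fit, panel, sims, mus, alpha, n_sims))


def dispersion_test_sim(fit: FitResult, panel: CountPanel, n_sims: int = 250,
                        seed: int = 0, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Simulation-based dispersion test.

    The statistic is the variance of Pearson residuals of the observed data
    divided by the mean of the same quantity over replicates simulated from
    the fitted model; the p-value is the two-sided Monte-Carlo rank of the
    observed quantity among the simulated ones.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not fit.converged:
        raise ValueError("dispersion test requires a converged fit")
    from .glmm import simulate_with_refitted_means

    sims, mus = simulate_with_refitted_means(fit, panel, n_sims, seed=seed)
    return _dispersion_from_sims(fit, panel, sims, mus, alpha, n_sims)


def zero_inflation_test_sim(fit: FitResult, panel: CountPanel, n_sims: int = 250,
                            seed: int = 0, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Simulation-based zero-inflation test.

    Statistic: observed zero count / mean simulated zero count (1 when both
    are zero, by convention).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not fit.converged:
        raise ValueError("zero-inflation test requires a converged fit")
    from .glmm import simulate_with_refitted_means

    sims, mus = simulate_with_refitted_means(fit, panel, n_sims, seed=seed)
    return _zi_from_sims(fit, panel, sims, mus, alpha, n_sims)


def pearson_od_test(observed: np.ndarray, fitted: np.ndarray, n_params: int,
                    alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Pearson chi-square overdispersion test.

    ``X^2 = sum (y - mu)^2 / mu`` (Poisson variance) compared with the
    residual degrees of freedom; the reported statistic is ``X^2 / df``.
    """
    y = np.asarray(observed, float)
    mu = np.asarray(fitted, float)
    if (mu <= 0).any():
        raise ValueError("fitted means must be > 0")
    df = y.size - n_params
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    x2 = float(np.sum((y - mu) ** 2 / mu))
    p = float(stats.chi2.sf(x2, df))
    return TestResult("pearson_od", x2 / df, p, alpha)


def zeros_chisq_test(observed_counts: np.ndarray, fitted_means: np.ndarray,
                     alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Chi-square comparison of observed vs model-expected zeros.

    Expected zeros are cells whose fitted mean rounds to zero.  The test is a
    one-degree-of-freedom chi-square on the 2x2 zero/non-zero cross-tabulation
    of the observed data against the rounded fitted data.
    """
    y = np.asarray(observed_counts, float)
    mu = np.asarray(fitted_means, float)
    if y.size == 0 or y.size != mu.size:
        raise ValueError("inputs must be non-empty and aligned")
    n = y.size
    o_zero = float(np.sum(y == 0))
    e_zero = float(np.sum(np.round(mu) == 0))
    # 2x2 table: rows = (observed data, fitted-rounded data), cols = (zero, nonzero)
    table = np.array([[o_zero, n - o_zero], [e_zero, n - e_zero]])
    if (table.sum(axis=0) == 0).any():
        warnings.warn("zeros_chisq_test: degenerate margin; continuity guard applied")
        table = table + 0.5
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    stat = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(stat, 1))
    return TestResult("zeros_chisq", stat, p, alpha)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

EARTH_RADIUS_KM = 6371.0


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between lon/lat points."""
    lon = np.deg2rad(coords[:, 0])
    lat = np.deg2rad(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def moran_weights(coords: np.ndarray) -> np.ndarray:
    """Inverse great-circle-distance weights with zero diagonal.

    Coincident sites (zero distance) get the weight of the smallest positive
    distance, with a warning.
    """
    d = great_circle_km(coords)
    n = len(d)
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        warnings.warn("moran_weights: coincident sites; capping weight at 1/d_min")
        d_min = d[off][d[off] > 0].min() if (d[off] > 0).any() else 1.0
        d[off & (d == 0)] = d_min
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return w


def morans_i_test(values: np.ndarray, coords: np.ndarray,
                  alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Moran's I with inverse-distance weights and the randomization-variance
    normal approximation (two-sided p)."""
    z = np.asarray(values, float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs >= 3 sites")
    if np.var(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = moran_weights(np.asarray(coords, float))
    zc = z - z.mean()
    s0 = w.sum()
    num = float(zc @ w @ zc)
    i_stat = (n / s0) * num / float(zc @ zc)

    # randomization moments
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    e_i = -1.0 / (n - 1)
    if n > 3:
        b2 = n * np.sum(zc**4) / (np.sum(zc**2) ** 2)
        var_i = (
            (n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
             - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2))
            / ((n - 1) * (n - 2) * (n - 3) * s0**2)
        ) - e_i**2
    else:
        # randomization variance needs n > 3; fall back to the normality form
        var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    if var_i < 1e-8:
        # degenerate variance (e.g. n = 3 with equal weights): no evidence
        return TestResult("morans_i", float(i_stat), 1.0, alpha)
    p = 2 * stats.norm.sf(abs(i_stat - e_i) / np.sqrt(var_i))
    return TestResult("morans_i", float(i_stat), float(min(1.0, p)), alpha)


def residuals_for_moran(panel: CountPanel, fit_or_fitted) -> np.ndarray:
    """Per-site mean of (observed - fitted) over observed cells."""
    fitted = fit_or_fitted.fitted_means if isinstance(fit_or_fitted, FitResult) else np.asarray(fit_or_fitted, float)
    mask = panel.observed_mask
    if (mask.sum(axis=1) == 0).any():
        raise ValueError("every site needs >= 1 observed cell")
    resid = np.where(mask, panel.counts - fitted, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(resid, axis=1)


def glmm_moran_values(fit: FitResult, panel: CountPanel, n_sims: int = 100,
                      seed: int = 0) -> np.ndarray:
    """Per-site mean simulation residuals for the mixed-model Moran input.

    The expected response is averaged over replicates that *redraw the iid
    site intercepts* from their fitted distribution while conditioning on any
    fitted spatial structure.  Conditioning on the estimated site intercepts
    instead would absorb an unmodeled spatial field into the intercepts and
    leave the residuals blind to it; redrawing the iid part keeps the
    spatially structured signal in the residuals until a spatial structure
    actually captures it.
    """
    from .glmm import _expected_from_etas

    rng = np.random.default_rng(seed)
    ns, ny = fit.panel_shape
    base_etas = []
    site_sds = []
    for part, (gX, gZ) in zip(fit.parts, fit._grids):
        eta = part.eta(gX, gZ)
        u_site = part.u_hat[: part.block_sizes[0]] if part.block_sizes else np.zeros(ns)
        # grid cells are site-major: the site-block contribution repeats per year
        eta = eta - np.repeat(u_site, ny)
        base_etas.append(eta)
        site_sds.append(float(np.exp(part.log_sds[0])) if part.n_blocks else 0.0)
    acc = np.zeros(ns * ny)
    for _ in range(n_sims):
        etas = [eta + np.repeat(rng.normal(0.0, sd, ns), ny)
                for eta, sd in zip(base_etas, site_sds)]
        acc += _expected_from_etas(fit.family.family_id, fit.parts, etas)
    expected = (acc / n_sims).reshape(ns, ny)
    resid = np.where(panel.observed_mask, panel.counts - expected, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(resid, axis=1)
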