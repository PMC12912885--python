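"""Laplace-approximated mixed models for count panels.

The model for a non-hurdle family is::

    log mu_it = beta0 + beta_year * std(t) + u_i [+ spatial term]
    u_i ~ N(0, site_sd^2),  count_it ~ family(mu_it, dispersion)

Random effects are integrated out by a Laplace approximation: for each value
of the outer parameters (fixed effects, log random-effect SDs, dispersion,
spatial range) the random-effect vector is profiled by an inner Newton
optimization and the marginal likelihood is approximated with the curvature
at the mode.  The outer parameters are then optimized quasi-Newton
(L-BFGS-B) with numerical gradients; a second start is attempted when the
first fails its sanity checks.

Hurdle (delta) families are fitted as two parts — a Bernoulli presence model
(logit link, or complementary-log-log for the Poisson-link variants) and a
strictly-positive abundance model on the positive cells, each with its own
fixed effects and random effects.  The Poisson-link variants tie the parts
through the group density: the presence linear predictor enters the positive
part as an offset so the expected count is ``n * w`` (density x weight).

The year covariate is standardized internally; reported slopes are per
calendar year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import linalg, optimize, sparse, special
from scipy.special import expit

from . import families as fam
from .families import FamilySpec, is_hurdle, is_plink
from .panel import CountPanel
from .spatial import GrfBasis, SpatialSpec, bps_basis, grid_cell_ids

__all__ = ["GlmmControls", "SanityReport", "FitResult", "fit_glmm",
           "simulate_from_fit", "predict_expected", "sanity_check"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlmmControls:
    """Numerical controls of the Laplace fitter."""

    maxiter_outer: int = 200
    inner_tol: float = 1e-9
    inner_maxiter: int = 80
    gradient_tol: float = 1e-3   # sanity threshold on the outer score
    multistart: int = 2
    bound_margin: float = 1e-3   # distance to a bound that counts as "at bound"


@dataclass(frozen=True)
class SanityReport:
    gradient_ok: bool
    hessian_pd: bool
    se_finite: bool
    params_in_bounds: bool

    @property
    def passed(self) -> bool:
        return self.gradient_ok and self.hessian_pd and self.se_finite and self.params_in_bounds


# ---------------------------------------------------------------------------
# per-cell observation families (vectorized log-likelihood in eta)
# ---------------------------------------------------------------------------

def _mu_of(eta):
    """exp(eta) with the linear predictor clipped to keep line searches finite."""
    return np.exp(np.clip(eta, -30.0, 30.0))


def _numeric_derivs(llfun, y, eta, h=1e-4):
    l0 = llfun(y, eta)
    lp = llfun(y, eta + h)
    lm = llfun(y, eta - h)
    g = (lp - lm) / (2 * h)
    w = -(lp - 2 * l0 + lm) / h**2
    return float(l0.sum()), g, np.clip(w, 1e-10, 1e10)


class _Obs:
    """One per-cell observation distribution, parameterized by eta and
    unconstrained dispersion parameters z."""

    n_disp = 0
    disp_bounds: list[tuple[float, float]] = []

    def init_disp(self, y):
        return []

    def loglik(self, y, eta, z):  # per-cell
        raise NotImplementedError

    def derivs(self, y, eta, z):
        return _numeric_derivs(lambda yy, ee: self.loglik(yy, ee, z), y, eta)

    def mean(self, eta, z):
        """Response-scale mean (conditional mean for positive parts)."""
        return _mu_of(eta)

    def natural_disp(self, z):
        return None


class _Poisson(_Obs):
    def loglik(self, y, eta, z):
        return y * eta - np.exp(np.clip(eta, -700, 700)) - special.gammaln(y + 1)

    def derivs(self, y, eta, z):
        mu = np.exp(np.clip(eta, -700, 700))
        ll = float(np.sum(y * eta - mu - special.gammaln(y + 1)))
        return ll, y - mu, np.clip(mu, 1e-10, 1e10)


class _NB2(_Obs):
    n_disp = 1
    disp_bounds = [(-4.0, 10.0)]

    def init_disp(self, y):
        m, v = y.mean(), y.var()
        th = m**2 / max(v - m, 1e-3) if v > m else 50.0
        return [float(np.log(np.clip(th, 0.05, 200.0)))]

    def loglik(self, y, eta, z):
        th = np.exp(z[0])
        mu = _mu_of(eta)
        return fam._nb2_logpmf(y, mu, th)

    def derivs(self, y, eta, z):
        th = np.exp(z[0])
        mu = _mu_of(eta)
        ll = float(np.sum(fam._nb2_logpmf(y, mu, th)))
        a = mu / (th + mu)
        g = y - (y + th) * a
        w = (y + th) * th * mu / (th + mu) ** 2
        return ll, g, np.clip(w, 1e-10, 1e10)

    def natural_disp(self, z):
        return float(np.exp(z[0]))


class _NB1(_Obs):
    n_disp = 1
    disp_bounds = [(-6.0, 6.0)]

    def init_disp(self, y):
        m, v = y.mean(), y.var()
        phi = max(v / max(m, 1e-6), 1.05)
        return [float(np.log(np.clip(phi - 1.0, 1e-3, 300.0)))]

    def loglik(self, y, eta, z):
        phi = 1.0 + np.exp(z[0])
        mu = _mu_of(eta)
        return fam._nb2_logpmf(y, mu, mu / (phi - 1.0))

    def natural_disp(self, z):
        return float(1.0 + np.exp(z[0]))


class _Tweedie(_Obs):
    # z0 -> power = 1 + expit(z0), bounded to [1.1, 1.9]: near the p -> 1
    # boundary the compound-Poisson series needs ever more terms and the
    # family degenerates to (quasi-)Poisson anyway
    n_disp = 2
    disp_bounds = [(-2.2, 2.2), (-4.0, 5.0)]

    def init_disp(self, y):
        return [0.0, 0.0]

    def loglik(self, y, eta, z):
        p = 1.0 + expit(z[0])
        phi = np.exp(z[1])
        return fam.tweedie_log_density(y, _mu_of(eta), p, phi)

    def derivs(self, y, eta, z):
        # exponential-dispersion family: score (y-mu)/(phi mu^{p-1}),
        # Fisher information mu^{2-p}/phi (expected, used for scoring steps)
        p = 1.0 + expit(z[0])
        phi = np.exp(z[1])
        mu = np.exp(np.clip(eta, -30, 30))
        ll = float(fam.tweedie_log_density(y, mu, p, phi).sum())
        g = (y - mu) / (phi * mu ** (p - 1.0))
        w = mu ** (2.0 - p) / phi
        return ll, g, np.clip(w, 1e-10, 1e10)

    def natural_disp(self, z):
        return (float(1.0 + expit(z[0])), float(np.exp(z[1])))


class _BernLogit(_Obs):
    def loglik(self, y, eta, z):
        return y * eta - np.logaddexp(0.0, eta)

    def derivs(self, y, eta, z):
        p = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll, y - p, np.clip(p * (1 - p), 1e-10, None)

    def mean(self, eta, z):
        return expit(eta)


class _BernCloglog(_Obs):
    """Presence part of the Poisson-link delta: p = 1 - exp(-exp(eta))."""

    def loglik(self, y, eta, z):
        n = _mu_of(eta)
        logp = np.log1p(-np.exp(-np.clip(n, 1e-12, 50.0)))
        return np.where(y > 0, logp, -n)

    def mean(self, eta, z):
        return 1.0 - np.exp(-_mu_of(eta))


class _Lognormal(_Obs):
    n_disp = 1
    disp_bounds = [(-4.0, 3.0)]

    def init_disp(self, y):
        s = np.log(y[y > 0]).std() if (y > 0).any() else 1.0
        return [float(np.log(np.clip(s, 0.05, 5.0)))]

    def loglik(self, y, eta, z):
        sd = np.exp(z[0])
        mulog = eta - 0.5 * sd**2  # E[y] = exp(eta)
        return -np.log(y) - np.log(sd) - 0.5 * np.log(2 * np.pi) - 0.5 * ((np.log(y) - mulog) / sd) ** 2

    def natural_disp(self, z):
        return float(np.exp(z[0]))


class _Gamma(_Obs):
    n_disp = 1
    disp_bounds = [(-4.0, 6.0)]

    def init_disp(self, y):
        yp = y[y > 0]
        cv2 = (yp.std() / yp.mean()) ** 2 if len(yp) > 2 and yp.mean() > 0 else 1.0
        return [float(np.log(np.clip(1.0 / max(cv2, 1e-3), 0.05, 100.0)))]

    def loglik(self, y, eta, z):
        k = np.exp(z[0])
        mu = _mu_of(eta)
        return (k - 1) * np.log(y) - y * k / mu - special.gammaln(k) + k * (np.log(k) - eta)

    def natural_disp(self, z):
        return float(np.exp(z[0]))


class _TruncNB2(_Obs):
    n_disp = 1
    disp_bounds = [(-4.0, 10.0)]
    init_disp = _NB2.init_disp

    def loglik(self, y, eta, z):
        th = np.exp(z[0])
        return fam.trunc_nb2_logpmf(y, _mu_of(eta), th)

    def mean(self, eta, z):
        th = np.exp(z[0])
        m = _mu_of(eta)
        f0 = (th / (th + m)) ** th
        return m / (1.0 - f0)

    def natural_disp(self, z):
        return float(np.exp(z[0]))


class _TruncNB1(_Obs):
    n_disp = 1
    disp_bounds = [(-6.0, 6.0)]
    init_disp = _NB1.init_disp

    def loglik(self, y, eta, z):
        phi = 1.0 + np.exp(z[0])
        m = _mu_of(eta)
        return fam.trunc_nb2_logpmf(y, m, m / (phi - 1.0))

    def mean(self, eta, z):
        phi = 1.0 + np.exp(z[0])
        m = _mu_of(eta)
        th = m / (phi - 1.0)
        f0 = (th / (th + m)) ** th
        return m / (1.0 - f0)

    def natural_disp(self, z):
        return float(1.0 + np.exp(z[0]))


_OBS = {
    "poisson": _Poisson(), "nb1": _NB1(), "nb2": _NB2(), "tweedie": _Tweedie(),
    "bern_logit": _BernLogit(), "bern_cloglog": _BernCloglog(),
    "lognormal": _Lognormal(), "gamma": _Gamma(),
    "trunc_nb1": _TruncNB1(), "trunc_nb2": _TruncNB2(),
}


# ---------------------------------------------------------------------------
# one Laplace-fitted model part
# ---------------------------------------------------------------------------

@dataclass
class _Part:
    """A fitted GLMM part: design, outer estimates, conditional modes."""

    obs_kind: str
    X: np.ndarray                 # fixed-effect design at observed cells
    Z: sparse.csr_matrix | None   # random-effect design (None if no RE)
    y: np.ndarray
    offset: np.ndarray
    block_sizes: list[int]
    block_names: list[str]
    grf_basis: GrfBasis | None
    grf_slice: slice | None       # columns of Z owned by the GRF block
    theta: np.ndarray             # outer params [beta..., log_sd..., disp..., log_range?]
    n_beta: int
    n_blocks: int
    u_hat: np.ndarray
    objective: float
    converged: bool
    grad_norm: float
    bounds: list[tuple[float | None, float | None]]
    cov: np.ndarray | None = None   # lazy outer covariance
    hess: np.ndarray | None = None  # outer FD Hessian, if already computed

    @property
    def beta(self) -> np.ndarray:
        return self.theta[: self.n_beta]

    @property
    def log_sds(self) -> np.ndarray:
        return self.theta[self.n_beta: self.n_beta + self.n_blocks]

    @property
    def disp_z(self) -> np.ndarray:
        obs = _OBS[self.obs_kind]
        s = self.n_beta + self.n_blocks
        return self.theta[s: s + obs.n_disp]

    def eta(self, X, Z) -> np.ndarray:
        e = X @ self.beta
        if Z is not None and self.u_hat.size:
            e = e + Z @ self.u_hat
        return e


def _fd_grad(objective, theta, h_scale: float = 1e-4) -> np.ndarray:
    """Central-difference gradient."""
    d = len(theta)
    g = np.zeros(d)
    for i in range(d):
        h = h_scale * max(1.0, abs(theta[i]))
        e = np.zeros(d); e[i] = h
        g[i] = (objective(theta + e) - objective(theta - e)) / (2 * h)
    return g


def _fd_hessian(objective, theta, h_scale: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (symmetric)."""
    d = len(theta)
    h = h_scale * np.maximum(1.0, np.abs(theta))
    H = np.zeros((d, d))
    f0 = objective(theta)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (objective(theta + ei) - 2 * f0 + objective(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    objective(theta + ei + ej) - objective(theta + ei - ej)
                    - objective(theta - ei + ej) + objective(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _clip_to_bounds(theta, bounds) -> np.ndarray:
    out = theta.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[i] = max(out[i], lo)
        if hi is not None:
            out[i] = min(out[i], hi)
    return out


def _solve_modes(obs, y, eta_fix, Z, d_inv, z, u0, tol, maxiter):
    """Inner Newton: conditional modes of the random effects given the outer
    parameters.  Returns (u_hat, pen_ll_at_mode)."""
    u = u0.copy()

    def pen_ll(u_):
        return float(obs.loglik(y, eta_fix + Z @ u_, z).sum()) - 0.5 * float(u_ @ (d_inv * u_))

    cur = pen_ll(u)
    for _ in range(maxiter):
        eta = eta_fix + Z @ u
        _, g_eta, w = obs.derivs(y, eta, z)
        grad = Z.T @ g_eta - d_inv * u
        if np.max(np.abs(grad)) < tol * (1 + abs(cur)):
            break
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(w))):
            break
        ZW = Z.multiply(w[:, None])
        H = (Z.T @ ZW).toarray()
        H[np.diag_indices_from(H)] += d_inv
        try:
            H_chol = linalg.cho_factor(H, lower=True)
        except linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-6 * np.abs(H).max()
            try:
                H_chol = linalg.cho_factor(H, lower=True)
            except linalg.LinAlgError:
                break
        step = linalg.cho_solve(H_chol, grad)
        t = 1.0
        for _ls in range(30):
            nxt = pen_ll(u + t * step)
            if nxt >= cur - 1e-12:
                u = u + t * step
                cur = nxt
                break
            t *= 0.5
        else:
            break
    return u, cur


def _build_objective(obs, y, X, Z_fixed, block_sizes, grf_basis, grf_cols_before,
                     n_beta, n_blocks, n_disp, site_index, controls):
    """Return (objective(theta), state) where state caches the warm start."""
    state = {"u": np.zeros(sum(block_sizes)), "range": None, "Z": Z_fixed}
    q = sum(block_sizes)

    def make_Z(theta):
        if grf_basis is None:
            return state["Z"]
        rng_deg = float(np.exp(theta[-1]))
        if state["range"] != rng_deg:
            B = grf_basis.design(rng_deg)          # n_sites x k
            Zg = B[site_index]                     # rows at observed cells
            Z = state["Z"].tolil(copy=True)
            Z[:, grf_cols_before: grf_cols_before + Zg.shape[1]] = Zg
            state["Z"] = Z.tocsr()
            state["range"] = rng_deg
        return state["Z"]

    def objective(theta):
        beta = theta[:n_beta]
        log_sd = theta[n_beta: n_beta + n_blocks]
        z = theta[n_beta + n_blocks: n_beta + n_blocks + n_disp]
        Z = make_Z(theta)
        eta_fix = X @ beta
        if q == 0:
            ll = float(obs.loglik(y, eta_fix, z).sum())
            return -ll
        d_inv = np.concatenate([
            np.full(bs, np.exp(-2.0 * ls)) for bs, ls in zip(block_sizes, log_sd)
        ])
        u, _ = _solve_modes(obs, y, eta_fix, Z, d_inv, z, state["u"],
                            controls.inner_tol, controls.inner_maxiter)
        state["u"] = u
        eta = eta_fix + Z @ u
        ll, _, w = obs.derivs(y, eta, z)
        ZW = Z.multiply(w[:, None])
        H = (Z.T @ ZW).toarray()
        H[np.diag_indices_from(H)] += d_inv
        if not np.all(np.isfinite(H)):
            return 1e10
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        logdet_d = -float(np.sum(np.log(d_inv)))
        laplace = ll - 0.5 * float(u @ (d_inv * u)) - 0.5 * logdet_d - 0.5 * logdet_h
        return -laplace if np.isfinite(laplace) else 1e10

    return objective, state


def _fit_part(obs_kind, y, X, blocks, offset, controls, start_beta=None):
    """Fit one GLMM part by Laplace + L-BFGS-B.

    ``blocks`` is a list of (name, Z_columns ndarray or sparse, kind) where
    kind is 'iid' or ('grf', GrfBasis, site_index).
    """
    obs = _OBS[obs_kind]
    n_beta = X.shape[1]
    block_names, block_sizes, Z_cols = [], [], []
    grf_basis, grf_cols_before, site_index = None, None, None
    has_range = False
    for name, Zb, kind in blocks:
        block_names.append(name)
        if isinstance(kind, tuple) and kind[0] == "grf":
            grf_basis, site_index = kind[1], kind[2]
            grf_cols_before = sum(block_sizes)
            block_sizes.append(grf_basis.n_knots)
            Z_cols.append(sparse.csr_matrix((len(y), grf_basis.n_knots)))
            has_range = True
        else:
            Zb = sparse.csr_matrix(Zb)
            block_sizes.append(Zb.shape[1])
            Z_cols.append(Zb)
    Z_fixed = sparse.hstack(Z_cols).tocsr() if Z_cols else None

    # offset folded into X path by subtracting from eta via loglik shift: we
    # absorb it by extending obs.loglik with offset added to eta.
    if offset is not None:
        base_obs = obs

        class _Shifted(type(base_obs)):  # noqa: N801 - internal
            def loglik(self, yy, eta, z, _o=offset, _b=base_obs):
                return _b.loglik(yy, eta + _o, z)

            def derivs(self, yy, eta, z, _o=offset, _b=base_obs):
                return _b.derivs(yy, eta + _o, z)

            def mean(self, eta, z, _o=offset, _b=base_obs):
                return _b.mean(eta + _o, z)

        obs = _Shifted()

    n_blocks = len(block_sizes)
    objective, state = _build_objective(
        obs, y, X, Z_fixed if Z_fixed is not None else sparse.csr_matrix((len(y), 0)),
        block_sizes, grf_basis, grf_cols_before, n_beta, n_blocks, obs.n_disp,
        site_index, controls)

    disp0 = list(_OBS[obs_kind].init_disp(y))
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * n_beta
    bounds += [(-5.0, 3.0)] * n_blocks
    bounds += list(_OBS[obs_kind].disp_bounds)
    if has_range:
        bounds += [(np.log(0.1), np.log(50.0))]

    def start_vector(jitter=0.0):
        if start_beta is not None:
            b0 = list(start_beta)
        else:
            ypos = np.clip(y, 0.1, None) if obs_kind not in ("bern_logit", "bern_cloglog") else None
            if obs_kind in ("bern_logit", "bern_cloglog"):
                p0 = np.clip(y.mean(), 0.01, 0.99)
                icept = float(np.log(p0 / (1 - p0)) if obs_kind == "bern_logit" else np.log(-np.log1p(-p0)))
            else:
                off = offset.mean() if offset is not None else 0.0
                icept = float(np.log(ypos.mean()) - off)
            b0 = [icept] + [0.0] * (n_beta - 1)
        th = np.array(b0 + [np.log(0.5) + jitter] * n_blocks + disp0 + ([np.log(2.0) + jitter] if has_range else []))
        return th

    best = None
    for attempt in range(controls.multistart):
        theta0 = start_vector(jitter=0.0 if attempt == 0 else 0.7 * attempt)
        state["u"] = np.zeros(sum(block_sizes))
        res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": controls.maxiter_outer, "ftol": 1e-11})
        cand = (res.fun, res, state["u"].copy())
        if best is None or cand[0] < best[0]:
            best = cand
        if res.success:
            break
    fun, res, u_hat = best

    # Newton polish: L-BFGS-B with numerical gradients stops on function
    # change, often with a sizeable residual score; a few damped Newton steps
    # with central-difference derivatives bring max|score| down to the sanity
    # threshold and yield the outer Hessian as a by-product.
    theta = res.x.copy()
    f0 = objective(theta)
    grad = _fd_grad(objective, theta)
    hess = None
    for _ in range(4):
        if not np.all(np.isfinite(grad)):
            break
        if np.max(np.abs(grad)) < 0.5 * controls.gradient_tol:
            break
        hess = _fd_hessian(objective, theta)
        try:
            step = -linalg.solve(hess, grad, assume_a="sym")
        except linalg.LinAlgError:
            break
        improved = False
        for t in (1.0, 0.5, 0.25, 0.1):
            cand_theta = _clip_to_bounds(theta + t * step, bounds)
            f_new = objective(cand_theta)
            if f_new <= f0 + 1e-9 * (1 + abs(f0)):
                theta, f0, improved = cand_theta, f_new, True
                break
        if not improved:
            break
        grad = _fd_grad(objective, theta)
    grad_norm = float(np.max(np.abs(grad)))
    fun = f0
    # leave the warm-start state at the final parameters
    objective(theta)
    u_hat = state["u"].copy()
    Z_final = state["Z"] if Z_fixed is not None else None

    return _Part(
        obs_kind=obs_kind, X=X, Z=Z_final, y=y, offset=offset if offset is not None else np.zeros(len(y)),
        block_sizes=block_sizes, block_names=block_names,
        grf_basis=grf_basis, grf_slice=(slice(grf_cols_before, grf_cols_before + grf_basis.n_knots)
                                        if grf_basis is not None else None),
        theta=theta, n_beta=n_beta, n_blocks=n_blocks, u_hat=u_hat,
        objective=float(fun), converged=bool(res.success and np.isfinite(fun)),
        grad_norm=grad_norm, bounds=bounds, hess=hess,
    ), objective


# ---------------------------------------------------------------------------
# public fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted count GLMM (any family, any spatial structure)."""

    family: FamilySpec
    spatial: SpatialSpec
    beta0: float
    beta_year: float
    beta_year_se: float
    random_sds: dict
    fitted_means: np.ndarray       # expected count, all cells incl. missing
    loglik: float
    converged: bool
    sanity: SanityReport
    years: np.ndarray
    site_ids: np.ndarray
    # internals used by simulation / prediction / index draws
    parts: list = field(default_factory=list, repr=False)
    objectives: list = field(default_factory=list, repr=False)
    panel_shape: tuple = (0, 0)
    year_scale: float = 1.0
    grid_X: np.ndarray | None = field(default=None, repr=False)
    grid_Z: list = field(default_factory=list, repr=False)
    cell_index: np.ndarray | None = field(default=None, repr=False)

    def fitted_at_observed(self, panel: CountPanel) -> np.ndarray:
        return self.fitted_means[panel.observed_mask]

    def to_json_dict(self) -> dict:
        """Parameters and flags in a JSON-serializable form."""
        return {
            "family_id": self.family.family_id,
            "dispersion": self.family.dispersion,
            "power": self.family.power,
            "spatial": self.spatial.label,
            "beta0": self.beta0,
            "beta_year": self.beta_year,
            "beta_year_se": self.beta_year_se,
            "random_sds": {k: float(v) if not isinstance(v, tuple) else list(v)
                           for k, v in self.random_sds.items()},
            "loglik": self.loglik,
            "converged": self.converged,
            "sanity": {"gradient_ok": self.sanity.gradient_ok,
                       "hessian_pd": self.sanity.hessian_pd,
                       "se_finite": self.sanity.se_finite,
                       "params_in_bounds": self.sanity.params_in_bounds,
                       "passed": self.sanity.passed},
        }

    def write_fitted_csv(self, path) -> None:
        """Cell-level fitted means as ``site_id,year,fitted``."""
        import pandas as pd

        rows = [(sid, int(yr), self.fitted_means[i, j])
                for i, sid in enumerate(self.site_ids)
                for j, yr in enumerate(self.years)]
        pd.DataFrame(rows, columns=["site_id", "year", "fitted"]).to_csv(path, index=False)


def _grid_designs(panel: CountPanel, part: _Part, spatial: SpatialSpec,
                  t_std_grid: np.ndarray, site_index_grid: np.ndarray,
                  extra_cols: dict) -> tuple[np.ndarray, np.ndarray | None]:
    """Full-grid (n_cells = n_sites*n_years) fixed/random designs for a part."""
    n_cells = panel.n_sites * panel.n_years
    X = np.column_stack([np.ones(n_cells), t_std_grid])
    if part.Z is None:
        return X, None
    cols = []
    for name, bs in zip(part.block_names, part.block_sizes):
        if name == "site":
            M = sparse.csr_matrix((np.ones(n_cells), (np.arange(n_cells), site_index_grid)),
                                  shape=(n_cells, bs))
        elif name == "grid":
            M = sparse.csr_matrix((np.ones(n_cells), (np.arange(n_cells), extra_cols["grid"][site_index_grid])),
                                  shape=(n_cells, bs))
        elif name == "bps":
            M = sparse.csr_matrix(extra_cols["bps"][site_index_grid])
        elif name == "grf":
            rng_deg = float(np.exp(part.theta[-1]))
            B = part.grf_basis.design(rng_deg)
            M = sparse.csr_matrix(B[site_index_grid])
        else:
            raise AssertionError(name)
        cols.append(M)
    return X, sparse.hstack(cols).tocsr()


def fit_glmm(panel: CountPanel, family: FamilySpec | str,
             spatial: SpatialSpec | None = None,
             controls: GlmmControls | None = None) -> FitResult:
    """Fit a log-link mixed model with a site random intercept.

    Parameters
    ----------
    panel : the count panel (already minimum-survey filtered).
    family : one of the ten candidate families (a :class:`FamilySpec` or id).
    spatial : spatial structure specification (default: none).
    controls : numerical controls.
    """
    if isinstance(family, str):
        family = FamilySpec(family)
    spatial = spatial or SpatialSpec("none")
    controls = controls or GlmmControls()
    if panel.n_sites == 0 or panel.observed_mask.sum() == 0:
        raise ValueError("empty panel")
    if panel.n_years < 2:
        raise ValueError("degenerate design: need >= 2 years")

    years = panel.years
    t_sd = years.std() if years.std() > 0 else 1.0
    t_std = (years - years.mean()) / t_sd
    obs_mask = panel.observed_mask
    site_idx_grid = np.repeat(np.arange(panel.n_sites), panel.n_years)
    t_std_grid = np.tile(t_std, panel.n_sites)
    flat_obs = obs_mask.ravel()
    cell_sites = site_idx_grid[flat_obs]
    cell_t = t_std_grid[flat_obs]
    y = panel.counts.ravel()[flat_obs]
    X = np.column_stack([np.ones(len(y)), cell_t])

    coords = panel.coords()
    extra_cols: dict = {}

    def make_blocks(for_cells_sites):
        blocks = [("site", sparse.csr_matrix(
            (np.ones(len(for_cells_sites)), (np.arange(len(for_cells_sites)), for_cells_sites)),
            shape=(len(for_cells_sites), panel.n_sites)), "iid")]
        sid = spatial.structure_id
        if sid == "ri_grid":
            g = grid_cell_ids(coords, spatial.grid_cell_km)
            extra_cols["grid"] = g
            blocks.append(("grid", sparse.csr_matrix(
                (np.ones(len(for_cells_sites)), (np.arange(len(for_cells_sites)), g[for_cells_sites])),
                shape=(len(for_cells_sites), g.max() + 1)), "iid"))
        elif sid == "bps":
            B = bps_basis(coords, spatial.bps_basis_dim)
            extra_cols["bps"] = B
            blocks.append(("bps", B[for_cells_sites], "iid"))
        elif sid in ("grf", "grf_barrier"):
            basis = GrfBasis(coords, spatial.mesh_cutoff_deg,
                             barrier=spatial.barrier if sid == "grf_barrier" else None)
            blocks.append(("grf", None, ("grf", basis, for_cells_sites)))
        return blocks

    fid = family.family_id
    parts, objectives = [], []

    if not is_hurdle(fid):
        part, objective = _fit_part(fid, y, X, make_blocks(cell_sites), None, controls)
        parts.append(part)
        objectives.append(objective)
    else:
        pres_kind = "bern_cloglog" if is_plink(fid) else "bern_logit"
        y01 = (y > 0).astype(float)
        p_part, p_obj = _fit_part(pres_kind, y01, X, make_blocks(cell_sites), None, controls)
        parts.append(p_part)
        objectives.append(p_obj)
        pos = y > 0
        y_pos = y[pos]
        X_pos = X[pos]
        pos_sites = cell_sites[pos]
        if fid.endswith("trunc_nb2"):
            pos_kind = "trunc_nb2"
        elif fid.endswith("trunc_nb1"):
            pos_kind = "trunc_nb1"
        elif fid.endswith("gamma"):
            pos_kind = "gamma"
        else:
            pos_kind = "lognormal"
        offset = None
        if is_plink(fid):
            eta1 = p_part.eta(X_pos, p_part.Z[np.flatnonzero(pos)] if p_part.Z is not None else None)
            n_dens = np.exp(np.clip(eta1, -30, 30))
            p_pres = np.clip(1.0 - np.exp(-n_dens), 1e-10, 1 - 1e-12)
            offset = eta1 - np.log(p_pres)  # so E[y|y>0] = n*w/p
        pos_part, pos_obj = _fit_part(pos_kind, y_pos, X_pos, make_blocks(pos_sites), offset, controls)
        parts.append(pos_part)
        objectives.append(pos_obj)

    # ---- full-grid expected means -------------------------------------
    grids = []
    for part in parts:
        gX, gZ = _grid_designs(panel, part, spatial, t_std_grid, site_idx_grid, extra_cols)
        grids.append((gX, gZ))
    fitted = _expected_grid(fid, parts, grids)
    fitted_means = fitted.reshape(panel.n_sites, panel.n_years)

    # ---- reported coefficients (abundance part for hurdles) -----------
    main = parts[-1]
    beta0 = float(main.beta[0])
    beta_year = float(main.beta[1] / t_sd)
    cov = _outer_covariance(main, objectives[-1])
    main.cov = cov
    se = np.sqrt(max(cov[1, 1], 0.0)) / t_sd if np.isfinite(cov[1, 1]) else np.nan
    loglik = -sum(p.objective for p in parts)
    converged = all(p.converged for p in parts)

    random_sds = {}
    for part in parts:
        tag = "" if len(parts) == 1 else ("presence_" if part is parts[0] else "positive_")
        for name, ls in zip(part.block_names, part.log_sds):
            random_sds[tag + name + "_sd"] = float(np.exp(ls))
        nd = _OBS[part.obs_kind].natural_disp(part.disp_z)
        if nd is not None:
            random_sds[tag + "dispersion"] = nd
        if part.grf_basis is not None:
            random_sds[tag + "grf_range"] = float(np.exp(part.theta[-1]))

    fit = FitResult(
        family=dc_replace(family,
                          dispersion=_OBS[main.obs_kind].natural_disp(main.disp_z)
                          if not isinstance(_OBS[main.obs_kind].natural_disp(main.disp_z), tuple)
                          else _OBS[main.obs_kind].natural_disp(main.disp_z)[1],
                          power=(_OBS[main.obs_kind].natural_disp(main.disp_z)[0]
                                 if fid == "tweedie" else family.power)),
        spatial=spatial, beta0=beta0, beta_year=beta_year, beta_year_se=float(se),
        random_sds=random_sds, fitted_means=fitted_means, loglik=loglik,
        converged=converged, sanity=_sanity(parts, controls, cov),
        years=years, site_ids=panel.site_ids, parts=parts, objectives=objectives,
        panel_shape=(panel.n_sites, panel.n_years), year_scale=t_sd,
        grid_X=grids[-1][0], grid_Z=[g[1] for g in grids],
        cell_index=np.flatnonzero(flat_obs),
    )
    fit._grids = grids
    return fit


def _expected_from_etas(fid, parts, etas) -> np.ndarray:
    """Expected count per cell from given per-part linear predictors."""
    if not is_hurdle(fid):
        part = parts[0]
        return _OBS[part.obs_kind].mean(etas[0], part.disp_z)
    p_part, pos_part = parts
    eta1, eta2 = etas
    if is_plink(fid):
        # E = n * w
        return np.exp(np.clip(eta1 + eta2, -30, 30))
    p = expit(eta1)
    cond_mean = _OBS[pos_part.obs_kind].mean(eta2, pos_part.disp_z)
    return p * cond_mean


def _expected_grid(fid, parts, grids) -> np.ndarray:
    """Expected count per full-grid cell."""
    etas = [part.eta(gX, gZ) for part, (gX, gZ) in zip(parts, grids)]
    return _expected_from_etas(fid, parts, etas)


def _outer_covariance(part: _Part, objective) -> np.ndarray:
    """Covariance of the outer parameters: inverse FD Hessian at the optimum."""
    H = part.hess
    if H is None:
        H = _fd_hessian(objective, part.theta)
        part.hess = H
        objective(part.theta)  # restore the warm-started modes
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.diag(cov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((len(part.theta), len(part.theta)), np.nan)
    return cov


def _sanity(parts, controls, cov) -> SanityReport:
    grad_ok = all(p.grad_norm < controls.gradient_tol for p in parts)
    se_finite = bool(np.all(np.isfinite(np.diag(cov)))) if cov is not None else False
    hess_pd = se_finite
    in_bounds = True
    for p in parts:
        for val, (lo, hi) in zip(p.theta, p.bounds):
            if lo is not None and val - lo < controls.bound_margin:
                in_bounds = False
            if hi is not None and hi - val < controls.bound_margin:
                in_bounds = False
    return SanityReport(gradient_ok=grad_ok, hessian_pd=hess_pd,
                        se_finite=se_finite, params_in_bounds=in_bounds)


def sanity_check(fit: FitResult) -> SanityReport:
    """The fit's sanity report (gradient, curvature, SEs, bounds)."""
    return fit.sanity


# ---------------------------------------------------------------------------
# simulation and prediction
# ---------------------------------------------------------------------------

def predict_expected(fit: FitResult, cells: np.ndarray | None = None) -> np.ndarray:
    """Expected count on the response scale.

    ``cells=None`` returns the full site x year matrix; otherwise ``cells``
    is an array of (site_index, year_index) pairs.
    """
    if cells is None:
        return fit.fitted_means
    cells = np.asarray(cells, int)
    ns, ny = fit.panel_shape
    if (cells[:, 0] >= ns).any() or (cells[:, 1] >= ny).any() or (cells < 0).any():
        raise ValueError("cells outside the fitted panel")
    return fit.fitted_means[cells[:, 0], cells[:, 1]]


def simulate_from_fit(fit: FitResult, panel: CountPanel, n_sims: int, seed: int = 0) -> np.ndarray:
    """Replicate responses at the observed cells of ``panel``.

    Random effects are held at their conditional modes; new observation noise
    is drawn per replicate from the fitted family.  Returns an array of shape
    ``(n_sims, n_observed_cells)``.
    """
    if not fit.converged:
        raise ValueError("cannot simulate from a non-converged fit")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = np.random.default_rng(seed)
    obs_mask = panel.observed_mask
    fid = fit.family.family_id
    if not is_hurdle(fid):
        mu = fit.fitted_means[obs_mask]
        spec = fit.family
        return np.stack([fam.simulate_counts(spec, mu, rng) for _ in range(n_sims)])
    # hurdle: presence prob and positive mean at observed cells
    p_part, pos_part = fit.parts
    (pX, pZ), (wX, wZ) = fit._grids
    eta1 = p_part.eta(pX, pZ).reshape(fit.panel_shape)[obs_mask]
    eta2 = pos_part.eta(wX, wZ).reshape(fit.panel_shape)[obs_mask]
    disp = _OBS[pos_part.obs_kind].natural_disp(pos_part.disp_z)
    spec = FamilySpec(fid, dispersion=disp)
    if is_plink(fid):
        means = (np.exp(np.clip(eta1, -30, 30)), np.exp(np.clip(eta2, -30, 30)))
    else:
        cond = _OBS[pos_part.obs_kind].mean(eta2, pos_part.disp_z)
        if pos_part.obs_kind.startswith("trunc"):
            cond = np.exp(eta2)  # simulate_counts truncates the untruncated mean itself
        means = (expit(eta1), cond)
    return np.stack([fam.simulate_counts(spec, means, rng) for _ in range(n_sims)])


def simulate_with_refitted_means(fit: FitResult, panel: CountPanel, n_sims: int,
                                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap replicates for the simulation-based diagnostics.

    Each replicate redraws every random-effect block from its fitted
    distribution, simulates responses from the fitted family at the observed
    cells, and *re-predicts the conditional modes* on the replicate (fixed
    effects and dispersion held at their estimates).  Comparing the observed
    statistic with replicate statistics computed against their own refitted
    means puts both sides through the same shrinkage, which is what makes the
    dispersion and zero-inflation tests calibrated under a correctly
    specified model.

    Returns ``(sims, mus)`` of shape ``(n_sims, n_observed_cells)``: the
    replicate responses and their refitted expected means.  Hurdle fits fall
    back to conditional simulation (means repeated).
    """
    if not fit.converged:
        raise ValueError("cannot simulate from a non-converged fit")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    obs_mask = panel.observed_mask
    fid = fit.family.family_id
    if is_hurdle(fid):
        sims = simulate_from_fit(fit, panel, n_sims, seed=seed)
        mu = np.broadcast_to(fit.fitted_means[obs_mask], sims.shape)
        return sims, np.array(mu)
    part = fit.parts[0]
    obs = _OBS[part.obs_kind]
    rng = np.random.default_rng(seed)
    Z = part.Z
    eta_fix = part.X @ part.beta + part.offset
    z = part.disp_z
    sds = np.exp(part.log_sds)
    d_inv = np.concatenate([np.full(bs, 1.0 / max(sd, 1e-8) ** 2)
                            for bs, sd in zip(part.block_sizes, sds)])
    sims = np.empty((n_sims, len(part.y)))
    mus = np.empty_like(sims)
    for k in range(n_sims):
        u_rep = np.concatenate([rng.normal(0.0, sd, bs)
                                for bs, sd in zip(part.block_sizes, sds)])
        mu_gen = obs.mean(np.clip(eta_fix + Z @ u_rep, -30.0, 30.0), z)
        y_rep = fam.simulate_counts(fit.family, mu_gen, rng)
        u_hat, _ = _solve_modes(obs, y_rep, eta_fix, Z, d_inv, z, u_rep,
                                tol=1e-7, maxiter=30)
        sims[k] = y_rep
        mus[k] = obs.mean(np.clip(eta_fix + Z @ u_hat, -30.0, 30.0), z)
    return sims, mus


def zero_prob_from_means(fit: FitResult, mu: np.ndarray) -> np.ndarray | None:
    """Per-cell probability of a zero under the fitted family at means ``mu``.

    Returns None for hurdle fits (their zero mass is the presence part).
    """
    fid = fit.family.family_id
    mu = np.asarray(mu, float)
    if fid == "poisson":
        return np.exp(-mu)
    if fid == "nb2":
        th = fit.family.dispersion
        return (th / (th + mu)) ** th
    if fid == "nb1":
        phi = fit.family.dispersion
        th = mu / (phi - 1.0)
        return (th / (th + mu)) ** th
    if fid == "tweedie":
        p = fit.family.power or 1.5
        phi = fit.family.dispersion
        lam = mu ** (2 - p) / (phi * (2 - p))
        return np.exp(-lam)
    return None


def presence_probability(fit: FitResult) -> np.ndarray | None:
    """Fitted presence probability grid for hurdle fits (else None)."""
    if not is_hurdle(fit.family.family_id):
        return None
    p_part = fit.parts[0]
    pX, pZ = fit._grids[0]
    eta1 = p_part.eta(pX, pZ)
    p = _OBS[p_part.obs_kind].mean(eta1, p_part.disp_z)
    return np.asarray(p).reshape(fit.panel_shape)
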