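"""Count-distribution families for abundance modeling.

The candidate set, in a fixed priority order of increasing statistical
complexity, is:

1.  ``poisson``
2.  ``nb1``        negative binomial type 1, Var = phi * mu (phi > 1)
3.  ``nb2``        negative binomial type 2, Var = mu + mu^2 / theta
4.  ``tweedie``    compound Poisson-Gamma, power p in (1, 2), dispersion phi
5.  ``hurdle_lognormal``
6.  ``hurdle_gamma``
7.  ``hurdle_trunc_nb1``
8.  ``hurdle_trunc_nb2``
9.  ``hurdle_plink_gamma``
10. ``hurdle_plink_lognormal``

Hurdle (delta) families have a presence/absence part and a strictly-positive
part.  Plain hurdles use a Bernoulli presence probability on the logit scale;
the two "Poisson-link" variants derive the presence probability from a latent
group density ``n``: ``p = 1 - exp(-n)`` (complementary log-log on the log
scale), and the conditional positive mean is ``n * w / p`` where ``w`` is the
positive-part predictor, so the two parts share the density scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = ["FAMILY_ORDER", "FamilySpec", "is_hurdle", "is_plink",
           "nll_poisson", "nll_nb1", "nll_nb2", "nll_tweedie",
           "trunc_nb2_logpmf", "hurdle_positive_nll", "neg_log_likelihood",
           "tweedie_log_density", "simulate_counts"]

FAMILY_ORDER = (
    "poisson", "nb1", "nb2", "tweedie",
    "hurdle_lognormal", "hurdle_gamma", "hurdle_trunc_nb1", "hurdle_trunc_nb2",
    "hurdle_plink_gamma", "hurdle_plink_lognormal",
)

_HURDLE = tuple(f for f in FAMILY_ORDER if f.startswith("hurdle"))
_PLINK = ("hurdle_plink_gamma", "hurdle_plink_lognormal")


def is_hurdle(family_id: str) -> bool:
    return family_id in _HURDLE


def is_plink(family_id: str) -> bool:
    return family_id in _PLINK


@dataclass(frozen=True)
class FamilySpec:
    """A family identifier plus its dispersion parameters.

    ``dispersion`` is phi for NB1 (>1 strictly overdispersed), theta for NB2,
    phi for Tweedie, and the positive-part shape/SD for hurdle families
    (sdlog for lognormal, gamma shape for gamma, NB dispersion for the
    truncated NB parts).  ``power`` is the Tweedie variance power.
    """

    family_id: str
    dispersion: float | None = None
    power: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family_id not in FAMILY_ORDER:
            raise ValueError(f"unknown family_id {self.family_id!r}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")
        if self.family_id == "tweedie" and self.power is not None and not 1 < self.power < 2:
            raise ValueError("tweedie power must lie in (1, 2)")


# ---------------------------------------------------------------------------
# negative log-likelihoods (exact densities, summed over cells)
# ---------------------------------------------------------------------------

def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float)
    if (y < 0).any() or not np.all(y == np.round(y)):
        raise ValueError("counts must be non-negative integers for discrete families")
    return y


def nll_poisson(y, mu) -> float:
    y = _check_counts(y)
    mu = np.asarray(mu, float)
    return float(np.sum(mu - y * np.log(mu) + special.gammaln(y + 1)))


def _nb2_logpmf(y, mu, theta):
    return (special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu)) + y * np.log(mu / (theta + mu)))


def nll_nb2(y, mu, theta: float) -> float:
    """NB2: Var = mu + mu^2/theta."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    y = _check_counts(y)
    return float(-np.sum(_nb2_logpmf(np.asarray(y, float), np.asarray(mu, float), theta)))


def nll_nb1(y, mu, phi: float) -> float:
    """NB1: Var = phi*mu, via the NB2 pmf with cell-wise theta = mu/(phi-1)."""
    if phi <= 1:
        raise ValueError("NB1 requires phi > 1 (phi -> 1 is the Poisson limit)")
    y = _check_counts(y)
    mu = np.asarray(mu, float)
    theta = mu / (phi - 1.0)
    return float(-np.sum(_nb2_logpmf(np.asarray(y, float), mu, theta)))


def tweedie_log_density(y, mu, power: float, phi: float, rtol: float = 1e-8) -> np.ndarray:
    """Log density of the Tweedie compound Poisson-Gamma at y >= 0.

    Series evaluation in log space, truncated adaptively: the summation range
    is grown from the dominant index until the edge terms fall below ``rtol``
    times the peak term.  Vectorized over cells.
    """
    if not 1 < power < 2:
        raise ValueError("power must lie in (1, 2)")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    y = np.asarray(y, float)
    mu = np.broadcast_to(np.asarray(mu, float), y.shape).ravel()
    yf = y.ravel()
    out = np.empty_like(yf)
    lam = mu ** (2 - power) / (phi * (2 - power))
    alpha = (2 - power) / (power - 1)
    gam_scale = phi * (power - 1) * mu ** (power - 1)
    zero = yf == 0
    out[zero] = -lam[zero]
    pos = ~zero
    if pos.any():
        yv, la, sc = yf[pos], lam[pos], gam_scale[pos]
        # dominant index of the Poisson x Gamma product series
        j_peak = yv ** (2 - power) / (phi * (2 - power))
        j_hi = int(np.ceil((j_peak + 12 * np.sqrt(j_peak) + 20).max()))
        j = np.arange(1.0, j_hi + 1)
        log_terms = (
            -la[:, None] + j[None, :] * np.log(la)[:, None]
            - special.gammaln(j + 1)[None, :]
            + (j[None, :] * alpha - 1) * np.log(yv)[:, None]
            - (yv / sc)[:, None]
            - j[None, :] * alpha * np.log(sc)[:, None]
            - special.gammaln(j * alpha)[None, :]
        )
        while True:
            peak = log_terms.max(axis=1)
            if np.all(log_terms[:, -1] < peak + np.log(rtol)):
                break
            extra = np.arange(float(j_hi + 1), j_hi * 2 + 1.0)
            more = (
                -la[:, None] + extra[None, :] * np.log(la)[:, None]
                - special.gammaln(extra + 1)[None, :]
                + (extra[None, :] * alpha - 1) * np.log(yv)[:, None]
                - (yv / sc)[:, None]
                - extra[None, :] * alpha * np.log(sc)[:, None]
                - special.gammaln(extra * alpha)[None, :]
            )
            log_terms = np.hstack([log_terms, more])
            j_hi *= 2
        peak = log_terms.max(axis=1)
        out[pos] = peak + np.log(np.exp(log_terms - peak[:, None]).sum(axis=1))
    return out.reshape(y.shape)


def nll_tweedie(y, mu, power: float, phi: float) -> float:
    y = np.asarray(y, float)
    if (y < 0).any():
        raise ValueError("tweedie responses must be >= 0")
    return float(-np.sum(tweedie_log_density(y, mu, power, phi)))


def trunc_nb2_logpmf(y, mu, theta):
    """Zero-truncated NB2 log pmf (y >= 1); ``mu`` is the untruncated mean."""
    y = np.asarray(y, float)
    if (y < 1).any():
        raise ValueError("truncated distribution requires y >= 1")
    log_f0 = theta * np.log(theta / (theta + np.asarray(mu, float)))
    return _nb2_logpmf(y, mu, theta) - np.log1p(-np.exp(log_f0))


def hurdle_positive_nll(family_id: str, y_pos, mean_pos, disp: float) -> float:
    """NLL of the strictly-positive part evaluated at its conditional mean.

    ``mean_pos`` is E[y | y > 0] for lognormal/gamma parts and the
    *untruncated* NB mean for the truncated-NB parts (the convention of the
    delta-model literature).
    """
    y = np.asarray(y_pos, float)
    m = np.asarray(mean_pos, float)
    if (y <= 0).any():
        raise ValueError("positive part requires y > 0")
    if family_id.endswith("lognormal"):
        sdlog = disp
        mulog = np.log(m) - 0.5 * sdlog**2  # location such that E[y] = m
        return float(-np.sum(stats.lognorm.logpdf(y, s=sdlog, scale=np.exp(mulog))))
    if family_id.endswith("gamma"):
        shape = disp
        return float(-np.sum(stats.gamma.logpdf(y, a=shape, scale=m / shape)))
    if family_id.endswith("trunc_nb2"):
        return float(-np.sum(trunc_nb2_logpmf(y, m, disp)))
    if family_id.endswith("trunc_nb1"):
        phi = disp
        if phi <= 1:
            raise ValueError("NB1 requires phi > 1")
        theta = m / (phi - 1.0)
        return float(-np.sum(trunc_nb2_logpmf(y, m, theta)))
    raise ValueError(f"no positive part for family {family_id!r}")


def _bernoulli_nll(y_nonzero, p) -> float:
    p = np.clip(np.asarray(p, float), 1e-12, 1 - 1e-12)
    y = np.asarray(y_nonzero, float)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def neg_log_likelihood(family: FamilySpec, counts, means) -> float:
    """Exact negative log density summed over cells.

    For non-hurdle families ``means`` is the per-cell mean.  For hurdle
    families ``means`` is a pair ``(p, mean_pos)`` of presence probability and
    positive-part mean; for the Poisson-link variants it is ``(n, w)`` — the
    latent group density and the positive-part predictor — from which
    ``p = 1 - exp(-n)`` and ``mean_pos = n*w/p``.
    """
    fid = family.family_id
    y = np.asarray(counts, float)
    if fid == "poisson":
        return nll_poisson(y, means)
    if fid == "nb1":
        return nll_nb1(y, means, family.dispersion)
    if fid == "nb2":
        return nll_nb2(y, means, family.dispersion)
    if fid == "tweedie":
        return nll_tweedie(y, means, family.power or 1.5, family.dispersion)
    p, m = means
    p = np.broadcast_to(np.asarray(p, float), y.shape)
    m = np.broadcast_to(np.asarray(m, float), y.shape)
    if is_plink(fid):
        n, w = p, m
        p = 1.0 - np.exp(-n)
        m = n * w / np.clip(p, 1e-12, None)
    pos = y > 0
    nll = _bernoulli_nll(pos.astype(float), p)
    if pos.any():
        nll += hurdle_positive_nll(fid, y[pos], m[pos], family.dispersion)
    return nll


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _sim_trunc_nb2(mu, theta, rng):
    """Zero-truncated NB2 draws by inversion of the conditional CDF."""
    mu = np.asarray(mu, float)
    p_nb = theta / (theta + mu)
    f0 = p_nb**theta
    u = f0 + rng.random(mu.shape) * (1 - f0)  # uniform on (F(0), 1)
    return stats.nbinom.ppf(np.clip(u, None, 1 - 1e-12), theta, p_nb)


def simulate_counts(family: FamilySpec, means, rng) -> np.ndarray:
    """Draw one replicate response matrix from the family at ``means``.

    ``means`` follows the same convention as :func:`neg_log_likelihood`.
    Hurdle families with continuous positive parts return continuous
    positives (zeros remain exact), as delta models do.
    """
    fid = family.family_id
    if fid == "poisson":
        return rng.poisson(np.asarray(means, float)).astype(float)
    if fid == "nb1":
        mu = np.asarray(means, float)
        phi = family.dispersion
        lam = rng.gamma(mu / (phi - 1.0), phi - 1.0)
        return rng.poisson(lam).astype(float)
    if fid == "nb2":
        mu = np.asarray(means, float)
        th = family.dispersion
        return rng.poisson(rng.gamma(th, mu / th)).astype(float)
    if fid == "tweedie":
        mu = np.asarray(means, float)
        p = family.power or 1.5
        phi = family.dispersion
        lam = mu ** (2 - p) / (phi * (2 - p))
        alpha = (2 - p) / (p - 1)
        sc = phi * (p - 1) * mu ** (p - 1)
        n = rng.poisson(lam)
        tot = np.where(n > 0, rng.gamma(np.maximum(n, 1) * alpha, sc), 0.0)
        return np.where(n > 0, tot, 0.0)
    p, m = means
    p = np.asarray(p, float)
    m = np.broadcast_to(np.asarray(m, float), p.shape)
    if is_plink(fid):
        n, w = p, m
        p = 1.0 - np.exp(-n)
        m = n * w / np.clip(p, 1e-12, None)
    present = rng.random(p.shape) < p
    disp = family.dispersion
    if fid.endswith("lognormal"):
        mulog = np.log(m) - 0.5 * disp**2
        pos = rng.lognormal(mulog, disp)
    elif fid.endswith("gamma"):
        pos = rng.gamma(disp, m / disp)
    elif fid.endswith("trunc_nb2"):
        pos = _sim_trunc_nb2(m, disp, rng)
    else:  # trunc_nb1
        pos = _sim_trunc_nb2(m, m / (disp - 1.0), rng)
    return np.where(present, pos, 0.0)
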