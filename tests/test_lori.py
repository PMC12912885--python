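import numpy as np
import pytest

import flywaybench as fb
from flywaybench.lori import (fit_lori, lori_annual_index, multiple_impute,
                              rubin_combine, select_penalties, svt)


def svt_oracle(mat, thr):
    """Brute-force SVD -> threshold -> reconstruct."""
    u, s, vt = np.linalg.svd(mat)
    k = min(mat.shape)
    out = np.zeros_like(mat, dtype=float)
    for i in range(k):
        out += max(s[i] - thr, 0.0) * np.outer(u[:, i], vt[i])
    return out


@pytest.fixture(scope="module")
def missing_panel():
    sites = fb.generate_sites(30, seed=1)
    panel, _ = fb.generate_counts(sites, beta0=np.log(10), beta_year=0.02,
                                  site_sd=0.5, family_id="poisson", seed=2)
    return fb.apply_missingness(panel, 0.15, seed=3)


class TestSvt:
    def test_closed_form_diag(self):
        np.testing.assert_allclose(svt(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]),
                                   atol=1e-12)

    def test_matches_oracle_on_random_5x5(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.normal(size=(5, 5))
            thr = rng.uniform(0, 2)
            np.testing.assert_allclose(svt(m, thr), svt_oracle(m, thr), atol=1e-10)

    def test_negative_threshold_error(self):
        with pytest.raises(ValueError):
            svt(np.eye(2), -1.0)


class TestFitLori:
    def test_objective_monotone(self, missing_panel):
        fit = fit_lori(missing_panel, lambda_nuclear=2.0)
        assert np.all(np.diff(fit.objective_path) <= 1e-9)
        assert (fit.fitted_means > 0).all()

    def test_huge_nuclear_penalty_matches_main_effects_oracle(self, missing_panel):
        """lambda_nuclear -> inf: Theta = 0 and coefficients equal an
        independently optimized main-effects penalized Poisson regression."""
        from scipy.optimize import minimize

        # a firm ridge keeps the main-effects decomposition well identified,
        # so coefficients (not just the objective) are comparable
        lam_main = 1.0
        fit = fit_lori(missing_panel, lambda_main=lam_main, lambda_nuclear=1e10,
                       max_iter=6000, tol=1e-14)
        assert fit.rank == 0
        mask = missing_panel.observed_mask
        y = np.nan_to_num(missing_panel.counts)
        cov = fit.design["covariates"]
        lon, lat, yr = cov["lon"], cov["lat"], cov["year"]
        n, T = missing_panel.counts.shape

        def unpack(v):
            return v[0], v[1:1 + n], v[1 + n:1 + n + T], v[1 + n + T:]

        def obj(v):
            m0, a, b, c = unpack(v)
            eta = (m0 + a[:, None] + b[None, :] + c[0] * lon[:, None]
                   + c[1] * lat[:, None] + c[2] * yr[None, :])
            mu = np.exp(eta)
            return (np.sum(np.where(mask, mu - y * eta, 0.0))
                    + 0.5 * lam_main * (a @ a + b @ b + c @ c))

        v0 = np.zeros(1 + n + T + 3)
        v0[0] = np.log(max(y[mask].mean(), 0.1))
        oracle = minimize(obj, v0, method="L-BFGS-B",
                          options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
        m0o, ao, bo, co = unpack(oracle.x)
        assert fit.cov_coefs["year"] == pytest.approx(co[2], abs=1e-4)
        eta_o = (m0o + ao[:, None] + bo[None, :] + co[0] * lon[:, None]
                 + co[1] * lat[:, None] + co[2] * yr[None, :])
        eta_f = np.log(fit.fitted_means)
        np.testing.assert_allclose(eta_f[mask], eta_o[mask], atol=1e-4)

    def test_rank_one_signal_recovered(self):
        """Strong rank-1 interaction: Theta-hat has rank 1 for small penalty."""
        rng = np.random.default_rng(5)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sites = fb.generate_sites(20, seed=seed)
            u = rng.normal(0, 1, 20)
            v = rng.normal(0, 0.8, 12)
            eta = np.log(20) + np.outer(u, v)
            counts = rng.poisson(np.exp(eta)).astype(float)
            panel = fb.CountPanel(sites=sites, years=np.arange(2000, 2012), counts=counts)
            panel, _ = panel.enforce_zero_generation_rule()
            fit = fit_lori(panel, lambda_main=1e4, lambda_nuclear=30.0, max_iter=800)
            s = np.linalg.svd(fit.theta, compute_uv=False)
            if s[0] > 1e-3 and (len(s) < 2 or s[1] / max(s[0], 1e-12) < 0.35):
                hits += 1
        assert hits >= 9

    def test_penalty_validation(self, missing_panel):
        with pytest.raises(ValueError):
            fit_lori(missing_panel, lambda_nuclear=-1.0)


class TestSelectPenalties:
    def test_pure_noise_gives_rank_zero(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sites = fb.generate_sites(20, seed=seed + 50)
            counts = rng.poisson(8.0, size=(20, 12)).astype(float)
            panel = fb.CountPanel(sites=sites, years=np.arange(2000, 2012), counts=counts)
            panel, _ = panel.enforce_zero_generation_rule()
            _, lam, _ = select_penalties(panel, method="qut", seed=seed)
            fit = fit_lori(panel, lambda_nuclear=lam)
            hits += fit.rank == 0
        assert hits >= 4

    def test_cv_path_complete(self, missing_panel):
        grid = np.array([5.0, 20.0, 80.0])
        _, lam, info = select_penalties(missing_panel, method="cv", seed=1,
                                        grid_nuclear=grid)
        assert len(info["scores"]) == len(grid)
        assert np.all(np.isfinite(info["scores"]))
        assert lam in grid

    def test_seeding(self, missing_panel):
        a = select_penalties(missing_panel, method="qut", seed=3)
        b = select_penalties(missing_panel, method="qut", seed=3)
        assert a[1] == b[1]


class TestMultipleImpute:
    def test_complete_panel_degenerate(self):
        sites = fb.generate_sites(15, seed=9)
        panel, _ = fb.generate_counts(sites, beta0=np.log(10), site_sd=0.3, seed=10)
        completed, totals, within, _ = multiple_impute(panel, m=5, seed=11)
        for k in range(5):
            np.testing.assert_array_equal(completed[k], panel.counts)
        combined = rubin_combine(totals, within)
        assert all(r.B == 0 for r in combined)

    def test_observed_cells_invariant(self, missing_panel):
        completed, _, _, _ = multiple_impute(missing_panel, m=4, seed=12,
                                             lambda_nuclear=5.0)
        mask = missing_panel.observed_mask
        for k in range(4):
            np.testing.assert_array_equal(completed[k][mask], missing_panel.counts[mask])

    def test_imputed_mean_matches_fit(self, missing_panel):
        completed, _, _, base = multiple_impute(missing_panel, m=60, seed=13,
                                                lambda_nuclear=5.0)
        miss = ~missing_panel.observed_mask
        imputed_mean = completed[:, miss].mean(axis=0)
        mu = base.fitted_means[miss]
        # bootstrap refits + Poisson draws: mean within ~4 SE of the base fit
        se = np.sqrt(mu / 60) + 0.15 * mu
        assert np.all(np.abs(imputed_mean - mu) < 4 * se + 1.0)

    def test_reproducible(self, missing_panel):
        a = multiple_impute(missing_panel, m=3, seed=14, lambda_nuclear=5.0)
        b = multiple_impute(missing_panel, m=3, seed=14, lambda_nuclear=5.0)
        np.testing.assert_array_equal(a[0], b[0])

    def test_m_validation(self, missing_panel):
        with pytest.raises(ValueError):
            multiple_impute(missing_panel, m=1)


class TestRubin:
    def test_hand_example(self):
        """totals {100, 110}, within {4, 6}, m=2: W=5, B=50, V=80."""
        out = rubin_combine(np.array([[100.0], [110.0]]), np.array([[4.0], [6.0]]))
        r = out[0]
        assert r.W == pytest.approx(5.0)
        assert r.B == pytest.approx(50.0)
        assert r.V_total == pytest.approx(80.0)
        assert r.estimate == pytest.approx(105.0)
        lo, hi = r.ci95
        assert lo == pytest.approx(105 - 1.96 * np.sqrt(80))
        assert hi == pytest.approx(105 + 1.96 * np.sqrt(80))

    def test_equal_totals(self):
        out = rubin_combine(np.full((4, 2), 7.0), np.full((4, 2), 3.0))
        for r in out:
            assert r.B == 0 and r.V_total == pytest.approx(r.W)

    def test_scaling_property(self):
        base = rubin_combine(np.array([[10.0], [20.0]]), np.zeros((2, 1)))[0]
        scaled = rubin_combine(np.array([[30.0], [60.0]]), np.zeros((2, 1)))[0]
        assert scaled.B == pytest.approx(9 * base.B)
        assert (scaled.ci95[1] - scaled.ci95[0]) == pytest.approx(
            3 * (base.ci95[1] - base.ci95[0]))

    def test_mismatched_error(self):
        with pytest.raises(ValueError):
            rubin_combine(np.ones((3, 2)), np.ones((3, 3)))


def test_annual_index_runs(missing_panel):
    idx, base = lori_annual_index(missing_panel, m=10, seed=15, lambda_nuclear=5.0)
    assert len(idx.totals) == missing_panel.n_years
    assert np.all(idx.lo95 <= idx.totals) and np.all(idx.totals <= idx.hi95)
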