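import numpy as np
import pytest

import flywaybench as fb
from flywaybench.glmm import (GlmmControls, _fit_part, fit_glmm, predict_expected,
                              presence_probability, sanity_check, simulate_from_fit)
from flywaybench.panel import make_site_table
from flywaybench.spatial import SpatialSpec


def _constant_panel(value=5.0, n_sites=10, n_years=8):
    sites = fb.generate_sites(n_sites, seed=0)
    counts = np.full((n_sites, n_years), float(value))
    return fb.CountPanel(sites=sites, years=np.arange(2000, 2000 + n_years), counts=counts)


class TestFitGlmm:
    def test_constant_data(self):
        panel = _constant_panel(5.0)
        fit = fit_glmm(panel, "poisson")
        assert fit.converged
        assert fit.beta0 == pytest.approx(np.log(5.0), abs=1e-3)
        assert fit.beta_year == pytest.approx(0.0, abs=1e-3)
        assert fit.random_sds["site_sd"] < 0.05
        np.testing.assert_allclose(fit.fitted_means, 5.0, rtol=1e-2)

    def test_matches_poisson_glm_oracle(self):
        """Without random effects the Laplace objective is a plain Poisson
        GLM; coefficients must match an independent IRLS solution."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.3 * x)
        y = rng.poisson(mu).astype(float)
        X = np.column_stack([np.ones(n), x])
        part, _ = _fit_part("poisson", y, X, [], None, GlmmControls())
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(part.beta, oracle.params, atol=1e-6)

    def test_poisson_trend_recovery(self):
        sites = fb.generate_sites(100, seed=3)
        panel, _ = fb.generate_counts(sites, beta0=np.log(8), beta_year=0.05,
                                      site_sd=0.5, family_id="poisson", seed=4)
        fit = fit_glmm(panel, "poisson")
        assert fit.converged
        assert abs(fit.beta_year - 0.05) < 3 * fit.beta_year_se
        assert fit.random_sds["site_sd"] == pytest.approx(0.5, abs=0.15)

    def test_nb2_dispersion_recovery(self):
        sites = fb.generate_sites(80, seed=5)
        panel, _ = fb.generate_counts(sites, beta0=np.log(20), family_id="nb2",
                                      dispersion=0.5, site_sd=0.5, seed=6)
        fit = fit_glmm(panel, "nb2")
        assert fit.converged
        assert fit.random_sds["dispersion"] == pytest.approx(0.5, rel=0.25)

    def test_empty_and_degenerate_errors(self):
        sites = make_site_table(["a", "b"], [0, 1], [0, 1])
        one_year = fb.CountPanel(sites=sites, years=np.array([2000]),
                                 counts=np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_glmm(one_year, "poisson")

    def test_hurdle_fit_runs(self, nb2_panel):
        fit = fit_glmm(nb2_panel, "hurdle_gamma")
        assert fit.converged
        assert (fit.fitted_means > 0).all()
        p = presence_probability(fit)
        assert p.shape == fit.fitted_means.shape
        assert ((p > 0) & (p < 1)).all()


class TestPredictExpected:
    def test_constant_fit(self):
        fit = fit_glmm(_constant_panel(5.0), "poisson")
        np.testing.assert_allclose(predict_expected(fit), 5.0, rtol=1e-2)

    def test_cells_interface_and_bounds(self, poisson_fit):
        cells = np.array([[0, 0], [1, 3]])
        vals = predict_expected(poisson_fit, cells)
        assert vals.shape == (2,)
        np.testing.assert_allclose(vals, poisson_fit.fitted_means[[0, 1], [0, 3]])
        with pytest.raises(ValueError):
            predict_expected(poisson_fit, np.array([[0, 999]]))

    def test_monotone_in_year_for_positive_trend(self):
        sites = fb.generate_sites(30, seed=7)
        panel, _ = fb.generate_counts(sites, beta0=np.log(5), beta_year=0.05,
                                      site_sd=0.3, family_id="poisson", seed=8)
        fit = fit_glmm(panel, "poisson")
        assert fit.beta_year > 0
        diffs = np.diff(fit.fitted_means, axis=1)
        assert (diffs > 0).all()

    def test_hurdle_product_rule(self, nb2_panel):
        fit = fit_glmm(nb2_panel, "hurdle_lognormal")
        p = presence_probability(fit)
        # E[count] = presence prob x conditional positive mean => E <= cond mean
        cond = fit.fitted_means / np.clip(p, 1e-12, None)
        assert (fit.fitted_means <= cond + 1e-9).all()


class TestSimulateFromFit:
    def test_unbiasedness(self):
        panel = _constant_panel(5.0, n_sites=20, n_years=10)
        fit = fit_glmm(panel, "poisson")
        sims = simulate_from_fit(fit, panel, n_sims=400, seed=1)
        grand_means = sims.mean(axis=1)
        se = grand_means.std() / np.sqrt(len(grand_means))
        assert abs(grand_means.mean() - 5.0) < 3 * se + 0.05

    def test_seeding_contract(self, poisson_fit, poisson_panel):
        a = simulate_from_fit(poisson_fit, poisson_panel, 5, seed=9)
        b = simulate_from_fit(poisson_fit, poisson_panel, 5, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_hurdle_zero_fraction_matches_presence(self, nb2_panel):
        fit = fit_glmm(nb2_panel, "hurdle_gamma")
        sims = simulate_from_fit(fit, nb2_panel, n_sims=200, seed=2)
        p = presence_probability(fit)[nb2_panel.observed_mask]
        zero_frac = (sims == 0).mean()
        expected = 1 - p.mean()
        se = np.sqrt(expected * (1 - expected) / sims.size)
        assert abs(zero_frac - expected) < 4 * se + 0.01

    def test_requires_n_sims(self, poisson_fit, poisson_panel):
        with pytest.raises(ValueError):
            simulate_from_fit(poisson_fit, poisson_panel, 1, seed=0)


class TestSanity:
    def test_well_conditioned_fit_passes(self, poisson_fit):
        rep = sanity_check(poisson_fit)
        assert rep.passed
        assert rep.gradient_ok and rep.hessian_pd and rep.se_finite and rep.params_in_bounds

    def test_variance_at_bound_flags(self):
        """Constant data drives the site variance to its lower bound."""
        fit = fit_glmm(_constant_panel(5.0), "poisson")
        assert not fit.sanity.params_in_bounds


class TestSpatialStructures:
    @pytest.mark.parametrize("structure", ["ri_grid", "bps"])
    def test_structures_fit(self, structure):
        sites = fb.generate_sites(40, seed=9)
        panel, _ = fb.generate_counts(sites, beta0=np.log(10), site_sd=0.3,
                                      spatial_sd=0.8, spatial_range=8.0,
                                      family_id="poisson", seed=10)
        fit = fit_glmm(panel, "poisson", SpatialSpec(structure))
        assert fit.converged
        assert (fit.fitted_means > 0).all()

    def test_grf_estimates_field(self):
        sites = fb.generate_sites(50, seed=11)
        panel, _ = fb.generate_counts(sites, beta0=np.log(10), site_sd=0.2,
                                      spatial_sd=1.0, spatial_range=8.0,
                                      family_id="poisson", seed=12)
        fit = fit_glmm(panel, "poisson", SpatialSpec("grf", mesh_cutoff_deg=1.0))
        assert fit.converged
        assert fit.random_sds["grf_sd"] > 0.2  # field detected

    def test_barrier_requires_geometry(self):
        with pytest.raises(ValueError):
            SpatialSpec("grf_barrier")
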