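import numpy as np
import pytest

import flywaybench as fb
from flywaybench.trim import fit_trim, trim_time_totals, trim_two_step


@pytest.fixture(scope="module")
def complete_panel():
    sites = fb.generate_sites(25, seed=1)
    panel, _ = fb.generate_counts(sites, beta0=np.log(10), beta_year=0.02,
                                  site_sd=0.6, family_id="poisson", seed=2)
    return panel


@pytest.fixture(scope="module")
def missing_panel(complete_panel):
    return fb.apply_missingness(complete_panel, 0.15, seed=3)


class TestFitTrim:
    def test_saturated_totals_match_observed(self, complete_panel):
        """Complete data, Poisson likelihood equations: fitted yearly totals
        equal observed yearly totals exactly."""
        fit = fit_trim(complete_panel, overdisp=False, serialcor=False)
        idx = trim_time_totals(fit)
        np.testing.assert_allclose(idx.totals, complete_panel.counts.sum(axis=0),
                                   rtol=1e-8)

    def test_matches_poisson_glm_oracle(self, complete_panel):
        """Both options off, complete data: identical to an independent
        Poisson GLM with site + year factors."""
        import pandas as pd
        import statsmodels.formula.api as smf

        fit = fit_trim(complete_panel, overdisp=False, serialcor=False)
        rows = []
        for i, sid in enumerate(complete_panel.site_ids):
            for j, yr in enumerate(complete_panel.years):
                rows.append((sid, str(yr), complete_panel.counts[i, j]))
        df = pd.DataFrame(rows, columns=["site", "year", "y"])
        glm = smf.glm("y ~ C(site) + C(year)", data=df,
                      family=__import__("statsmodels.api", fromlist=["x"]).families.Poisson()).fit()
        mu_oracle = np.asarray(glm.fittedvalues).reshape(complete_panel.counts.shape)
        np.testing.assert_allclose(fit.fitted_means, mu_oracle, rtol=1e-6)
        # year effects match the treatment-coded year coefficients
        year_coefs = np.array([glm.params[f"C(year)[T.{yr}]"]
                               for yr in complete_panel.years[1:]])
        np.testing.assert_allclose(fit.year_effects[1:, 0], year_coefs, atol=1e-6)

    def test_poisson_calibration(self, missing_panel):
        fit = fit_trim(missing_panel, overdisp=True, serialcor=True)
        n_obs = missing_panel.observed_mask.sum()
        se_sigma = np.sqrt(2.0 / (n_obs - fit.n_params))
        assert abs(fit.sigma2 - 1.0) < 4 * se_sigma
        assert abs(fit.rho) < 0.1

    def test_quasi_poisson_sigma2_recovery(self):
        """NB1-type noise with Var = 3 mu: sigma^2-hat ~ 3."""
        sites = fb.generate_sites(30, seed=4)
        panel, _ = fb.generate_counts(sites, beta0=np.log(20), family_id="nb1",
                                      dispersion=3.0, site_sd=0.5, seed=5)
        fit = fit_trim(panel, overdisp=True, serialcor=False)
        assert fit.sigma2 == pytest.approx(3.0, rel=0.25)

    def test_missing_cell_adds_to_total(self, complete_panel):
        counts = complete_panel.counts.copy()
        counts[0, 5] = np.nan
        panel = fb.CountPanel(sites=complete_panel.sites, years=complete_panel.years,
                              counts=counts)
        fit = fit_trim(panel, overdisp=False, serialcor=False)
        idx = trim_time_totals(fit)
        observed_sum = np.nansum(panel.counts[:, 5])
        assert idx.totals[5] == pytest.approx(observed_sum + fit.fitted_means[0, 5], rel=1e-6)

    def test_doubling_counts_doubles_totals(self, complete_panel):
        fit1 = fit_trim(complete_panel, overdisp=False, serialcor=False)
        doubled = complete_panel.with_counts(complete_panel.counts * 2)
        fit2 = fit_trim(doubled, overdisp=False, serialcor=False)
        np.testing.assert_allclose(trim_time_totals(fit2).totals,
                                   2 * trim_time_totals(fit1).totals, rtol=1e-7)

    def test_site_relabeling_invariance(self, missing_panel):
        fit1 = fit_trim(missing_panel)
        perm = np.random.default_rng(0).permutation(missing_panel.n_sites)
        shuffled = missing_panel.subset_sites(perm)
        fit2 = fit_trim(shuffled)
        assert fit1.sigma2 == pytest.approx(fit2.sigma2, rel=1e-6)

    def test_region_year_effects(self, missing_panel):
        region = {s: ("north" if i % 2 else "south")
                  for i, s in enumerate(missing_panel.site_ids)}
        fit = fit_trim(missing_panel, region_map=region)
        assert fit.converged
        assert fit.year_effects.shape == (missing_panel.n_years, 2)

    def test_empty_year_error(self, complete_panel):
        counts = complete_panel.counts.copy()
        counts[:, 3] = np.nan
        panel = fb.CountPanel(sites=complete_panel.sites, years=complete_panel.years,
                              counts=counts)
        panel, _ = panel.enforce_zero_generation_rule()
        with pytest.raises(ValueError, match="year"):
            fit_trim(panel)


class TestTwoStep:
    def test_rules(self, missing_panel):
        """Poisson data: sigma2 < 1 and rho < 0.2 -> both options disabled."""
        fit = trim_two_step(missing_panel)
        step1 = fit.steps[0]
        assert step1[0] == "step1"
        sigma1, rho1 = step1[1], step1[2]
        assert fit.overdisp_on == (sigma1 >= 1.0)
        assert fit.serialcor_on == (rho1 >= 0.2)

    def test_overdispersed_data_keeps_option(self):
        sites = fb.generate_sites(30, seed=6)
        panel, _ = fb.generate_counts(sites, beta0=np.log(20), family_id="nb1",
                                      dispersion=4.0, site_sd=0.5, seed=7)
        fit = trim_two_step(panel)
        assert fit.overdisp_on
        assert fit.sigma2 > 1.0

    def test_no_refit_when_both_kept(self):
        sites = fb.generate_sites(25, seed=8)
        panel, _ = fb.generate_counts(sites, beta0=np.log(30), family_id="nb1",
                                      dispersion=5.0, site_sd=0.5, seed=9)
        # inject strong serial correlation by smoothing counts in time
        c = panel.counts.copy()
        sm = np.round((c[:, :-1] + c[:, 1:]) / 2)
        c[:, 1:] = sm
        panel = panel.with_counts(c)
        fit = trim_two_step(panel)
        if fit.overdisp_on and fit.serialcor_on:
            assert len(fit.steps) == 1


class TestCoverage:
    def test_mcar_poisson_ci_coverage(self):
        """Time-total 95% CIs cover the true totals under MCAR missingness."""
        covered = total = 0
        for seed in range(50):
            sites = fb.generate_sites(15, seed=100 + seed)
            panel, _ = fb.generate_counts(sites, beta0=np.log(15), beta_year=0.01,
                                          site_sd=0.4, family_id="poisson",
                                          seed=200 + seed)
            panel = fb.apply_missingness(panel, 0.2, seed=300 + seed)
            truth = panel.truth.true_totals
            fit = fit_trim(panel, overdisp=False, serialcor=False)
            if not fit.converged:
                continue
            idx = trim_time_totals(fit)
            covered += int(np.sum((idx.lo95 <= truth) & (truth <= idx.hi95)))
            total += len(truth)
        assert covered / total >= 0.90
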