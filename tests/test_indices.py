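import numpy as np
import pytest

import flywaybench as fb
from flywaybench.indices import (AnnualIndex, glmm_index, percent_difference,
                                 rrmse, trend_from_index)


class TestTrend:
    def test_closed_form(self):
        idx = AnnualIndex("x", np.arange(2000, 2004), [100, 110, 120, 130],
                          [90, 100, 110, 120], [110, 120, 130, 140])
        tr = trend_from_index(idx)
        assert tr.slope == pytest.approx(10.0)
        assert tr.slope_per_1000 == pytest.approx(1000 * 10 / 115, abs=1e-9)
        # perfect line: zero residual variance, zero SE
        assert tr.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_constant_totals(self):
        idx = AnnualIndex("x", np.arange(2000, 2006), np.full(6, 50.0),
                          np.full(6, 40.0), np.full(6, 60.0))
        tr = trend_from_index(idx)
        assert tr.slope == pytest.approx(0.0)
        assert tr.ci95[0] <= 0 <= tr.ci95[1]

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(0)
        totals = rng.uniform(50, 150, 8)
        years = np.arange(2000, 2008)
        a = trend_from_index(AnnualIndex("x", years, totals, totals, totals))
        b = trend_from_index(AnnualIndex("x", years, totals[::-1],
                                         totals[::-1], totals[::-1]))
        assert a.slope == pytest.approx(-b.slope)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        years = np.arange(1995, 2021)
        totals = 100 + 2.0 * (years - years.mean()) + rng.normal(0, 5, 26)
        tr = trend_from_index(AnnualIndex("x", years, totals, totals, totals))
        # independent closed-form OLS
        b = np.polyfit(years, totals, 1)[0]
        assert tr.slope == pytest.approx(b, abs=1e-10)

    def test_too_few_years(self):
        idx = AnnualIndex("x", [2000, 2001], [1.0, 2.0], [1, 2], [1, 2])
        with pytest.raises(ValueError):
            trend_from_index(idx)


class TestRrmse:
    def test_perfect_fit(self, poisson_panel):
        m = rrmse(poisson_panel, poisson_panel.counts)
        assert m.value == 0.0

    def test_hand_example(self):
        sites = fb.make_site_table(["a"], [0.0], [0.0])
        panel = fb.CountPanel(sites=sites, years=np.array([2000, 2001]),
                              counts=np.array([[0.0, 4.0]]))
        m = rrmse(panel, np.array([[2.0, 2.0]]))
        assert m.value == pytest.approx(1.0)
        assert m.n_cells == 2

    def test_scale_invariance(self):
        sites = fb.make_site_table(["a"], [0.0], [0.0])
        y = np.array([[1.0, 5.0, 3.0]])
        mu = np.array([[2.0, 4.0, 3.0]])
        panel1 = fb.CountPanel(sites=sites, years=np.arange(3), counts=y)
        panel3 = fb.CountPanel(sites=sites, years=np.arange(3), counts=3 * y)
        assert rrmse(panel1, mu).value == pytest.approx(rrmse(panel3, 3 * mu).value)

    def test_all_zero_guard(self):
        sites = fb.make_site_table(["a"], [0.0], [0.0])
        panel = fb.CountPanel(sites=sites, years=np.arange(2), counts=np.zeros((1, 2)))
        with pytest.raises(ValueError):
            rrmse(panel, np.ones((1, 2)))


class TestPercentDifference:
    def test_printed_estimates(self):
        # late-period divergence between imputation and mixed-model estimates
        assert percent_difference(185_000, 110_000) == pytest.approx(68.2)
        # early-period agreement
        assert percent_difference(95_000, 106_000) == pytest.approx(-10.4)

    def test_identity(self):
        assert percent_difference(42.0, 42.0) == 0.0

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestGlmmIndex:
    def test_additivity(self, poisson_fit, poisson_panel):
        idx = glmm_index(poisson_fit, poisson_panel, n_draws=50, seed=1)
        np.testing.assert_allclose(idx.totals, poisson_fit.fitted_means.sum(axis=0))

    def test_ci_brackets_point(self, poisson_fit, poisson_panel):
        idx = glmm_index(poisson_fit, poisson_panel, n_draws=200, seed=2)
        assert np.all(idx.lo95 <= idx.totals)
        assert np.all(idx.totals <= idx.hi95)

    def test_constant_panel_totals(self):
        sites = fb.generate_sites(10, seed=3)
        counts = np.full((10, 6), 5.0)
        panel = fb.CountPanel(sites=sites, years=np.arange(2000, 2006), counts=counts)
        fit = fb.fit_glmm(panel, "poisson")
        idx = glmm_index(fit, panel, n_draws=50, seed=4)
        np.testing.assert_allclose(idx.totals, 50.0, rtol=1e-2)


class TestAnnualIndexValidation:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            AnnualIndex("x", [2000], [10.0], [11.0], [12.0])

    def test_alignment_enforced(self):
        with pytest.raises(ValueError):
            AnnualIndex("x", [2000, 2001], [10.0], [9.0], [11.0])


def test_compare_methods_shape(poisson_panel_missing):
    panel = fb.filter_min_surveys(poisson_panel_missing)
    report = fb.compare_methods(panel, [fb.DesignSpec("raw")], ["simple_glmm"],
                                seed=1, n_sims=60)
    assert len(report.rows) == 1
    row = report.rows[0]
    assert row["converged"]
    for key in ("index", "trend", "rrmse", "od", "zi", "sa"):
        assert row[key] is not None
    assert "trend_bias" in row  # truth available from the generator
    frame = report.to_index_frame()
    assert set(frame.columns) == {"design", "method", "year", "total", "lo95", "hi95"}
    assert len(frame) == panel.n_years
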