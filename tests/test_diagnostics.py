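import numpy as np
import pytest

import flywaybench as fb
from flywaybench.diagnostics import (_mc_two_sided_p, dispersion_test_sim,
                                     great_circle_km, morans_i_test, pearson_od_test,
                                     residuals_for_moran, zero_inflation_test_sim,
                                     zeros_chisq_test)


def moran_brute_force(values, coords):
    """Independent double-loop Moran's I with inverse-distance weights."""
    z = np.asarray(values, float)
    n = len(z)
    d = great_circle_km(np.asarray(coords, float))
    zc = z - z.mean()
    num = s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = 1.0 / d[i, j]
            num += w * zc[i] * zc[j]
            s0 += w
    return (n / s0) * num / np.sum(zc**2)


class TestMoran:
    def test_hand_example_equidistant(self):
        """Three equidistant sites with values (1, 0, -1): I = -1/(n-1)."""
        # near-equilateral triangle on a small patch of the sphere
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        res = morans_i_test(np.array([1.0, 0.0, -1.0]), coords)
        assert res.statistic == pytest.approx(-0.5, abs=0.01)
        assert res.p_value > 0.9

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = np.column_stack([rng.uniform(-5, 5, 40), rng.uniform(30, 50, 40)])
        values = rng.normal(size=40)
        res = morans_i_test(values, coords)
        assert res.statistic == pytest.approx(moran_brute_force(values, coords), abs=1e-12)

    def test_constant_values_error(self):
        coords = np.array([[0, 0], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError):
            morans_i_test(np.ones(3), coords)

    def test_detects_spatial_field(self):
        """Long-range field values across 100 sites: strongly significant."""
        sites = fb.generate_sites(100, seed=1)
        coords = sites[["lon", "lat"]].to_numpy()
        from flywaybench.simulate import _spatial_field
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = _spatial_field(coords, sd=1.0, range_deg=10.0, rng=rng)
            hits += morans_i_test(vals, coords).significant
        assert hits >= 9

    def test_coincident_sites_warn(self):
        coords = np.array([[0, 0], [0, 0], [1, 1.0]])
        with pytest.warns(UserWarning, match="coincident"):
            morans_i_test(np.array([1.0, 2.0, 3.0]), coords)


class TestPearsonOd:
    def test_x2_equal_df(self):
        """X^2 == df: statistic 1, p ~ 0.49 at df = 100."""
        rng = np.random.default_rng(1)
        mu = np.full(103, 4.0)
        # construct residuals with exactly X^2 = 100 (df = 103 - 3)
        y = mu + np.sqrt(mu) * np.sqrt(100 / 103)
        y = np.round(y)  # keep integers: recompute the implied statistic
        res = pearson_od_test(y, mu, n_params=3)
        from scipy.stats import chi2
        x2 = np.sum((y - mu) ** 2 / mu)
        assert res.statistic == pytest.approx(x2 / 100)
        assert res.p_value == pytest.approx(chi2.sf(x2, 100), abs=1e-12)

    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_od_test(y, y, 1).p_value == pytest.approx(1.0)

    def test_poisson_calibrated_statistic(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(5.0, 10_000).astype(float)
        res = pearson_od_test(y, np.full(10_000, 5.0), n_params=1)
        # E[X2/df] = 1, SD ~ sqrt(2/df) times the kurtosis factor
        assert abs(res.statistic - 1.0) < 3 * np.sqrt(3.0 / 10_000)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(3.0, 50).astype(float)
        mu = rng.uniform(2, 4, 50)
        a = pearson_od_test(y, mu, 2).statistic
        perm = rng.permutation(50)
        b = pearson_od_test(y[perm], mu[perm], 2).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_df_validation(self):
        with pytest.raises(ValueError):
            pearson_od_test(np.ones(3), np.ones(3), 3)


class TestZerosChisq:
    def test_identical_vectors(self):
        y = np.array([0.0, 0, 1, 2, 0, 5])
        res = zeros_chisq_test(y, y)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_many_unmodeled_zeros_significant(self):
        y = np.concatenate([np.zeros(60), np.ones(40)])
        mu = np.full(100, 2.0)  # rounds to 2: zero expected zeros
        res = zeros_chisq_test(y, mu)
        assert res.significant

    def test_empty_error(self):
        with pytest.raises(ValueError):
            zeros_chisq_test(np.array([]), np.array([]))


class TestSimTests:
    def test_null_model_not_significant(self, poisson_fit, poisson_panel):
        od = dispersion_test_sim(poisson_fit, poisson_panel, n_sims=200, seed=1)
        zi = zero_inflation_test_sim(poisson_fit, poisson_panel, n_sims=200, seed=2)
        assert not od.significant
        assert not zi.significant
        assert od.statistic == pytest.approx(1.0, abs=0.2)

    def test_overdispersion_detected(self, nb2_panel):
        fit = fb.fit_glmm(nb2_panel, "poisson")
        od = dispersion_test_sim(fit, nb2_panel, n_sims=200, seed=3)
        assert od.significant
        assert od.statistic > 2

    def test_zero_inflation_detected(self):
        sites = fb.generate_sites(40, seed=6)
        panel, _ = fb.generate_counts(sites, beta0=np.log(10), site_sd=0.3,
                                      zi_prob=0.5, family_id="poisson", seed=7)
        fit = fb.fit_glmm(panel, "poisson")
        zi = zero_inflation_test_sim(fit, panel, n_sims=200, seed=8)
        assert zi.significant
        assert zi.statistic > 1.5

    def test_reproducible_under_seed(self, poisson_fit, poisson_panel):
        a = dispersion_test_sim(poisson_fit, poisson_panel, n_sims=50, seed=11)
        b = dispersion_test_sim(poisson_fit, poisson_panel, n_sims=50, seed=11)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_mc_p_tie_convention(self):
        # observed equal to every simulated value -> p = 1
        assert _mc_two_sided_p(1.0, np.ones(99)) == pytest.approx(1.0)


class TestResidualsForMoran:
    def test_hand_arithmetic(self):
        sites = fb.make_site_table(["a", "b"], [0, 1], [0, 1])
        panel = fb.CountPanel(sites=sites, years=np.array([2000, 2001]),
                              counts=np.array([[2.0, 4.0], [1.0, np.nan]]))
        fitted = np.array([[1.0, 3.0], [0.5, 9.9]])
        vals = residuals_for_moran(panel, fitted)
        np.testing.assert_allclose(vals, [1.0, 0.5])

    def test_perfect_fit_zero(self, poisson_panel, poisson_fit):
        vals = residuals_for_moran(poisson_panel, poisson_panel.counts)
        np.testing.assert_allclose(vals, 0.0)

    def test_constant_shift(self, poisson_panel):
        fitted = poisson_panel.counts.copy()
        base = residuals_for_moran(poisson_panel, fitted)
        shifted = residuals_for_moran(poisson_panel, fitted + 2.0)
        np.testing.assert_allclose(shifted, base - 2.0)
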