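import numpy as np
import pytest

import flywaybench as fb


@pytest.fixture(scope="session")
def poisson_panel():
    """Poisson panel with a site random intercept and a mild trend."""
    sites = fb.generate_sites(40, seed=1)
    panel, _ = fb.generate_counts(sites, beta0=np.log(8.0), beta_year=0.02,
                                  site_sd=0.5, family_id="poisson", seed=2)
    return panel


@pytest.fixture(scope="session")
def poisson_panel_missing(poisson_panel):
    return fb.apply_missingness(poisson_panel, 0.15, seed=3)


@pytest.fixture(scope="session")
def nb2_panel():
    """Strongly overdispersed NB2 panel."""
    sites = fb.generate_sites(40, seed=4)
    panel, _ = fb.generate_counts(sites, beta0=np.log(20.0), beta_year=0.02,
                                  site_sd=0.5, family_id="nb2", dispersion=0.5,
                                  seed=5)
    return panel


@pytest.fixture(scope="session")
def poisson_fit(poisson_panel):
    return fb.fit_glmm(poisson_panel, "poisson")


@pytest.fixture(scope="session")
def tiny_panel():
    """2 sites x 2 years, counts [[0, 2], [4, missing]]."""
    sites = fb.make_site_table(["a", "b"], [0.0, 1.0], [0.0, 1.0])
    counts = np.array([[0.0, 2.0], [4.0, np.nan]])
    return fb.CountPanel(sites=sites, years=np.array([2000, 2001]), counts=counts)
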