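"""Site x year count panels: the universal input container.

A :class:`CountPanel` holds a rectangular site x year matrix of non-negative
integer counts with missing cells (NaN), the site coordinate table, and an
optional :class:`TruthRecord` describing the generating process when the panel
is synthetic.  Every modeling approach in this package consumes a panel and
every sampling-design transform maps panel -> panel.

Panels obey the *zero-generation rule* of site-based census schemes: a zero is
only recorded at a site where the species has been seen at least once over the
monitoring period, so every retained site must have at least one positive
observed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TruthRecord",
    "CountPanel",
    "PanelSummary",
    "make_site_table",
    "summarize_panel",
    "read_panel_csv",
    "write_panel_csv",
]


def make_site_table(site_ids: Sequence[str], lon: Sequence[float], lat: Sequence[float]) -> pd.DataFrame:
    """Build and validate a site table (``site_id``, ``lon``, ``lat``)."""
    sites = pd.DataFrame({"site_id": list(site_ids), "lon": np.asarray(lon, float), "lat": np.asarray(lat, float)})
    if sites["site_id"].duplicated().any():
        raise ValueError("site_id values must be unique")
    if not ((sites["lon"] >= -180) & (sites["lon"] <= 180)).all():
        raise ValueError("longitudes must lie in [-180, 180]")
    if not ((sites["lat"] >= -90) & (sites["lat"] <= 90)).all():
        raise ValueError("latitudes must lie in [-90, 90]")
    return sites.reset_index(drop=True)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth parameters of a synthetic panel.

    Real census data never come with truth; synthetic panels carry one so that
    parameter-recovery and coverage tests are possible.

    Parameters are on the log scale of the mean: ``log mu_it = beta0 +
    beta_year * (t - mean(t)) + u_i + s_i`` with ``u_i ~ N(0, site_sd^2)`` and
    ``s`` a stationary spatial field with exponential correlation of range
    ``spatial_range`` (decimal degrees) and marginal SD ``spatial_sd``.
    """

    beta0: float
    beta_year: float
    site_sd: float
    spatial_sd: float
    spatial_range: float
    family_id: str
    dispersion: float
    zi_prob: float
    true_totals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if min(self.site_sd, self.spatial_sd, self.spatial_range) < 0:
            raise ValueError("SD and range parameters must be >= 0")
        if not 0 <= self.zi_prob < 1:
            raise ValueError("zi_prob must lie in [0, 1)")
        object.__setattr__(self, "true_totals", np.asarray(self.true_totals, float))
        if self.true_totals.size and not (self.true_totals > 0).all():
            raise ValueError("true_totals must be positive")


@dataclass
class CountPanel:
    """A site x year count matrix with missing cells.

    ``counts`` is a float matrix of shape ``(n_sites, n_years)``; missing
    cells are NaN, all other entries are non-negative integers.
    """

    sites: pd.DataFrame
    years: np.ndarray
    counts: np.ndarray
    truth: TruthRecord | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (len(self.sites), len(self.years)):
            raise ValueError(
                f"counts shape {self.counts.shape} != (n_sites={len(self.sites)}, n_years={len(self.years)})"
            )
        obs = self.counts[np.isfinite(self.counts)]
        if obs.size and ((obs < 0).any() or (obs != np.round(obs)).any()):
            raise ValueError("observed counts must be non-negative integers")

    # -- basic views -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.counts)

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites["site_id"].to_numpy()

    def coords(self) -> np.ndarray:
        """Site coordinates as an (n_sites, 2) lon/lat array."""
        return self.sites[["lon", "lat"]].to_numpy(float)

    def site_mean_counts(self) -> np.ndarray:
        """Per-site arithmetic mean over observed cells only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=1)

    def satisfies_zero_generation_rule(self) -> bool:
        """True iff every site has >= 1 observed positive count."""
        with np.errstate(invalid="ignore"):
            return bool(np.all(np.nansum(self.counts > 0, axis=1) > 0))

    def subset_sites(self, keep: np.ndarray) -> "CountPanel":
        """Panel restricted to a boolean/integer site selection (truth kept)."""
        keep = np.asarray(keep)
        return CountPanel(
            sites=self.sites.iloc[keep].reset_index(drop=True) if keep.dtype != bool
            else self.sites.loc[keep].reset_index(drop=True),
            years=self.years.copy(),
            counts=self.counts[keep].copy(),
            truth=self.truth,
        )

    def with_counts(self, counts: np.ndarray) -> "CountPanel":
        return replace(self, counts=np.asarray(counts, float))

    def enforce_zero_generation_rule(self) -> tuple["CountPanel", int]:
        """Drop sites with no observed positive count; return (panel, n_dropped)."""
        with np.errstate(invalid="ignore"):
            keep = np.nansum(self.counts > 0, axis=1) > 0
        dropped = int((~keep).sum())
        if dropped == 0:
            return self, 0
        return self.subset_sites(keep), dropped


@dataclass(frozen=True)
class PanelSummary:
    """Descriptive statistics of a panel, in census-report layout.

    Count statistics (mean, SD, quantiles, max) are over observed cells only;
    ``n_site_year`` counts all cells including missing ones, so
    ``pct_missing = 100 * n_missing / n_site_year``.
    """

    n_sites: int
    mean_count_per_site: float
    sd_count: float
    q05: float
    q50: float
    q95: float
    max_count: float
    n_site_year: int
    n_missing: int
    pct_missing: float
    pct_zero_of_observed: float

    @property
    def pct_missing_display(self) -> float:
        return round(self.pct_missing, 1)


def summarize_panel(panel: CountPanel) -> PanelSummary:
    """Summary statistics over a panel's observed cells."""
    if panel.n_sites == 0:
        raise ValueError("cannot summarize a panel with zero sites")
    obs = panel.counts[panel.observed_mask]
    n_cells = panel.n_sites * panel.n_years
    n_missing = n_cells - obs.size
    if obs.size == 0:
        raise ValueError("panel has no observed cells")
    q05, q50, q95 = np.quantile(obs, [0.05, 0.50, 0.95])
    return PanelSummary(
        n_sites=panel.n_sites,
        mean_count_per_site=float(obs.mean()),
        sd_count=float(obs.std(ddof=1)) if obs.size > 1 else 0.0,
        q05=float(q05),
        q50=float(q50),
        q95=float(q95),
        max_count=float(obs.max()),
        n_site_year=n_cells,
        n_missing=n_missing,
        pct_missing=100.0 * n_missing / n_cells,
        pct_zero_of_observed=100.0 * float((obs == 0).mean()),
    )


# -- CSV dialect -----------------------------------------------------------
# Long format `site_id,year,count` with an empty count field for missing,
# plus a companion `site_id,lon,lat` table.  UTF-8, header row required.

def write_panel_csv(panel: CountPanel, counts_path: str | Path, sites_path: str | Path) -> None:
    """Write a panel in the long-format CSV dialect."""
    rows = []
    for i, sid in enumerate(panel.site_ids):
        for j, year in enumerate(panel.years):
            c = panel.counts[i, j]
            rows.append((sid, int(year), "" if not np.isfinite(c) else int(c)))
    pd.DataFrame(rows, columns=["site_id", "year", "count"]).to_csv(counts_path, index=False)
    panel.sites.to_csv(sites_path, index=False)


def read_panel_csv(counts_path: str | Path, sites_path: str | Path) -> CountPanel:
    """Read a panel from the long-format CSV dialect."""
    long = pd.read_csv(counts_path, dtype={"site_id": str})
    sites = pd.read_csv(sites_path, dtype={"site_id": str})
    sites = make_site_table(sites["site_id"], sites["lon"], sites["lat"])
    years = np.sort(long["year"].unique())
    wide = long.pivot(index="site_id", columns="year", values="count")
    wide = wide.reindex(index=sites["site_id"], columns=years)
    return CountPanel(sites=sites, years=years, counts=wide.to_numpy(float))
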