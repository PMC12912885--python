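"""Sampling-design perturbations of a count panel.

Four dataset configurations mimic realistic monitoring biases:

``raw``
    the panel untouched (after the minimum-survey filter).
``larger_out``
    remove the 10% of sites with the highest mean counts — the largest
    sites are too vast to monitor.  Missingness depends on abundance, i.e.
    missing not at random (MNAR).
``smaller_out``
    remove the 10% of sites with the lowest mean counts — small sites judged
    not worth the effort.
``unbalanced``
    convert to missing 20% of the counts of high-mean sites (mean count above
    the 0.75 quantile) in the early period, and 20% of the counts of low-mean
    sites (mean below the 0.25 quantile) in the late period: a temporal shift
    of monitoring resources from small to large sites.

All transforms are pure and seeded; they never create counts, only remove
sites or mask cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .panel import CountPanel

__all__ = ["DesignSpec", "DESIGN_IDS", "filter_min_surveys", "site_mean_counts", "apply_design"]

log = logging.getLogger(__name__)

DESIGN_IDS = ("raw", "larger_out", "smaller_out", "unbalanced")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one sampling-design perturbation."""

    design_id: str = "raw"
    drop_fraction: float = 0.10
    convert_fraction: float = 0.20
    q_low: float = 0.25
    q_high: float = 0.75
    split_year: int | None = None  # first year of the late period; default midpoint
    per_site: bool = False  # stratify the 20% conversion within each site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design_id not in DESIGN_IDS:
            raise ValueError(f"design_id must be one of {DESIGN_IDS}")
        for f in (self.drop_fraction, self.convert_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if not self.q_low < self.q_high:
            raise ValueError("q_low must be < q_high")


def filter_min_surveys(panel: CountPanel, min_surveys: int = 15) -> CountPanel:
    """Remove sites with fewer than ``min_surveys`` observed cells.

    A site with exactly ``min_surveys`` observed cells is retained.
    """
    if min_surveys < 1:
        raise ValueError("min_surveys must be >= 1")
    n_obs = panel.observed_mask.sum(axis=1)
    keep = n_obs >= min_surveys
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("minimum-survey filter removed every site")
    if removed:
        log.info("filter_min_surveys: removed %d of %d sites", removed, panel.n_sites)
    return panel.subset_sites(keep) if removed else panel


def site_mean_counts(panel: CountPanel) -> np.ndarray:
    """Per-site arithmetic mean over observed cells only."""
    n_obs = panel.observed_mask.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("every site needs >= 1 observed cell to compute its mean")
    return panel.site_mean_counts()


def _remove_extreme_sites(panel: CountPanel, frac: float, highest: bool) -> CountPanel:
    means = site_mean_counts(panel)
    k = int(np.floor(frac * panel.n_sites))
    if k >= panel.n_sites:
        raise ValueError("cannot remove all sites")
    if k == 0:
        return panel
    # ties broken by site_id lexicographic order
    order = np.lexsort((panel.site_ids, -means if highest else means))
    drop = set(order[:k])
    keep = np.array([i not in drop for i in range(panel.n_sites)])
    return panel.subset_sites(keep)


def _convert_block(counts, mask_sites, year_sel, frac, rng, per_site):
    """Mask round(frac * eligible) observed cells in a site/period block."""
    obs = np.isfinite(counts)
    eligible = np.zeros_like(obs)
    eligible[np.ix_(mask_sites, year_sel)] = obs[np.ix_(mask_sites, year_sel)]
    idx = np.argwhere(eligible)
    if len(idx) == 0:
        warnings.warn("unbalanced design: no eligible cells in group; converting none")
        return counts
    if per_site:
        for i in np.flatnonzero(mask_sites):
            cols = np.flatnonzero(eligible[i])
            m = int(round(frac * len(cols)))
            if m:
                pick = rng.choice(cols, size=m, replace=False)
                counts[i, pick] = np.nan
        return counts
    m = int(round(frac * len(idx)))
    if m:
        pick = idx[rng.choice(len(idx), size=m, replace=False)]
        counts[pick[:, 0], pick[:, 1]] = np.nan
    return counts


def apply_design(panel: CountPanel, spec: DesignSpec) -> CountPanel:
    """Apply one sampling-design perturbation to an already-filtered panel."""
    if spec.design_id == "raw":
        return panel
    if spec.design_id == "larger_out":
        return _remove_extreme_sites(panel, spec.drop_fraction, highest=True)
    if spec.design_id == "smaller_out":
        return _remove_extreme_sites(panel, spec.drop_fraction, highest=False)

    # unbalanced
    rng = np.random.default_rng(spec.seed)
    means = site_mean_counts(panel)
    q_lo, q_hi = np.quantile(means, [spec.q_low, spec.q_high])  # type-7 interpolation
    high = means > q_hi
    low = means < q_lo
    split = spec.split_year if spec.split_year is not None else int(np.median(panel.years)) + 1
    if not panel.years.min() < split <= panel.years.max():
        raise ValueError("split_year must lie strictly inside the year range")
    early = panel.years < split
    late = ~early
    if not high.any() and not low.any():
        warnings.warn("unbalanced design: degenerate quantiles select no sites; panel unchanged")
        return panel
    counts = panel.counts.copy()
    if high.any():
        counts = _convert_block(counts, high, early, spec.convert_fraction, rng, spec.per_site)
    if low.any():
        counts = _convert_block(counts, low, late, spec.convert_fraction, rng, spec.per_site)
    return CountPanel(sites=panel.sites.copy(), years=panel.years.copy(), counts=counts, truth=panel.truth)
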