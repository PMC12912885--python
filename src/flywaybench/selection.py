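"""Optimized-GLMM selection: first the probability distribution, then the
spatial structure.

Distribution stage: families are tried in a fixed priority order of
increasing statistical complexity; the first converged family whose
dispersion and zero-inflation tests are both non-significant is selected.
If none qualifies, the fallback picks the candidate whose test statistics
are jointly closest to their null value of 1 (overdispersion first,
lexicographically), ties broken by priority order.

Spatial stage: the structure-free fit is kept if its Moran's I test on
per-site simulation residuals is already non-significant; otherwise the
structures are tried in the order grid random intercept, coordinate smooth,
Gaussian field (finer mesh first), Gaussian field with barrier, and the
first converged structure with non-significant Moran's I wins.  If none
succeeds, the structure with minimal |I| is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import TestResult, glmm_moran_values, morans_i_test, od_zi_tests
from .families import FAMILY_ORDER, FamilySpec
from .glmm import FitResult, GlmmControls, fit_glmm
from .panel import CountPanel
from .spatial import SpatialSpec

__all__ = ["SelectionTrace", "TraceEntry", "select_distribution", "select_spatial",
           "optimized_glmm", "DEFAULT_STRUCTURE_ORDER"]

log = logging.getLogger(__name__)

DEFAULT_STRUCTURE_ORDER = (
    SpatialSpec("ri_grid"),
    SpatialSpec("bps"),
    SpatialSpec("grf", mesh_cutoff_deg=0.5),
    SpatialSpec("grf", mesh_cutoff_deg=1.0),
)


@dataclass
class TraceEntry:
    candidate_id: str
    converged: bool
    od_test: TestResult | None = None
    zi_test: TestResult | None = None
    sa_test: TestResult | None = None
    selected: bool = False


@dataclass
class SelectionTrace:
    """Ordered record of every candidate attempted at one selection stage."""

    stage: str
    entries: list[TraceEntry] = field(default_factory=list)
    selection_rule: str = "first_nonsignificant"

    @property
    def selected_id(self) -> str | None:
        for e in self.entries:
            if e.selected:
                return e.candidate_id
        return None

    def to_dict(self) -> dict:
        """JSON-serializable record of the whole stage."""
        def tr(t):
            return None if t is None else {"statistic": t.statistic,
                                           "p_value": t.p_value,
                                           "significant": t.significant}
        return {
            "stage": self.stage,
            "selection_rule": self.selection_rule,
            "selected": self.selected_id,
            "entries": [{"candidate": e.candidate_id, "converged": e.converged,
                         "od": tr(e.od_test), "zi": tr(e.zi_test),
                         "sa": tr(e.sa_test), "selected": e.selected}
                        for e in self.entries],
        }


def _default_barrier(panel: CountPanel) -> np.ndarray:
    """A synthetic north-south barrier polyline through the panel's extent,
    standing in for a coastline when none is supplied."""
    lon0 = float(np.quantile(panel.sites["lon"], 0.3))
    lat = panel.sites["lat"]
    return np.array([[lon0, lat.min() - 1.0], [lon0, lat.max() + 1.0]])


def select_distribution(panel: CountPanel, family_order=FAMILY_ORDER,
                        controls: GlmmControls | None = None, seed: int = 0,
                        n_sims: int = 250, alpha: float = 0.05,
                        rank_by: str = "statistic") -> tuple[FitResult, SelectionTrace]:
    """Sequentially select the count distribution (no spatial structure).

    ``rank_by`` controls the fallback ranking: ``"statistic"`` (distance of
    the dispersion/zero-inflation ratio statistics from 1, lexicographic) or
    ``"p_value"`` (largest p first).
    """
    trace = SelectionTrace(stage="distribution")
    fits: dict[str, FitResult] = {}
    results: dict[str, tuple[TestResult, TestResult]] = {}
    chosen = None
    for k, fid in enumerate(family_order):
        fit = fit_glmm(panel, FamilySpec(fid), SpatialSpec("none"), controls)
        entry = TraceEntry(candidate_id=fid, converged=fit.converged)
        trace.entries.append(entry)
        if not fit.converged:
            log.info("select_distribution: %s did not converge; skipped", fid)
            continue
        od, zi = od_zi_tests(fit, panel, n_sims=n_sims, seed=seed + 1000 * k, alpha=alpha)
        entry.od_test, entry.zi_test = od, zi
        fits[fid] = fit
        results[fid] = (od, zi)
        if not od.significant and not zi.significant:
            entry.selected = True
            chosen = fid
            break
    if chosen is None:
        if not fits:
            raise RuntimeError("no candidate distribution converged")
        if len(fits) == 1:
            chosen = next(iter(fits))
            trace.selection_rule = "min_value_fallback"
        else:
            def key(fid):
                od, zi = results[fid]
                if rank_by == "p_value":
                    return (-od.p_value, -zi.p_value)
                return (abs(od.statistic - 1.0), abs(zi.statistic - 1.0))
            order = [f for f in family_order if f in fits]
            chosen = min(order, key=key)  # stable: ties keep priority order
            trace.selection_rule = "min_value_fallback"
        for e in trace.entries:
            e.selected = e.candidate_id == chosen
    return fits[chosen], trace


def select_spatial(panel: CountPanel, family: FamilySpec,
                   structure_order=DEFAULT_STRUCTURE_ORDER,
                   controls: GlmmControls | None = None, seed: int = 0,
                   n_sims: int = 250, alpha: float = 0.05,
                   barrier: np.ndarray | None = None,
                   include_barrier: bool = True) -> tuple[FitResult, SelectionTrace]:
    """Sequentially select the spatial structure for a fixed family."""
    trace = SelectionTrace(stage="spatial")
    candidates = [SpatialSpec("none")] + list(structure_order)
    if include_barrier:
        b = barrier if barrier is not None else _default_barrier(panel)
        candidates += [SpatialSpec("grf_barrier", mesh_cutoff_deg=c, barrier=b) for c in (0.5, 1.0)]
    fits: dict[str, FitResult] = {}
    moran: dict[str, TestResult] = {}
    chosen = None
    for k, spec in enumerate(candidates):
        fit = fit_glmm(panel, family, spec, controls)
        entry = TraceEntry(candidate_id=spec.label, converged=fit.converged)
        trace.entries.append(entry)
        if not fit.converged:
            log.info("select_spatial: %s did not converge; skipped", spec.label)
            continue
        vals = glmm_moran_values(fit, panel, n_sims=min(n_sims, 100), seed=seed + 99 * k)
        try:
            sa = morans_i_test(vals, panel.coords(), alpha=alpha)
        except ValueError:
            sa = TestResult("morans_i", 0.0, 1.0, alpha)
        entry.sa_test = sa
        fits[spec.label] = fit
        moran[spec.label] = sa
        if not sa.significant:
            entry.selected = True
            chosen = spec.label
            break
    if chosen is None:
        if not fits:
            raise RuntimeError("no spatial structure converged")
        labels = [s.label for s in candidates if s.label in fits]
        chosen = min(labels, key=lambda L: abs(moran[L].statistic))
        trace.selection_rule = "min_value_fallback"
        for e in trace.entries:
            e.selected = e.candidate_id == chosen
    return fits[chosen], trace


def optimized_glmm(panel: CountPanel, controls: GlmmControls | None = None,
                   seed: int = 0, n_sims: int = 250, alpha: float = 0.05,
                   family_order=FAMILY_ORDER, structure_order=DEFAULT_STRUCTURE_ORDER,
                   barrier: np.ndarray | None = None, include_barrier: bool = True,
                   ) -> tuple[FitResult, SelectionTrace, SelectionTrace]:
    """Two-stage optimized GLMM: distribution, then spatial structure.

    The final fit is re-diagnosed (dispersion, zero inflation, Moran's I) by
    the caller as needed, since adding a spatial structure can reintroduce
    either issue.
    """
    fam_fit, fam_trace = select_distribution(panel, family_order, controls, seed,
                                             n_sims=n_sims, alpha=alpha)
    final, sp_trace = select_spatial(panel, fam_fit.family, structure_order, controls,
                                     seed=seed + 7, n_sims=n_sims, alpha=alpha,
                                     barrier=barrier, include_barrier=include_barrier)
    return final, fam_trace, sp_trace
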