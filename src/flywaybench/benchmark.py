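"""End-to-end benchmark orchestration and reusable fixtures.

A run is: generate (or load) a panel -> minimum-survey filter -> apply each
sampling design -> fit each method -> diagnose -> index -> trend -> write a
tidy report.  Everything is driven by a flat YAML config and explicit seeds,
so identical configs give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .designs import DESIGN_IDS, DesignSpec, filter_min_surveys
from .indices import compare_methods
from .panel import CountPanel, read_panel_csv, summarize_panel, write_panel_csv
from .simulate import DEFAULT_YEARS, apply_missingness, generate_counts, generate_sites

__all__ = ["RunConfig", "run_benchmark", "make_fixture", "FIXTURES"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    # generator (used unless counts_csv is given)
    n_sites: int = 60
    n_years: int = 26
    beta0: float = float(np.log(5.0))
    beta_year: float = 0.02
    site_sd: float = 0.8
    spatial_sd: float = 0.0
    spatial_range: float = 5.0
    family_id: str = "nb2"
    dispersion: float = 0.5
    zi_prob: float = 0.0
    mcar_rate: float = 0.15
    counts_csv: str | None = None
    sites_csv: str | None = None
    # pipeline
    designs: list = field(default_factory=lambda: ["raw"])
    methods: list = field(default_factory=lambda: ["simple_glmm"])
    min_surveys: int = 15
    seed: int = 1
    alpha: float = 0.05
    n_sims: int = 100
    m_imputations: int = 30
    out_dir: str = "benchmark_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if not set(self.designs) <= set(DESIGN_IDS):
            raise ValueError(f"designs must be within {DESIGN_IDS}")
        for p in (self.counts_csv, self.sites_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _load_or_generate(config: RunConfig) -> CountPanel:
    if config.counts_csv:
        panel = read_panel_csv(config.counts_csv, config.sites_csv)
        log.info("loaded panel: %d sites x %d years", panel.n_sites, panel.n_years)
        return panel
    sites = generate_sites(config.n_sites, seed=config.seed)
    years = DEFAULT_YEARS[: config.n_years]
    panel, dropped = generate_counts(
        sites, years, beta0=config.beta0, beta_year=config.beta_year,
        site_sd=config.site_sd, spatial_sd=config.spatial_sd,
        spatial_range=config.spatial_range, family_id=config.family_id,
        dispersion=config.dispersion, zi_prob=config.zi_prob, seed=config.seed + 1)
    log.info("generated panel: %d sites (%d dropped by zero rule)", panel.n_sites, dropped)
    if config.mcar_rate > 0:
        panel = apply_missingness(panel, config.mcar_rate, seed=config.seed + 2)
    return panel


def run_benchmark(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("flywaybench")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        panel = _load_or_generate(config)
        panel = filter_min_surveys(panel, min_surveys=min(config.min_surveys, panel.n_years))
        write_panel_csv(panel, out / "panel_counts.csv", out / "panel_sites.csv")
        summary = summarize_panel(panel)
        (out / "panel_summary.json").write_text(json.dumps(asdict(summary), indent=2))

        specs = [DesignSpec(design_id=d, seed=config.seed + 10) for d in config.designs]
        report = compare_methods(panel, specs, config.methods, seed=config.seed + 20,
                                 n_sims=config.n_sims, m_imputations=config.m_imputations,
                                 alpha=config.alpha)
        frame = report.to_index_frame()
        frame.to_csv(out / "report_index.csv", index=False, float_format="%.6f")
        (out / "report_summary.json").write_text(
            json.dumps(report.summary(), indent=2, default=float))
        log.info("benchmark complete: %d design x method cells", len(report.rows))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _tiny_worked() -> CountPanel:
    """3 sites x 4 years with one missing cell; summaries are hand-checkable."""
    sites = generate_sites(3, extent=((0.0, 1.0), (0.0, 1.0)), seed=11)
    counts = np.array([
        [0.0, 2.0, 1.0, 3.0],
        [4.0, np.nan, 2.0, 0.0],
        [1.0, 1.0, 0.0, 5.0],
    ])
    return CountPanel(sites=sites, years=np.arange(2001, 2005), counts=counts)


def _poisson_flat(seed: int = 5) -> CountPanel:
    sites = generate_sites(50, seed=seed)
    panel, _ = generate_counts(sites, beta0=np.log(8.0), beta_year=0.0,
                               site_sd=0.5, family_id="poisson", seed=seed + 1)
    return apply_missingness(panel, 0.10, seed=seed + 2)


def _nb2_trend(seed: int = 6) -> CountPanel:
    sites = generate_sites(60, seed=seed)
    panel, _ = generate_counts(sites, beta0=np.log(20.0), beta_year=0.03,
                               site_sd=0.8, family_id="nb2", dispersion=0.4,
                               seed=seed + 1)
    return apply_missingness(panel, 0.15, seed=seed + 2)


def _zi_spatial(seed: int = 7) -> CountPanel:
    sites = generate_sites(60, seed=seed)
    panel, _ = generate_counts(sites, beta0=np.log(10.0), beta_year=0.0,
                               site_sd=0.4, spatial_sd=1.0, spatial_range=8.0,
                               family_id="poisson", zi_prob=0.3, seed=seed + 1)
    return apply_missingness(panel, 0.10, seed=seed + 2)


FIXTURES = {
    "tiny_worked": _tiny_worked,
    "poisson_flat": _poisson_flat,
    "nb2_trend": _nb2_trend,
    "zi_spatial": _zi_spatial,
}


def make_fixture(name: str, out_dir: str | Path = ".") -> CountPanel:
    """Build a registered fixture panel and write its CSVs + truth JSON."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    panel = FIXTURES[name]()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel_csv(panel, out / f"{name}_counts.csv", out / f"{name}_sites.csv")
    if panel.truth is not None:
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in asdict(panel.truth).items()}
        (out / f"{name}_truth.json").write_text(json.dumps(truth, indent=2))
    return panel
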