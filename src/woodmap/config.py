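"""Run configuration for the pipeline CLI.

A single YAML file configures every stage; each analysis constant
(20-certificate suppression threshold, 7pm–1am peak window, JJA/DJF
seasons, B = 10,000 bootstrap replications, 5th/95th percentile map
truncation) surfaces as a key with its standard value as the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or missing configuration keys."""


@dataclass
class RunConfig:
    # paths (inputs default to the simulate stage's outputs under workdir)
    workdir: str = "woodmap_run"
    epc_path: str = "epc.csv"
    lookup_path: str = "uprn_lookup.csv"
    boundaries_path: str = "lsoas.geojson"
    census_stock_path: str = "census_stock.csv"
    covariates_path: str = "covariates.csv"
    hierarchy_path: str = "hierarchy.csv"
    sites_path: str = "sites.csv"
    pm25_path: str = "pm25.csv"
    keyword_ruleset_path: str | None = None
    # study window
    study_start: str = "2009-01-01"
    study_end: str = "2025-02-28"
    exclude_years: list = field(default_factory=list)  # e.g. COVID years for PM2.5
    # estimation
    min_epc: int = 20
    flag: str = "wood_fuel"
    suppressed_strategy: str = "exclude"
    truncate_lower_pct: float = 5.0
    truncate_upper_pct: float = 95.0
    crs: str = "EPSG:27700"  # metadata; all coordinates are planar metres
    # validation
    buffer_radii_m: list = field(default_factory=lambda: [500.0, 1000.0, 2000.0])
    peak_hours: list = field(default_factory=lambda: [19, 20, 21, 22, 23, 0])
    offpeak_hours: list = field(default_factory=lambda: list(range(5, 17)))
    min_valid_hours: int = 24
    bootstrap_B: int = 10_000
    alpha: float = 0.05
    paired_season_bootstrap: bool = True
    # regression
    reference_region: str | None = None
    # randomness
    seed: int = 0
    # synthetic-scenario overrides for the simulate stage (ScenarioConfig keys)
    scenario: dict = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if any(r <= 0 for r in self.buffer_radii_m):
            problems.append("buffer_radii_m must be positive")
        if set(self.peak_hours) & set(self.offpeak_hours):
            problems.append("peak_hours and offpeak_hours must be disjoint")
        if self.bootstrap_B < 100:
            problems.append("bootstrap_B must be at least 100")
        if self.min_epc < 1:
            problems.append("min_epc must be at least 1")
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        if self.suppressed_strategy not in ("exclude", "borrow"):
            problems.append("suppressed_strategy must be 'exclude' or 'borrow'")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def resolve(self, name: str) -> Path:
        """Input paths are relative to the working directory unless absolute."""
        p = Path(getattr(self, name))
        return p if p.is_absolute() else Path(self.workdir) / p
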