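"""YAML/JSON run configuration, validation, and run reporting.

A configuration file drives the command-line entry points.  Every key has
a default matching the applied-example choices (λ = 0.056 with sd 0.01,
Gamma(2, 0.5) incidence, birth rate 27.5/1000, p0 = p1 = 1, β and s grids,
10 000 replications), so an empty file is a valid configuration and a bare
run on synthetic data mirrors the reference setup.  β and s may be scalars
(single run) or lists (full results grid).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ambusim.delay import DelayParams, SpeedParams
from ambusim.epidemiology import IncidenceParams
from ambusim.estimator import ModelParams
from ambusim.scenarios import ScenarioSpec
from ambusim.survival import SurvivalParams
from ambusim.synthetic import SyntheticSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unknown keys or constraint violations in a config file."""


_SCHEMA: dict[str, dict[str, object]] = {
    "paths": {"density": None, "friction": None, "travel_time": None,
              "facilities": None, "output_dir": "results"},
    "delay": {"beta": [60.0, 120.0, 180.0, 240.0, 300.0]},
    "speed": {"s": [0.6, 0.7, 0.8, 0.9]},
    "survival": {"lambda_mean": 0.056, "lambda_sd": 0.01},
    "incidence": {"gamma_shape": 2.0, "gamma_scale": 0.5, "birth_rate_per_1000": 27.5},
    "careseeking": {"p0": 1.0, "p1": 1.0},
    "scenario": {"choice_rule": "fastest", "random_weight": 0.5, "callout_delay": 0.0},
    "monte_carlo": {"n_reps": 10000, "seed": 1},
    "travel": {"connectivity": 8, "edge_cost": "mean"},
    "synth": {"shape": [50, 50], "cell_km": 1.0, "n_towns": 6,
              "town_peak_density": 2000.0, "background_density": 5.0,
              "town_sd_km": 3.0, "n_roads": 8,
              "road_friction_min_per_m": 0.0012,
              "offroad_friction_min_per_m": 0.03,
              "n_facilities": 2, "seed": 0},
    "tau_mode": "sample",
    "cell_area_km2": None,
}


@dataclass
class RunConfig:
    """Fully resolved configuration; see module docstring for defaults."""

    raw: dict

    def __getitem__(self, key: str):
        return self.raw[key]

    # -- typed views --------------------------------------------------------

    @property
    def betas(self) -> list[float]:
        b = self.raw["delay"]["beta"]
        return [float(x) for x in (b if isinstance(b, (list, tuple)) else [b])]

    @property
    def speeds(self) -> list[float]:
        s = self.raw["speed"]["s"]
        return [float(x) for x in (s if isinstance(s, (list, tuple)) else [s])]

    @property
    def is_grid(self) -> bool:
        """Lists for β or s request the full results grid."""
        return isinstance(self.raw["delay"]["beta"], (list, tuple)) or \
            isinstance(self.raw["speed"]["s"], (list, tuple))

    def model_params(self, beta: float | None = None,
                     s: float | None = None) -> ModelParams:
        r = self.raw
        return ModelParams(
            delay=DelayParams(beta=self.betas[0] if beta is None else beta),
            speed=SpeedParams(s=self.speeds[0] if s is None else s),
            survival=SurvivalParams(**r["survival"]),
            incidence=IncidenceParams(**r["incidence"],
                                      p0=r["careseeking"]["p0"],
                                      p1=r["careseeking"]["p1"]),
            tau_mode=r["tau_mode"],
        )

    def scenario(self) -> ScenarioSpec:
        return ScenarioSpec(**self.raw["scenario"])

    def synth_spec(self) -> SyntheticSpec:
        d = dict(self.raw["synth"])
        d["shape"] = tuple(d["shape"])
        return SyntheticSpec(**d)

    def validate_paths(self) -> None:
        """Simulation-time path constraints: exactly one travel-time source."""
        p = self.raw["paths"]
        has_friction = p["friction"] is not None
        has_tt = p["travel_time"] is not None
        if has_friction == has_tt:
            raise ConfigError("exactly one of paths.friction (+ paths.facilities) "
                              "or paths.travel_time must be provided")
        if has_friction and p["facilities"] is None:
            raise ConfigError("paths.facilities is required with paths.friction")
        if p["density"] is None:
            raise ConfigError("paths.density is required")
        for key in ("density", "friction", "travel_time", "facilities"):
            if p[key] is not None and not Path(p[key]).exists():
                raise ConfigError(f"paths.{key}: file not found: {p[key]}")


def _merge(defaults, given, crumb: str):
    if given is None:
        return json.loads(json.dumps(defaults))  # deep copy
    if isinstance(defaults, dict):
        if not isinstance(given, dict):
            raise ConfigError(f"{crumb}: expected a mapping")
        unknown = sorted(set(given) - set(defaults))
        if unknown:
            raise ConfigError(f"unknown config keys under {crumb or 'top level'}: {unknown}")
        return {k: _merge(defaults[k], given.get(k), f"{crumb}.{k}" if crumb else k)
                for k in defaults}
    return given


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config, filling in all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    raw = _merge(_SCHEMA, data, "")
    cfg = RunConfig(raw=raw)
    if raw["monte_carlo"]["n_reps"] < 1:
        raise ConfigError("monte_carlo.n_reps must be at least 1")
    # construct typed views eagerly so bad values fail at load time
    cfg.model_params()
    cfg.scenario()
    return cfg


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def report(results_dir) -> str:
    """Render a Markdown summary of a ``simulate`` output directory.

    Includes the results grid and references to the map files; missing maps
    produce a warning but the summary is still written (to ``report.md``).
    Byte-reproducible given fixed inputs (no timestamps).
    """
    import pandas as pd

    results_dir = Path(results_dir)
    grid_path = results_dir / "results_grid.csv"
    if not grid_path.exists():
        raise FileNotFoundError(f"missing {grid_path}; run simulate first")
    grid = pd.read_csv(grid_path)

    lines = ["# Simulation report", "",
             "## Mean lives saved per year (95% CrI)", ""]
    lines.append("| s | beta | mean | 2.5% | 97.5% |")
    lines.append("|---|------|------|------|-------|")
    for _, row in grid.iterrows():
        lines.append(f"| {row['s']:g} | {row['beta']:g} | {row['mean']:.2f} "
                     f"| {row['cri_low']:.2f} | {row['cri_high']:.2f} |")
    lines += ["", "## Maps", ""]
    any_map = False
    for _, row in grid.iterrows():
        stem = f"lives_saved_mean_{row['beta']:g}_{row['s']:g}"
        tif = results_dir / f"{stem}.tif"
        if tif.exists():
            lines.append(f"- `{tif.name}`")
            any_map = True
        else:
            logger.warning("missing map file %s", tif)
    if not any_map:
        lines.append("- (no map files found)")
    log_path = results_dir / "run_log.json"
    if log_path.exists():
        log = json.loads(log_path.read_text())
        lines += ["", "## Run metadata", "",
                  f"- seed: {log.get('seed')}",
                  f"- n_reps: {log.get('n_reps')}",
                  f"- package version: {log.get('version')}"]
    text = "\n".join(lines) + "\n"
    (results_dir / "report.md").write_text(text)
    return text
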