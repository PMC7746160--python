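"""End-to-end spacing optimization: config handling, orchestration, trace I/O.

Couples the MPSO optimizer to the canopy simulator: the objective of a
spacing candidate is the areal grain yield of a freshly grown season at
that spacing (every evaluation restarts the stand from seedlings).  The
climate series is generated (or read) once per run and shared across all
evaluations; run-to-run variability comes from the optimizer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from .climate import (
    ClimateSeries,
    SeasonalProfile,
    generate_synthetic_climate,
    read_climate_table,
)
from .fitness import FitnessResult, evaluate_fitness
from .mpso import MPSOConfig, OptimizeResult, optimize
from .ricecanopy import CultivarParams, simulate_season
from .trace import OptimizationTrace, TraceRow

__all__ = [
    "ConfigError",
    "ClimateConfig",
    "LatticeConfig",
    "RunConfig",
    "default_config",
    "fast_config",
    "load_config",
    "make_objective",
    "SpacingOptimizationResult",
    "run_spacing_optimization",
    "grid_scan",
    "export_trace",
    "read_trace",
]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration fields."""


@dataclass(frozen=True)
class ClimateConfig:
    """Where the driving climate comes from.

    ``source`` is either ``"synthetic"`` (seeded generator) or a path to a
    climate table.  ``n_days`` is the season length in days; the growing
    season is not prescribed by the optimization itself, so it is exposed
    here (default 120 d, a typical transplant-to-harvest rice season).
    """

    source: str = "synthetic"
    n_days: int = 120
    seed: int = 42
    profile: SeasonalProfile = field(default_factory=SeasonalProfile)

    def load(self) -> ClimateSeries:
        if self.source == "synthetic":
            return generate_synthetic_climate(self.n_days, self.seed, self.profile)
        return read_climate_table(self.source)


@dataclass(frozen=True)
class LatticeConfig:
    """Stand geometry: a rows x cols lattice scored on its inner plants."""

    rows: int = 6
    cols: int = 6
    grid_resolution: float = 2.0  # cm, ground-cell size of the light grid
    init_jitter: float = 0.05  # relative jitter of initial plant biomass

    def __post_init__(self) -> None:
        if self.rows < 3 or self.cols < 3:
            raise ConfigError("lattice.rows and lattice.cols must each be >= 3")
        if self.grid_resolution <= 0:
            raise ConfigError("lattice.grid_resolution must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a spacing-optimization run."""

    climate: ClimateConfig = field(default_factory=ClimateConfig)
    cultivar: CultivarParams = field(default_factory=CultivarParams)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    mpso: MPSOConfig = field(default_factory=MPSOConfig)

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    """Full-scale defaults: 6x6 stand, 20 particles, 300 iterations."""
    return RunConfig()


def fast_config(seed: int = 0) -> RunConfig:
    """Reduced profile for quick runs: 5x5 stand (3x3 inner), 10 particles,
    50 iterations, switching-point range scaled accordingly."""
    return RunConfig(
        lattice=LatticeConfig(rows=5, cols=5),
        mpso=MPSOConfig(
            n_particles=10,
            t_max=50,
            t_switch_range=(13, 38),
            seed=seed,
        ),
    )


def _build_section(cls, section: str, data: dict[str, Any]):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ConfigError(
            f"unknown field(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config with sections climate/cultivar/lattice/mpso.

    Every field is optional and defaults to the package default; unknown
    sections or fields raise a :class:`ConfigError` naming them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    known = {"climate", "cultivar", "lattice", "mpso"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    climate_raw = dict(raw.get("climate", {}))
    if "profile" in climate_raw:
        climate_raw["profile"] = _build_section(
            SeasonalProfile, "climate.profile", dict(climate_raw["profile"])
        )
    mpso_raw = dict(raw.get("mpso", {}))
    for key in ("t_switch_range", "bounds", "init_bounds"):
        if key in mpso_raw and mpso_raw[key] is not None:
            mpso_raw[key] = tuple(mpso_raw[key])
    return RunConfig(
        climate=_build_section(ClimateConfig, "climate", climate_raw),
        cultivar=_build_section(CultivarParams, "cultivar", dict(raw.get("cultivar", {}))),
        lattice=_build_section(LatticeConfig, "lattice", dict(raw.get("lattice", {}))),
        mpso=_build_section(MPSOConfig, "mpso", mpso_raw),
    )


def make_objective(
    config: RunConfig, climate: ClimateSeries | None = None
) -> Callable[[float], float]:
    """Objective closure: spacing -> areal grain yield of a fresh season.

    Accepts a ``seed`` keyword so the optimizer can make stochastic
    evaluations repeatable.
    """
    series = climate if climate is not None else config.climate.load()

    def objective(spacing: float, seed: int = 0) -> float:
        canopy = simulate_season(
            spacing,
            series,
            config.cultivar,
            rows=config.lattice.rows,
            cols=config.lattice.cols,
            seed=seed,
            grid_resolution=config.lattice.grid_resolution,
            init_jitter=config.lattice.init_jitter,
        )
        return evaluate_fitness(canopy).fitness

    return objective


@dataclass(frozen=True)
class SpacingOptimizationResult:
    best_spacing: float  # cm
    fitness: FitnessResult  # re-simulated at the best spacing
    trace: OptimizationTrace
    t_switch: int


def run_spacing_optimization(
    config: RunConfig, seed: int | None = None
) -> SpacingOptimizationResult:
    """Run the full optimization loop and return best spacing, its fitness
    (from a re-simulated season at that spacing), and the iteration trace.

    ``seed`` overrides ``config.mpso.seed`` when given.  Identical config
    and seed reproduce the result and trace exactly.
    """
    mpso_cfg = (
        dataclasses.replace(config.mpso, seed=seed) if seed is not None else config.mpso
    )
    series = config.climate.load()
    objective = make_objective(config, series)
    result: OptimizeResult = optimize(objective, mpso_cfg)

    canopy = simulate_season(
        result.best_x,
        series,
        config.cultivar,
        rows=config.lattice.rows,
        cols=config.lattice.cols,
        seed=mpso_cfg.seed,
        grid_resolution=config.lattice.grid_resolution,
        init_jitter=config.lattice.init_jitter,
    )
    fit = evaluate_fitness(canopy)
    trace = result.trace
    trace.metadata.update(
        {
            "seed": mpso_cfg.seed,
            "t_switch": result.t_switch,
            "config_digest": config.digest(),
            "best_spacing_cm": result.best_x,
            "best_fitness": result.best_f,
        }
    )
    return SpacingOptimizationResult(
        best_spacing=result.best_x, fitness=fit, trace=trace, t_switch=result.t_switch
    )


def grid_scan(
    config: RunConfig,
    s_min: float = 5.0,
    s_max: float = 50.0,
    step: float = 0.5,
    seed: int = 0,
    climate: ClimateSeries | None = None,
) -> pd.DataFrame:
    """Brute-force fitness scan over a spacing grid (the optimizer's oracle).

    Every grid point is evaluated with the same simulation seed so the scan
    is a deterministic function of the config.
    """
    if step <= 0 or s_min >= s_max:
        raise ValueError("need step > 0 and s_min < s_max")
    objective = make_objective(config, climate)
    spacings = np.arange(s_min, s_max + step / 2, step)
    values = [objective(float(s), seed=seed) for s in spacings]
    return pd.DataFrame({"spacing_cm": spacings, "fitness": values})


def export_trace(trace: OptimizationTrace, path: str | Path) -> tuple[Path, Path]:
    """Write a trace as CSV plus a JSON metadata sidecar.

    Returns the two paths written; ``read_trace`` on the CSV path
    reproduces the trace exactly.
    """
    if len(trace) == 0:
        raise ValueError("cannot export an empty trace")
    csv_path = Path(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w") as fh:  # repr precision => exact round-trip
        fh.write("iteration,gbest_spacing_cm,gbest_fitness,event\n")
        for r in trace.rows:
            fh.write(f"{r.iteration},{r.gbest_x!r},{r.gbest_f!r},{r.event}\n")
    meta_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(trace.metadata, fh, indent=2, sort_keys=True, default=float)
    return csv_path, meta_path


def read_trace(path: str | Path) -> OptimizationTrace:
    """Read back a trace written by :func:`export_trace`."""
    csv_path = Path(path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    rows = [
        TraceRow(
            iteration=int(r.iteration),
            gbest_x=float(r.gbest_spacing_cm),
            gbest_f=float(r.gbest_fitness),
            event=str(r.event),
        )
        for r in df.itertuples()
    ]
    meta_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    metadata: dict[str, Any] = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return OptimizationTrace(rows=rows, metadata=metadata)
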