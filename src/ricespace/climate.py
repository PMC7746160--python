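"""Daily climate series driving the canopy simulator.

The simulator consumes one record per day of the growing season: the daily
integral of photosynthetically active radiation (PAR, mol photons m^-2 d^-1),
mean air temperature (deg C) and day length (h).  Real seasons can be read
from a delimited table; for self-contained work a seeded synthetic generator
produces a subtropical lowland season (a mid-season radiation and temperature
peak with multiplicative/additive noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateRecord",
    "ClimateSeries",
    "SeasonalProfile",
    "ClimateFormatError",
    "generate_synthetic_climate",
    "read_climate_table",
    "write_climate_table",
]

#: column names of the on-disk climate table
CLIMATE_COLUMNS = ("day", "par", "temp", "daylen")


class ClimateFormatError(ValueError):
    """Raised when a climate table violates the expected format."""


@dataclass(frozen=True)
class ClimateRecord:
    """One day of weather.

    Parameters
    ----------
    day_index : int
        1-based day of the season.
    par_daily : float
        Daily incident PAR integral, mol photons m^-2 ground d^-1.
    temp_mean : float
        Daily mean air temperature, deg C.
    day_length : float
        Photoperiod, hours (0 < day_length <= 24).
    """

    day_index: int
    par_daily: float
    temp_mean: float
    day_length: float

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        if self.par_daily < 0:
            raise ValueError(f"par_daily must be >= 0, got {self.par_daily}")
        if not 0 < self.day_length <= 24:
            raise ValueError(
                f"day_length must lie in (0, 24], got {self.day_length}"
            )


@dataclass(frozen=True)
class ClimateSeries:
    """An ordered, contiguous run of daily records starting at day 1."""

    records: tuple[ClimateRecord, ...]
    site_label: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("ClimateSeries must contain at least one record")
        days = [r.day_index for r in self.records]
        if days != list(range(1, len(days) + 1)):
            raise ValueError(
                "day_index must be contiguous starting at 1, got "
                f"{days[:5]}{'...' if len(days) > 5 else ''}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ClimateRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ClimateRecord:
        return self.records[i]

    @property
    def par_daily(self) -> np.ndarray:
        return np.array([r.par_daily for r in self.records])

    @property
    def temp_mean(self) -> np.ndarray:
        return np.array([r.temp_mean for r in self.records])

    @property
    def day_length(self) -> np.ndarray:
        return np.array([r.day_length for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [r.day_index for r in self.records],
                "par": [r.par_daily for r in self.records],
                "temp": [r.temp_mean for r in self.records],
                "daylen": [r.day_length for r in self.records],
            }
        )

    @classmethod
    def from_arrays(
        cls,
        par: Sequence[float],
        temp: Sequence[float],
        daylen: Sequence[float],
        site_label: str = "synthetic",
    ) -> "ClimateSeries":
        records = tuple(
            ClimateRecord(i + 1, float(p), float(t), float(d))
            for i, (p, t, d) in enumerate(zip(par, temp, daylen))
        )
        return cls(records=records, site_label=site_label)


@dataclass(frozen=True)
class SeasonalProfile:
    """Envelope parameters of the synthetic season.

    PAR and temperature follow one full cosine cycle over the season
    (minimum at the season edges, maximum mid-season), so the envelope mean
    over the season equals the configured mean exactly.  Day length sweeps
    the configured range on the same cycle without noise.
    """

    par_mean: float = 35.0  # mol m^-2 d^-1
    par_amplitude: float = 10.0
    par_noise_sigma: float = 0.15  # lognormal sigma, multiplicative, mean-one
    temp_mean: float = 25.0  # deg C
    temp_amplitude: float = 5.0
    temp_noise_sigma: float = 1.5  # additive normal, deg C
    day_length_min: float = 11.0  # h
    day_length_max: float = 14.0
    temp_clip: tuple[float, float] = (-10.0, 50.0)

    def __post_init__(self) -> None:
        if self.par_mean < 0 or self.par_amplitude < 0:
            raise ValueError("PAR envelope parameters must be non-negative")
        if not 0 < self.day_length_min <= self.day_length_max <= 24:
            raise ValueError("day length range must satisfy 0 < min <= max <= 24")

    def envelope(self, n_days: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Noise-free (par, temp, daylen) envelopes for an ``n_days`` season."""
        d = np.arange(1, n_days + 1)
        # -cos over one full cycle: trough at the edges, peak mid-season,
        # discrete mean exactly zero
        shape = -np.cos(2.0 * np.pi * (d - 0.5) / n_days)
        par = self.par_mean + self.par_amplitude * shape
        temp = self.temp_mean + self.temp_amplitude * shape
        mid = 0.5 * (self.day_length_min + self.day_length_max)
        half = 0.5 * (self.day_length_max - self.day_length_min)
        daylen = mid + half * shape
        return par, temp, daylen


def generate_synthetic_climate(
    n_days: int,
    seed: int,
    profile: SeasonalProfile | None = None,
) -> ClimateSeries:
    """Generate a seeded synthetic season of daily climate records.

    Noise is lognormal multiplicative (mean one) on PAR and additive normal
    on temperature; both are clipped so every record satisfies its
    invariants.  Identical ``(n_days, seed, profile)`` give an identical
    series.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    prof = profile if profile is not None else SeasonalProfile()
    rng = np.random.default_rng(seed)
    par_env, temp_env, daylen = prof.envelope(n_days)
    # mean-one lognormal: exp(N(-sigma^2/2, sigma^2))
    s = prof.par_noise_sigma
    par = par_env * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n_days)
    par = np.clip(par, 0.0, None)
    temp = temp_env + rng.normal(0.0, prof.temp_noise_sigma, size=n_days)
    temp = np.clip(temp, *prof.temp_clip)
    return ClimateSeries.from_arrays(par, temp, daylen, site_label=f"synthetic-seed{seed}")


def write_climate_table(series: ClimateSeries, path: str | Path) -> None:
    """Write a series as a comma-separated table with header day,par,temp,daylen.

    Floats are written with full (repr) precision so a write-then-read
    round-trip reproduces the series exactly.
    """
    with open(path, "w") as fh:
        fh.write("day,par,temp,daylen\n")
        for r in series:
            fh.write(f"{r.day_index},{r.par_daily!r},{r.temp_mean!r},{r.day_length!r}\n")


def read_climate_table(path: str | Path) -> ClimateSeries:
    """Read and validate a climate table.

    Expects comma-separated text with header columns ``day,par,temp,daylen``.
    An optional ``hour`` column marks sub-daily data, which is aggregated to
    daily resolution on read (PAR summed, temperature averaged, day length
    taken from the first row of each day).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ClimateFormatError(f"{path}: file is empty") from None
    if df.empty:
        raise ClimateFormatError(f"{path}: table has no data rows")
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ClimateFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in CLIMATE_COLUMNS + (("hour",) if "hour" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ClimateFormatError(
                f"{path}: non-numeric or missing value in column '{col}', line {row}"
            )
        df[col] = coerced

    if "hour" in df.columns:
        grouped = df.groupby("day", sort=True)
        df = pd.DataFrame(
            {
                "day": list(grouped.groups),
                "par": grouped["par"].sum().to_numpy(),
                "temp": grouped["temp"].mean().to_numpy(),
                "daylen": grouped["daylen"].first().to_numpy(),
            }
        )

    days = df["day"].to_numpy()
    expected = np.arange(1, len(days) + 1)
    if not np.array_equal(days, expected):
        first_bad = int(np.argmax(days != expected))
        raise ClimateFormatError(
            f"{path}: day column must be contiguous from 1; "
            f"row {first_bad + 1} has day {days[first_bad]}, expected {expected[first_bad]}"
        )
    try:
        return ClimateSeries.from_arrays(
            df["par"].to_numpy(), df["temp"].to_numpy(), df["daylen"].to_numpy(),
            site_label=str(path.name),
        )
    except ValueError as exc:
        raise ClimateFormatError(f"{path}: {exc}") from exc
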