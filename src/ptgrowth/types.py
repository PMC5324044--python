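"""Shared containers: site metadata and the monthly forcing series.

A :class:`ForcingSeries` is the single input currency of the pipeline: an
aligned monthly climate table (temperature, diurnal range, precipitation,
vapour pressure, cloud fraction) plus an annual ambient-CO2 series for one
site.  Derived drivers (VPD, PAR, moisture index alpha, growing-season flag)
are filled in by :mod:`ptgrowth.prep` and live in the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: raw monthly climate variables every series must carry
RAW_COLUMNS = ["tmp", "dtr", "pre", "vap", "cld"]
#: derived driver columns added by forcing preparation
DERIVED_COLUMNS = ["vpd", "par", "alpha", "growing"]

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class SiteMeta:
    """Location of a site: latitude/longitude in decimal degrees, elevation in m a.s.l."""

    latitude: float
    longitude: float
    elevation: float
    name: str = "site"

    def __post_init__(self) -> None:
        if not np.isfinite([self.latitude, self.longitude, self.elevation]).all():
            raise ValueError("site coordinates must be finite")
        if abs(self.latitude) > 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -500 <= self.elevation <= 9000:
            raise ValueError(f"elevation {self.elevation} m implausible")


@dataclass
class ForcingSeries:
    """Monthly climate plus annual CO2 for one site.

    ``data`` is indexed by a (year, month) MultiIndex with one row per
    calendar month, gap free, months 1-12.  ``co2`` is indexed by year (ppm).
    """

    site: SiteMeta
    data: pd.DataFrame
    co2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        self.data = self.data.sort_index()
        validate_monthly_index(self.data)
        missing = [c for c in RAW_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"forcing table missing columns: {missing}")

    # -- convenience -----------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return self.data.index.get_level_values("year").unique().to_numpy()

    @property
    def n_years(self) -> int:
        return len(self.years)

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(self.site, self.data.copy(), self.co2.copy())

    def with_site(self, site: SiteMeta) -> "ForcingSeries":
        return ForcingSeries(site, self.data.copy(), self.co2.copy())

    def monthly_co2(self) -> pd.Series:
        """Ambient CO2 (ppm) broadcast from years to the monthly index."""
        if self.co2.empty:
            raise ValueError("no CO2 series attached to this forcing")
        yrs = self.data.index.get_level_values("year")
        missing = set(yrs.unique()) - set(self.co2.index)
        if missing:
            raise ValueError(f"CO2 series missing years: {sorted(missing)[:5]} ...")
        return pd.Series(self.co2.reindex(yrs).to_numpy(), index=self.data.index, name="ca_ppm")

    def climatology(self, columns: list[str] | None = None) -> pd.DataFrame:
        """Per-calendar-month means (12 rows) of the requested columns."""
        cols = columns or RAW_COLUMNS
        return self.data[cols].groupby(level="month").mean()


def monthly_index(first_year: int, n_years: int) -> pd.MultiIndex:
    years = np.repeat(np.arange(first_year, first_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    return pd.MultiIndex.from_arrays([years, months], names=["year", "month"])


def validate_monthly_index(data: pd.DataFrame) -> None:
    idx = data.index
    if list(idx.names) != ["year", "month"]:
        raise ValueError("forcing table must be indexed by (year, month)")
    if idx.duplicated().any():
        dups = idx[idx.duplicated()].tolist()
        raise ValueError(f"duplicate year-months: {dups[:5]}")
    years = idx.get_level_values("year").unique()
    expected = monthly_index(int(years.min()), len(years))
    missing = expected.difference(idx)
    if len(missing):
        raise ValueError(
            "gaps in monthly series: missing "
            + ", ".join(f"{y:04d}-{m:02d}" for y, m in missing[:6])
        )


__all__ = [
    "SiteMeta",
    "ForcingSeries",
    "monthly_index",
    "validate_monthly_index",
    "RAW_COLUMNS",
    "DERIVED_COLUMNS",
    "MONTH_DAYS",
]
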