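"""File formats: Tucson/RWL ring-width series, tabular climate and CO2 files,
and the structured run configuration.

Readers validate and reject malformed input rather than silently repairing
it; writers stamp every output with the seed and config hash that produced
it (as comment lines readers skip).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tmodel import RingSeries
from .types import ForcingSeries, SiteMeta

RWL_SCALE = {0.01: 999, 0.001: -9999}  # mm per unit -> end-of-series marker


# ----------------------------------------------------------------------
# Tucson / RWL
# ----------------------------------------------------------------------

def read_rwl(path) -> dict[str, RingSeries]:
    """Read a Tucson/RWL decadal file into per-series ring widths (mm).

    Accepts the common 0.01 mm dialect (terminator 999) and the 0.001 mm
    dialect (terminator -9999).  Malformed decade rows raise with the line
    number.
    """
    series: dict[str, dict[int, float]] = {}
    done: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        sid, rest = raw[:8].strip(), raw[8:].split()
        if not sid or not rest:
            raise ValueError(f"{path}:{lineno}: malformed decade row")
        try:
            year = int(rest[0])
            values = [int(v) for v in rest[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field in decade row") from exc
        if sid in done:
            raise ValueError(f"{path}:{lineno}: data after terminator for series {sid}")
        store = series.setdefault(sid, {})
        for i, v in enumerate(values):
            if v == 999:
                done.add(sid)
                scale = 0.01
                break
            if v == -9999:
                done.add(sid)
                scale = 0.001
                break
            store[year + i] = v
        else:
            continue
        # apply the dialect scale now that the terminator fixed it
        for y in store:
            store[y] = store[y] * scale
    out = {}
    for sid, widths in series.items():
        if sid not in done:
            raise ValueError(f"{path}: series {sid} has no terminator")
        s = pd.Series(widths, dtype=float).sort_index().rename_axis("year")
        out[sid] = RingSeries(s, meta={"series_id": sid, "source": str(path)})
    return out


def write_rwl(series: RingSeries, path, series_id: str = "SYN001",
              units_mm: float = 0.01, header: str | None = None) -> None:
    """Write one ring series in the Tucson decadal dialect.

    ``units_mm`` selects the 0.01 mm (terminator 999) or 0.001 mm
    (terminator -9999) encoding; widths not representable in the chosen
    units raise.
    """
    if units_mm not in RWL_SCALE:
        raise ValueError("units_mm must be 0.01 or 0.001")
    marker = RWL_SCALE[units_mm]
    widths = series.widths
    if (widths < 0).any():
        raise ValueError("ring widths must be non-negative")
    if widths.max() > 99.99:
        raise ValueError("widths above 99.99 mm are not representable in Tucson decadal rows")
    years = widths.index.to_numpy(int)
    if len(years) and np.any(np.diff(years) != 1):
        raise ValueError("ring series must cover consecutive years")
    lines = []
    if header:
        lines.append(f"# {header}")
    y = int(years[0])
    last = int(years[-1])
    while y <= last:
        decade_end = (y // 10) * 10 + 9
        row_years = range(y, min(decade_end, last) + 1)
        vals = [int(round(widths.loc[yy] / units_mm)) for yy in row_years]
        if row_years[-1] == last:
            vals.append(marker)
        lines.append(f"{series_id:<8}{y:>4}" + "".join(f"{v:>6}" for v in vals))
        y = decade_end + 1
    Path(path).write_text("\n".join(lines) + "\n")


def mean_ring_series(collection: dict[str, RingSeries]) -> RingSeries:
    """Site mean across series (per-year mean of the available series)."""
    frame = pd.DataFrame({sid: rs.widths for sid, rs in collection.items()})
    return RingSeries(frame.mean(axis=1).dropna(), meta={"n_series": len(collection)})


# ----------------------------------------------------------------------
# tabular climate and CO2
# ----------------------------------------------------------------------

CLIMATE_COLUMNS = ["year", "month", "tmp", "dtr", "pre", "vap", "cld"]

_PLAUSIBLE = {
    "tmp": (-60.0, 60.0), "dtr": (0.0, 40.0), "pre": (0.0, 3000.0),
    "vap": (0.0, 100.0), "cld": (0.0, 1.0),
}


def write_climate_table(series: ForcingSeries, path, provenance: dict | None = None) -> None:
    """Write the raw monthly variables as whitespace-delimited text."""
    frame = series.data[["tmp", "dtr", "pre", "vap", "cld"]].reset_index()
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance, series.site))
        frame.to_string(fh, index=False, float_format=lambda v: f"{v:.4f}")
        fh.write("\n")


def read_climate_table(path, site: SiteMeta | None = None) -> ForcingSeries:
    """Read a monthly climate table (columns: year month tmp dtr pre vap cld).

    Row order is irrelevant; gaps, duplicates and out-of-range values raise
    with the offending year-months named.
    """
    site_from_header = _site_from_header(path)
    frame = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in CLIMATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for var, (lo, hi) in _PLAUSIBLE.items():
        bad = frame[(frame[var] < lo) | (frame[var] > hi)]
        if len(bad):
            ym = [f"{int(r.year):04d}-{int(r.month):02d}" for r in bad.itertuples()][:5]
            raise ValueError(f"{path}: {var} outside plausible range at {ym}")
    data = frame.set_index(["year", "month"]).sort_index()
    return ForcingSeries(site or site_from_header or SiteMeta(0.0, 0.0, 0.0), data)


def write_co2_table(co2: pd.Series, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance, None))
        for year, ppm in co2.items():
            fh.write(f"{int(year):6d} {ppm:10.3f}\n")


def read_co2_table(path) -> pd.Series:
    frame = pd.read_csv(path, sep=r"\s+", comment="#", names=["year", "co2_ppm"])
    if frame["year"].duplicated().any():
        raise ValueError(f"{path}: duplicate years in CO2 table")
    s = frame.set_index("year")["co2_ppm"].sort_index()
    if (s <= 0).any():
        raise ValueError(f"{path}: non-positive CO2 values")
    return s


def _provenance_header(provenance: dict | None, site: SiteMeta | None) -> str:
    lines = []
    if site is not None:
        lines.append(
            f"# site lat={site.latitude} lon={site.longitude} elev={site.elevation} name={site.name}"
        )
    if provenance:
        tag = " ".join(f"{k}={v}" for k, v in provenance.items())
        lines.append(f"# {tag}")
    return ("\n".join(lines) + "\n") if lines else ""


def _site_from_header(path) -> SiteMeta | None:
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            if raw.startswith("# site "):
                kv = dict(tok.split("=", 1) for tok in raw[7:].split())
                return SiteMeta(float(kv["lat"]), float(kv["lon"]), float(kv["elev"]),
                                name=kv.get("name", "site"))
    return None


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

_KNOWN_KEYS = {
    "site", "seed", "output_dir", "forcing_file", "co2_file", "rings_file",
    "synthetic_climate", "anomaly", "species_params", "pmodel_constants",
    "abc", "experiments", "d0", "soil_capacity",
}


def load_config(path) -> dict:
    """Load the YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("forcing_file", "co2_file", "rings_file"):
        if key in cfg and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{path}: {key} -> {cfg[key]} does not exist")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for output provenance stamps."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


__all__ = [
    "read_rwl",
    "write_rwl",
    "mean_ring_series",
    "read_climate_table",
    "write_climate_table",
    "read_co2_table",
    "write_co2_table",
    "load_config",
    "config_hash",
    "CLIMATE_COLUMNS",
]
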