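"""Forcing preparation: derived photosynthesis drivers from raw monthly climate.

Turns a raw :class:`~ptgrowth.types.ForcingSeries` (temperature, diurnal
range, precipitation, vapour pressure, cloud) into the drivers the P model
consumes:

* vapour pressure deficit (Pa), via the Magnus saturation curve;
* monthly photosynthetically active radiation (mol photon m-2 month-1) from
  analytic solar geometry, modified by an Angstrom-type transmissivity that
  depends on sunshine fraction and elevation;
* atmospheric pressure from the standard-atmosphere barometric formula;
* a moisture index alpha = AET/EET from a monthly Priestley-Taylor bucket;
* the growing-season mask (monthly mean temperature strictly above -1 deg C);

plus the climatology corrections (elevation downscaling, glacial bias
correction) and the 24-month carbon-accumulation window that maps monthly
values onto ring years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MONTH_DAYS, ForcingSeries, SiteMeta

# ----------------------------------------------------------------------
# basic physics
# ----------------------------------------------------------------------

P0 = 101325.0  # Pa, standard sea-level pressure
SOLAR_CONSTANT = 1361.0  # W m-2
PAR_PHOTON_PER_J = 2.04e-6  # mol photon per J total shortwave (incl. ~50% PAR fraction)
LATENT_HEAT = 2.45e6  # J kg-1, vaporisation of water
PSYCHROMETRIC = 65.0  # Pa K-1
ALBEDO = 0.17
PT_COEFF = 1.26  # Priestley-Taylor coefficient; also the alpha cap
GROWING_THRESHOLD = -1.0  # deg C, strict ">"


def saturation_vapour_pressure(temp_c):
    """Saturation vapour pressure (Pa) over water, Magnus form."""
    t = np.asarray(temp_c, dtype=float)
    return 611.21 * np.exp(17.502 * t / (t + 240.97))


def svp_slope(temp_c):
    """d e_sat / dT (Pa K-1) of the Magnus curve."""
    t = np.asarray(temp_c, dtype=float)
    return saturation_vapour_pressure(t) * 17.502 * 240.97 / (t + 240.97) ** 2


def vpd_from_vapour_pressure(temp_c, vap_hpa):
    """Vapour pressure deficit D (Pa) from temperature (C) and vapour pressure (hPa).

    Negative deficits (super-saturation in the data) are clipped to zero.
    """
    vap = np.asarray(vap_hpa, dtype=float)
    if np.any(vap < 0):
        raise ValueError("vapour pressure must be non-negative")
    return np.maximum(0.0, saturation_vapour_pressure(temp_c) - vap * 100.0)


def atmospheric_pressure(elevation_m: float) -> float:
    """Standard-atmosphere pressure (Pa) at the given elevation (m)."""
    if not np.isfinite(elevation_m):
        raise ValueError("elevation must be finite")
    return P0 * (1.0 - 2.25577e-5 * elevation_m) ** 5.25588


# ----------------------------------------------------------------------
# solar geometry and PAR
# ----------------------------------------------------------------------

_MONTH_START_DOY = np.concatenate([[0], np.cumsum(MONTH_DAYS)])[:12]


def solar_declination(day_of_year):
    """Solar declination (radians), 365-day calendar."""
    n = np.asarray(day_of_year, dtype=float)
    return np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + n) / 365.0)


def daily_toa_radiation(latitude_deg: float, day_of_year) -> np.ndarray:
    """Daily top-of-atmosphere shortwave (J m-2 d-1), analytic integral.

    Uses the sunset-hour-angle closed form; polar night returns 0.
    """
    phi = np.deg2rad(latitude_deg)
    n = np.asarray(day_of_year, dtype=float)
    delta = solar_declination(n)
    ecc = 1.0 + 0.033 * np.cos(2.0 * np.pi * n / 365.0)
    cos_hs = -np.tan(phi) * np.tan(delta)
    hs = np.arccos(np.clip(cos_hs, -1.0, 1.0))  # 0 = polar night, pi = polar day
    q = (
        (86400.0 / np.pi)
        * SOLAR_CONSTANT
        * ecc
        * (hs * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(hs))
    )
    return np.maximum(0.0, q)


def transmissivity(cloud_fraction, elevation_m: float,
                   a: float = 0.25, b: float = 0.50, k_elev: float = 2.67e-5):
    """Angstrom-type atmospheric transmissivity with an elevation enhancement."""
    cld = np.asarray(cloud_fraction, dtype=float)
    if np.any((cld < 0) | (cld > 1)):
        raise ValueError("cloud fraction must lie in [0, 1]")
    return (a + b * (1.0 - cld)) * (1.0 + k_elev * elevation_m)


def monthly_surface_shortwave(site: SiteMeta, cloud_fraction: float, month: int) -> float:
    """Total surface shortwave for one calendar month (J m-2 month-1)."""
    days = _MONTH_START_DOY[month - 1] + np.arange(MONTH_DAYS[month - 1]) + 1
    toa = daily_toa_radiation(site.latitude, days).sum()
    return float(toa * transmissivity(cloud_fraction, site.elevation))


def monthly_par(site: SiteMeta, cloud_fraction: float, month: int) -> float:
    """Canopy-incident PAR for one calendar month (mol photon m-2 month-1)."""
    return monthly_surface_shortwave(site, cloud_fraction, month) * PAR_PHOTON_PER_J


# ----------------------------------------------------------------------
# moisture index alpha (Priestley-Taylor bucket)
# ----------------------------------------------------------------------

def equilibrium_et_mm(temp_c, net_radiation_j):
    """Equilibrium evapotranspiration (mm month-1) from net radiation."""
    s = svp_slope(temp_c)
    return np.maximum(0.0, (s / (s + PSYCHROMETRIC)) * np.asarray(net_radiation_j) / LATENT_HEAT)


def moisture_index_alpha(series: ForcingSeries, soil_capacity: float = 150.0) -> pd.Series:
    """Monthly alpha = AET/EET from a single-store bucket, capped at 1.26.

    Equilibrium ET comes from net radiation (surface shortwave x (1 - albedo))
    through the Priestley-Taylor relation; actual ET is limited by the month's
    precipitation plus the soil store (default capacity 150 mm).  The bucket is
    spun up on one repeated climatology year before the reported pass, so the
    first January does not start artificially empty.  Months with zero demand
    report the cap (1.26): moisture does not limit anything there.
    """
    data = series.data
    temp = data["tmp"].to_numpy(float)
    prec = data["pre"].to_numpy(float)
    cld = data["cld"].to_numpy(float)
    months = data.index.get_level_values("month").to_numpy()

    sw = np.array([monthly_surface_shortwave(series.site, c, m) for c, m in zip(cld, months)])
    eet = equilibrium_et_mm(temp, (1.0 - ALBEDO) * sw)
    demand = PT_COEFF * eet

    # spin-up on the mean climatology year
    clim = data.groupby(level="month").mean()
    clim_sw = np.array(
        [monthly_surface_shortwave(series.site, clim["cld"][m], m) for m in range(1, 13)]
    )
    clim_eet = equilibrium_et_mm(clim["tmp"].to_numpy(float), (1.0 - ALBEDO) * clim_sw)
    clim_demand = PT_COEFF * clim_eet
    clim_pre = clim["pre"].to_numpy(float)

    store = soil_capacity / 2.0
    for p, d in zip(clim_pre, clim_demand):
        aet = min(store + p, d)
        store = min(soil_capacity, store + p - aet)

    alpha = np.empty_like(eet)
    for i, (p, d, e) in enumerate(zip(prec, demand, eet)):
        aet = min(store + p, d)
        store = min(soil_capacity, store + p - aet)
        alpha[i] = PT_COEFF if e <= 0.0 else min(PT_COEFF, aet / e)
    return pd.Series(alpha, index=data.index, name="alpha")


# ----------------------------------------------------------------------
# climatology corrections
# ----------------------------------------------------------------------

_ADDITIVE_VARS = ("tmp", "vap")
_RATIO_VARS = ("pre", "cld")


def elevation_correct(series: ForcingSeries, coarse_normals: pd.DataFrame,
                      fine_normals: pd.DataFrame) -> ForcingSeries:
    """Downscale a coarse-grid series to site elevation using two climatologies.

    Per calendar month: additive (fine - coarse) shifts for temperature and
    vapour pressure; ratio (fine / coarse) scaling for precipitation and cloud.
    A zero coarse normal for a ratio variable falls back to an additive shift
    for that month.  Cloud is clipped to [0, 1], precipitation and vapour
    pressure to >= 0.
    """
    for normals in (coarse_normals, fine_normals):
        if set(normals.index) != set(range(1, 13)):
            raise ValueError("climatology normals must cover months 1-12")
    out = series.copy()
    months = out.data.index.get_level_values("month")
    for var in _ADDITIVE_VARS:
        if var in coarse_normals.columns:
            shift = (fine_normals[var] - coarse_normals[var]).reindex(months).to_numpy()
            out.data[var] = out.data[var].to_numpy() + shift
    for var in _RATIO_VARS:
        if var not in coarse_normals.columns:
            continue
        coarse = coarse_normals[var].reindex(months).to_numpy(float)
        fine = fine_normals[var].reindex(months).to_numpy(float)
        vals = out.data[var].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = vals * np.where(coarse != 0, fine / np.where(coarse != 0, coarse, 1.0), np.nan)
        additive = vals + (fine - coarse)
        out.data[var] = np.where(coarse != 0, scaled, additive)
    out.data["vap"] = out.data["vap"].clip(lower=0.0)
    out.data["pre"] = out.data["pre"].clip(lower=0.0)
    out.data["cld"] = out.data["cld"].clip(0.0, 1.0)
    return out


def bias_correct_lgm(lgm_series: ForcingSeries, picontrol_normals: pd.DataFrame,
                     modern_normals: pd.DataFrame,
                     precip_mode: str = "additive") -> ForcingSeries:
    """Remove control-run bias from a glacial series.

    Adds (modern normal - piControl normal) to every month of the glacial
    series, per calendar month and variable, so the corrected glacial
    climatology differs from the raw one by exactly the control-run bias.
    Precipitation can optionally be corrected as a ratio instead.
    """
    if precip_mode not in ("additive", "ratio"):
        raise ValueError("precip_mode must be 'additive' or 'ratio'")
    for normals in (picontrol_normals, modern_normals):
        if set(normals.index) != set(range(1, 13)):
            raise ValueError("climatology normals must cover months 1-12")
    out = lgm_series.copy()
    months = out.data.index.get_level_values("month")
    for var in ("tmp", "dtr", "pre", "vap", "cld"):
        if var not in picontrol_normals.columns:
            continue
        if var == "pre" and precip_mode == "ratio":
            pic = picontrol_normals[var].reindex(months).to_numpy(float)
            mod = modern_normals[var].reindex(months).to_numpy(float)
            ratio = np.where(pic != 0, mod / np.where(pic != 0, pic, 1.0), 1.0)
            out.data[var] = out.data[var].to_numpy(float) * ratio
        else:
            shift = (modern_normals[var] - picontrol_normals[var]).reindex(months).to_numpy()
            out.data[var] = out.data[var].to_numpy(float) + shift
    out.data["pre"] = out.data["pre"].clip(lower=0.0)
    out.data["vap"] = out.data["vap"].clip(lower=0.0)
    out.data["cld"] = out.data["cld"].clip(0.0, 1.0)
    return out


# ----------------------------------------------------------------------
# growing season and the accumulation window
# ----------------------------------------------------------------------

def growing_season_mask(temp_c) -> np.ndarray:
    """True for months whose mean temperature is strictly above -1 deg C."""
    return np.asarray(temp_c, dtype=float) > GROWING_THRESHOLD


def accumulation_window(monthly: pd.Series, ring_year: int, mode: str = "sum") -> float:
    """Accumulate a monthly series over the ring year's 24-month carbon window.

    The window for ring year ``y`` spans July(y-2) .. June(y).  ``mode='sum'``
    returns the annualized sum (24-month total divided by 2); ``mode='mean'``
    the plain 24-month mean.  Raises KeyError when the window is incomplete,
    so the first two ring years of any run are unavailable.
    """
    window = _window_index(ring_year)
    try:
        vals = monthly.loc[window]
    except KeyError as exc:
        raise KeyError(f"incomplete 24-month window for ring year {ring_year}") from exc
    if len(vals) != 24 or vals.isna().any():
        raise KeyError(f"incomplete 24-month window for ring year {ring_year}")
    if mode == "sum":
        return float(vals.sum()) / 2.0
    if mode == "mean":
        return float(vals.mean())
    raise ValueError("mode must be 'sum' or 'mean'")


def _window_index(ring_year: int) -> pd.MultiIndex:
    pairs = [(ring_year - 2, m) for m in range(7, 13)]
    pairs += [(ring_year - 1, m) for m in range(1, 13)]
    pairs += [(ring_year, m) for m in range(1, 7)]
    return pd.MultiIndex.from_tuples(pairs, names=["year", "month"])


def available_ring_years(series_index: pd.MultiIndex) -> np.ndarray:
    """Ring years whose full 24-month window lies inside the series."""
    years = np.sort(series_index.get_level_values("year").unique().to_numpy())
    return years[2:] if len(years) > 2 else np.array([], dtype=int)


def annualize(monthly: pd.Series, mode: str = "sum") -> pd.Series:
    """Vectorised accumulation window over every available ring year."""
    out = {}
    for y in available_ring_years(monthly.index):
        out[int(y)] = accumulation_window(monthly, int(y), mode=mode)
    return pd.Series(out, dtype=float).rename(monthly.name)


# ----------------------------------------------------------------------
# the driver pipeline
# ----------------------------------------------------------------------

def prepare_forcing(series: ForcingSeries, soil_capacity: float = 150.0) -> ForcingSeries:
    """Fill the derived driver columns (vpd, par, alpha, growing) in place of a copy."""
    out = series.copy()
    data = out.data
    data["vpd"] = vpd_from_vapour_pressure(data["tmp"], data["vap"])
    months = data.index.get_level_values("month").to_numpy()
    data["par"] = [
        monthly_par(out.site, c, m) for c, m in zip(data["cld"].to_numpy(float), months)
    ]
    data["alpha"] = moisture_index_alpha(out, soil_capacity=soil_capacity)
    data["growing"] = growing_season_mask(data["tmp"])
    return out


__all__ = [
    "saturation_vapour_pressure",
    "svp_slope",
    "vpd_from_vapour_pressure",
    "atmospheric_pressure",
    "solar_declination",
    "daily_toa_radiation",
    "transmissivity",
    "monthly_surface_shortwave",
    "monthly_par",
    "equilibrium_et_mm",
    "moisture_index_alpha",
    "elevation_correct",
    "bias_correct_lgm",
    "growing_season_mask",
    "accumulation_window",
    "available_ring_years",
    "annualize",
    "prepare_forcing",
    "P0",
    "PT_COEFF",
]
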