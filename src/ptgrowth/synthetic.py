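"""Synthetic forcing: site-like monthly climate, CO2 trajectories and rings.

The generator emulates the kind of inputs the real analysis draws from
gridded monthly climate products and ice-core CO2 records, so that every
downstream stage is testable without downloads:

* monthly temperature = annual-mean + seasonal sinusoid (July peak in the
  northern hemisphere) + AR(1) noise;
* precipitation = seasonal winter/summer split with multiplicative
  lognormal interannual noise;
* vapour pressure = mean relative humidity x Magnus saturation pressure of
  the month's temperature, so the synthetic humidity is self-consistent
  with how VPD is later derived;
* cloud fraction = constant + small Gaussian noise, clipped to [0, 1];
* glacial-style scenarios via additive per-calendar-month anomalies
  (temperature, precipitation, relative humidity);
* truth-known "observed" ring series by running the full forward model and
  adding Gaussian observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prep
from .tmodel import RingSeries, SpeciesParams, simulate_growth
from .types import ForcingSeries, SiteMeta, monthly_index

#: emulates a high-elevation dry-summer montane conifer site in California
DEFAULT_SITE = SiteMeta(latitude=36.95, longitude=-118.92, elevation=2630.0, name="synthetic-montane")


@dataclass(frozen=True)
class SyntheticClimateConfig:
    """Stated world for the synthetic modern climate (montane, dry-summer)."""

    n_years: int = 83
    first_year: int = 1903
    mean_annual_temp: float = 7.5     # deg C
    seasonal_amplitude: float = 9.0   # deg C, half peak-to-trough
    diurnal_range: float = 14.0       # deg C
    annual_precip: float = 600.0      # mm
    precip_winter_fraction: float = 0.75  # Oct-Mar share of the annual total
    mean_relative_humidity: float = 0.55
    cloud_fraction: float = 0.35
    ar1_coefficient: float = 0.3
    noise_sd_temp: float = 1.0        # deg C
    noise_sd_precip_lognormal: float = 0.4  # SD of log precip multiplier
    seed: int = 0
    southern_hemisphere: bool = False

    def __post_init__(self):
        vals = [self.mean_annual_temp, self.seasonal_amplitude, self.diurnal_range,
                self.annual_precip, self.precip_winter_fraction,
                self.mean_relative_humidity, self.cloud_fraction,
                self.ar1_coefficient, self.noise_sd_temp, self.noise_sd_precip_lognormal]
        if not np.isfinite(vals).all():
            raise ValueError("climate config values must be finite")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in ("precip_winter_fraction", "mean_relative_humidity", "cloud_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class AnomalyConfig:
    """Per-calendar-month climate anomalies defining a scenario shift.

    Defaults are a mid-range glacial scenario for the study region: year-round
    cooling of 4 deg C (pollen evidence: 2-6 deg C in both summer and winter),
    +200 mm/yr precipitation (evidence: 100-300 mm more than today) and
    slightly higher relative humidity.
    """

    delta_temp: tuple = (-4.0,) * 12     # deg C per calendar month
    delta_precip: tuple = (200.0 / 12,) * 12  # mm per calendar month
    delta_rh: tuple = (0.05,) * 12       # RH fraction per calendar month

    def __post_init__(self):
        for name in ("delta_temp", "delta_precip", "delta_rh"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            if not np.isfinite(v).all():
                raise ValueError(f"{name} must be finite")

    @classmethod
    def uniform(cls, d_temp: float = 0.0, d_precip_annual: float = 0.0,
                d_rh: float = 0.0) -> "AnomalyConfig":
        return cls((d_temp,) * 12, (d_precip_annual / 12.0,) * 12, (d_rh,) * 12)


# seasonal precipitation shape: winter share spread Oct-Mar, rest Apr-Sep
_WINTER = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1], dtype=bool)


def generate_monthly_climate(config: SyntheticClimateConfig,
                             site: SiteMeta = DEFAULT_SITE) -> ForcingSeries:
    """Generate a seeded, site-like monthly climate series (no CO2 attached)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_years
    idx = monthly_index(config.first_year, n)
    months = idx.get_level_values("month").to_numpy()

    # temperature: sinusoid peaking mid-July (northern) or mid-January (southern)
    peak_month = 1.0 if config.southern_hemisphere else 7.0
    phase = 2.0 * np.pi * (months - peak_month) / 12.0
    seasonal = config.mean_annual_temp + config.seasonal_amplitude * np.cos(phase)
    noise = np.zeros(12 * n)
    if config.noise_sd_temp > 0:
        eps = rng.normal(0.0, config.noise_sd_temp * np.sqrt(1 - config.ar1_coefficient**2),
                         size=12 * n)
        prev = 0.0
        for i in range(12 * n):
            prev = config.ar1_coefficient * prev + eps[i]
            noise[i] = prev
    tmp = seasonal + noise

    # precipitation: seasonal split x lognormal multiplicative noise
    winter_total = config.annual_precip * config.precip_winter_fraction
    summer_total = config.annual_precip - winter_total
    base = np.where(_WINTER[months - 1], winter_total / 6.0, summer_total / 6.0)
    if config.noise_sd_precip_lognormal > 0:
        sd = config.noise_sd_precip_lognormal
        mult = rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=12 * n)
    else:
        mult = np.ones(12 * n)
    pre = base * mult

    vap = config.mean_relative_humidity * prep.saturation_vapour_pressure(tmp) / 100.0  # hPa
    # cloud jitter scales with the temperature noise so a zero-noise config
    # yields an exactly repeating annual cycle
    cld_sd = 0.02 * config.noise_sd_temp
    cld_noise = rng.normal(0.0, cld_sd, size=12 * n) if cld_sd > 0 else np.zeros(12 * n)
    cld = np.clip(config.cloud_fraction + cld_noise, 0.0, 1.0)

    data = pd.DataFrame(
        {"tmp": tmp, "dtr": config.diurnal_range, "pre": pre, "vap": vap, "cld": cld},
        index=idx,
    )
    return ForcingSeries(site, data)


def apply_anomalies(series: ForcingSeries, anomaly: AnomalyConfig) -> ForcingSeries:
    """Shift a series by per-calendar-month anomalies.

    Relative humidity is the conserved humidity quantity: the RH implied by
    the original months is shifted by delta_rh and vapour pressure is then
    recomputed at the anomaly-shifted temperature.  Exactly invertible by
    negating the anomaly wherever no clipping occurred.
    """
    out = series.copy()
    months = out.data.index.get_level_values("month").to_numpy()
    d_t = np.asarray(anomaly.delta_temp)[months - 1]
    d_p = np.asarray(anomaly.delta_precip)[months - 1]
    d_rh = np.asarray(anomaly.delta_rh)[months - 1]

    tmp_old = out.data["tmp"].to_numpy(float)
    rh = out.data["vap"].to_numpy(float) * 100.0 / prep.saturation_vapour_pressure(tmp_old)
    rh_new = np.clip(rh + d_rh, 0.0, 1.0)
    tmp_new = tmp_old + d_t
    out.data["tmp"] = tmp_new
    out.data["vap"] = rh_new * prep.saturation_vapour_pressure(tmp_new) / 100.0
    out.data["pre"] = np.maximum(0.0, out.data["pre"].to_numpy(float) + d_p)
    return out


def generate_co2_series(years, mode: str = "constant",
                        level_or_endpoints=180.0) -> pd.Series:
    """Annual CO2 (ppm): a constant level or a linear ramp between endpoints."""
    years = np.asarray(list(years), dtype=int)
    if mode == "constant":
        level = float(level_or_endpoints)
        if level <= 0:
            raise ValueError("CO2 level must be positive")
        vals = np.full(len(years), level)
    elif mode == "ramp":
        lo, hi = (float(v) for v in level_or_endpoints)
        if lo <= 0 or hi <= 0:
            raise ValueError("CO2 endpoints must be positive")
        vals = np.linspace(lo, hi, len(years))
    else:
        raise ValueError("mode must be 'constant' or 'ramp'")
    return pd.Series(vals, index=pd.Index(years, name="year"), name="co2_ppm")


def generate_synthetic_rings(params: SpeciesParams, forcing: ForcingSeries,
                             obs_noise_sd: float = 0.0, seed: int = 0,
                             d0: float = 0.3) -> RingSeries:
    """Truth-known "observed" rings: forward model plus Gaussian noise.

    The forcing must already be prepared (derived drivers present) and long
    enough for the 24-month accumulation window.  Noisy widths are clipped at
    0 (a ring cannot be negative); the true parameters travel in the metadata.
    """
    truth = simulate_growth(forcing, params, d0=d0)
    rng = np.random.default_rng(seed)
    widths = truth.widths.to_numpy(float)
    if obs_noise_sd > 0:
        widths = np.maximum(0.0, widths + rng.normal(0.0, obs_noise_sd, size=len(widths)))
    return RingSeries(
        pd.Series(widths, index=truth.widths.index),
        meta={**truth.meta, "true_params": params, "obs_noise_sd": obs_noise_sd, "seed": seed},
    )


__all__ = [
    "DEFAULT_SITE",
    "SyntheticClimateConfig",
    "AnomalyConfig",
    "generate_monthly_climate",
    "apply_anomalies",
    "generate_co2_series",
    "generate_synthetic_rings",
]
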