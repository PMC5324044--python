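"""Least-cost photosynthesis: optimal ci, CO2 limitation and potential GPP.

The light-use-efficiency ("P") model computes, month by month:

* the photorespiratory compensation point Gamma* (exponential temperature
  response calibrated to the Arrhenius curve, scaled with air pressure);
* the effective Michaelis-Menten coefficient K for Rubisco-limited
  photosynthesis (Bernacchi-type constants, pressure- and O2-dependent);
* the least-cost optimal leaf-internal CO2,
      ci = Gamma* + (ca - Gamma*) * xi / (xi + sqrt(D)),
  with stomatal sensitivity xi = sqrt(beta * (K + Gamma*) / (1.6 eta*)),
  where beta is the carboxylation:transpiration unit-cost ratio at 25 C and
  eta* the water-viscosity ratio relative to 25 C;
* the CO2 limitation factor m = (ci - Gamma*) / (ci + 2 Gamma*);
* potential GPP per unit ground area,
      GPP = Phi0 * PAR_growing * m * (alpha / 1.26)^(1/4),
  with Phi0 = 0.816 g C per mol photon (0.085 mol C per mol photon x 12 g
  per mol x leaf absorptance 0.8);
* diagnostic Vcmax(25) (coordination estimate) and stomatal conductance
  (Fick's law with the 1.6 diffusivity ratio).  These do not feed back into
  GPP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import prep
from .types import MONTH_DAYS, ForcingSeries

R_GAS = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class PModelConstants:
    """Physiological constants of the P model.

    ``beta`` is the single most sensitivity-relevant constant: the unit-cost
    ratio for carboxylation vs. transpiration at 25 C. The default 240 puts
    simulated modern ci/ca for dry-summer montane conifer sites in the
    observed 0.5-0.6 band.
    """

    phi0: float = 0.816  # g C mol-1 photon, = 0.085 * 12 * absorptance
    quantum_yield: float = 0.085  # mol C mol-1 photon
    leaf_absorptance: float = 0.8
    beta: float = 240.0
    gammastar25: float = 4.331  # Pa at 25 C, sea level
    exp_coeff_gammastar: float = 0.0512  # per deg C
    kc25: float = 39.97  # Pa
    ko25: float = 27480.0  # Pa
    dh_kc: float = 79430.0  # J mol-1
    dh_ko: float = 36380.0
    dh_gammastar: float = 37830.0  # used only by the Arrhenius cross-check
    dh_vcmax: float = 65330.0
    o2_mole_fraction: float = 0.20946
    drought_ref_alpha: float = prep.PT_COEFF

    def __post_init__(self):
        fields = (self.phi0, self.beta, self.gammastar25, self.kc25, self.ko25)
        if any(v <= 0 for v in fields[:1] + fields[2:]) or self.beta < 0:
            raise ValueError("P-model constants must be positive (beta >= 0)")


DEFAULT_CONSTANTS = PModelConstants()


def arrhenius(temp_c, dh: float) -> np.ndarray:
    """Arrhenius scaling factor relative to 25 C."""
    tk = np.asarray(temp_c, dtype=float) + 273.15
    return np.exp(dh / R_GAS * (1.0 / 298.15 - 1.0 / tk))


def gammastar(temp_c, patm: float, constants: PModelConstants = DEFAULT_CONSTANTS):
    """Photorespiratory compensation point Gamma* (Pa).

    Exponential in temperature (coefficient 0.0512 per deg C approximates the
    Arrhenius curve within 2% over 0-35 C) and linear in pressure, since
    Gamma* is a partial pressure.
    """
    dt = np.asarray(temp_c, dtype=float) - 25.0
    return constants.gammastar25 * np.exp(constants.exp_coeff_gammastar * dt) * (patm / prep.P0)


def gammastar_arrhenius(temp_c, patm: float,
                        constants: PModelConstants = DEFAULT_CONSTANTS):
    """Full-Arrhenius Gamma*: the independent cross-check for the exponential form."""
    return constants.gammastar25 * arrhenius(temp_c, constants.dh_gammastar) * (patm / prep.P0)


def effective_K(temp_c, patm: float, constants: PModelConstants = DEFAULT_CONSTANTS):
    """Effective Michaelis-Menten coefficient K (Pa) for Rubisco-limited photosynthesis.

    K = Kc (1 + pO2 / Ko); Kc and Ko follow Arrhenius responses from their
    25 C values and, being partial-pressure quantities, scale linearly with
    air pressure.
    """
    scale = patm / prep.P0
    kc = constants.kc25 * arrhenius(temp_c, constants.dh_kc) * scale
    ko = constants.ko25 * arrhenius(temp_c, constants.dh_ko) * scale
    po2 = constants.o2_mole_fraction * patm
    return kc * (1.0 + po2 / ko)


# CRC-handbook dynamic viscosity of pure water, mPa s (supercooled below 0 C)
_VISC_T = np.array([-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0,
                    20.0, 25.0, 30.0, 35.0, 40.0, 45.0])
_VISC_MU = np.array([4.33, 3.34, 2.60, 2.14, 1.793, 1.519, 1.307, 1.138,
                     1.002, 0.8904, 0.7975, 0.7195, 0.6530, 0.5961])
_visc_interp = PchipInterpolator(_VISC_T, _VISC_MU, extrapolate=True)


def viscosity_ratio(temp_c) -> np.ndarray:
    """eta* = viscosity of water at temp / viscosity at 25 C (handbook values)."""
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -20.0):
        raise ValueError("viscosity correlation valid only above -20 C")
    return np.asarray(_visc_interp(np.clip(t, -20.0, 45.0)) / _visc_interp(25.0))


def xi(temp_c, patm: float, constants: PModelConstants = DEFAULT_CONSTANTS):
    """Stomatal sensitivity xi (Pa^0.5): larger xi keeps ci closer to ca as D rises."""
    k = effective_K(temp_c, patm, constants)
    gs = gammastar(temp_c, patm, constants)
    eta = viscosity_ratio(temp_c)
    return np.sqrt(constants.beta * (k + gs) / (1.6 * eta))


def ci_leaf(ca_pa, vpd_pa, xi_val, gammastar_pa):
    """Least-cost optimal leaf-internal CO2 (Pa), bounded by [Gamma*, ca].

    ca below the compensation point is flagged by returning ci = ca (no
    assimilation downstream because m <= 0 there).
    """
    ca = np.asarray(ca_pa, dtype=float)
    d = np.asarray(vpd_pa, dtype=float)
    if np.any(d < 0):
        raise ValueError("VPD must be non-negative")
    ci = gammastar_pa + (ca - gammastar_pa) * xi_val / (xi_val + np.sqrt(d))
    return np.where(ca < gammastar_pa, ca, ci)


def co2_limitation(ci_pa, gammastar_pa):
    """CO2 limitation factor m = (ci - Gamma*)/(ci + 2 Gamma*), floored at 0."""
    ci = np.asarray(ci_pa, dtype=float)
    return np.maximum(0.0, (ci - gammastar_pa) / (ci + 2.0 * gammastar_pa))


def drought_factor(alpha, constants: PModelConstants = DEFAULT_CONSTANTS):
    """Soil-moisture GPP modifier (alpha / 1.26)^(1/4), in [0, 1]."""
    a = np.clip(np.asarray(alpha, dtype=float), 0.0, constants.drought_ref_alpha)
    return (a / constants.drought_ref_alpha) ** 0.25


def cica_from_discrimination(delta13_permil):
    """ci/ca from C3 carbon-isotope discrimination: (Delta - a)/(b - a), a=4.4, b=27 permil."""
    d = np.asarray(delta13_permil, dtype=float)
    if np.any((d < 0) | (d > 30)):
        raise ValueError("discrimination outside the plausible 0-30 permil range")
    return (d - 4.4) / (27.0 - 4.4)


def annual_cica(ci_over_ca: np.ndarray, weights: np.ndarray) -> float:
    """GPP-weighted annual mean of monthly ci/ca over growing-season months.

    Falls back to the unweighted mean when every weight is zero (e.g. a year
    of complete drought).
    """
    r = np.asarray(ci_over_ca, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.size == 0:
        raise ValueError("needs at least one growing-season month")
    if w.sum() <= 0:
        return float(r.mean())
    return float(np.average(r, weights=w))


def run_pmodel(series: ForcingSeries,
               constants: PModelConstants = DEFAULT_CONSTANTS,
               drought_mode: str = "monthly") -> pd.DataFrame:
    """Monthly P-model outputs for a prepared forcing series.

    Requires the derived columns from :func:`ptgrowth.prep.prepare_forcing`.
    Returns a frame indexed like the forcing with columns: ci_pa, ca_pa, cica,
    m, gpp (g C m-2 month-1, zero outside the growing season), vcmax25
    (umol m-2 s-1) and gs (mol m-2 s-1).

    ``drought_mode='annual'`` applies each calendar year's growing-season mean
    alpha uniformly instead of the month's own alpha.
    """
    if drought_mode not in ("monthly", "annual"):
        raise ValueError("drought_mode must be 'monthly' or 'annual'")
    data = series.data
    for col in ("vpd", "par", "alpha", "growing"):
        if col not in data.columns:
            raise ValueError("forcing not prepared: run prepare_forcing first")

    patm = prep.atmospheric_pressure(series.site.elevation)
    temp = data["tmp"].to_numpy(float)
    vpd = data["vpd"].to_numpy(float)
    par = data["par"].to_numpy(float)
    growing = data["growing"].to_numpy(bool)
    alpha = data["alpha"].to_numpy(float)
    ca_ppm = series.monthly_co2().to_numpy(float)
    ca_pa = ca_ppm * 1e-6 * patm

    gs_pa = np.asarray(gammastar(temp, patm, constants))
    xi_val = np.asarray(xi(temp, patm, constants))
    ci = ci_leaf(ca_pa, vpd, xi_val, gs_pa)
    m = co2_limitation(ci, gs_pa)

    if drought_mode == "annual":
        yrs = data.index.get_level_values("year")
        alpha_s = pd.Series(np.where(growing, alpha, np.nan), index=data.index)
        annual_alpha = alpha_s.groupby(level="year").mean()
        alpha = annual_alpha.reindex(yrs).fillna(constants.drought_ref_alpha).to_numpy()

    fdrought = drought_factor(alpha, constants)
    par_growing = np.where(growing, par, 0.0)
    gpp = constants.phi0 * par_growing * m * fdrought  # g C m-2 month-1

    # diagnostics (monthly-mean rates); not fed back into GPP
    phi0_mol = constants.phi0 / 12.0  # mol C per mol photon, absorptance included
    seconds = MONTH_DAYS[data.index.get_level_values("month").to_numpy() - 1] * 86400.0
    k = np.asarray(effective_K(temp, patm, constants))
    with np.errstate(divide="ignore", invalid="ignore"):
        vcmax = phi0_mol * (par_growing / seconds) * (ci + k) / (ci + 2.0 * gs_pa)
        vcmax25 = np.where(ci > gs_pa, vcmax / arrhenius(temp, constants.dh_vcmax), np.nan) * 1e6
        assim = (gpp / 12.0) / seconds  # mol C m-2 s-1
        gs_cond = np.where(ca_pa > ci, 1.6 * assim / ((ca_pa - ci) / patm), np.nan)

    return pd.DataFrame(
        {
            "ci_pa": ci,
            "ca_pa": ca_pa,
            "cica": ci / ca_pa,
            "m": m,
            "gpp": gpp,
            "vcmax25": vcmax25,
            "gs": gs_cond,
        },
        index=data.index,
    )


def annual_potential_gpp(pmodel_monthly: pd.DataFrame) -> pd.Series:
    """Annualized potential GPP per ring year (kg C m-2 a-1), 24-month window."""
    return prep.annualize(pmodel_monthly["gpp"], mode="sum") / 1000.0


def annual_summaries(pmodel_monthly: pd.DataFrame) -> pd.DataFrame:
    """Calendar-year GPP-weighted ci/ca, vcmax25 and gs plus annual GPP totals."""
    rows = {}
    for year, grp in pmodel_monthly.groupby(level="year"):
        w = grp["gpp"].to_numpy(float)
        rows[year] = {
            "cica": annual_cica(grp["cica"].to_numpy(), w),
            "gpp": float(w.sum()) / 1000.0,  # kg C m-2 a-1
            "vcmax25": _weighted_or_nan(grp["vcmax25"].to_numpy(), w),
            "gs": _weighted_or_nan(grp["gs"].to_numpy(), w),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("year")


def _weighted_or_nan(values: np.ndarray, weights: np.ndarray) -> float:
    ok = np.isfinite(values) & (weights > 0)
    if not ok.any():
        return float("nan")
    return float(np.average(values[ok], weights=weights[ok]))


__all__ = [
    "PModelConstants",
    "DEFAULT_CONSTANTS",
    "arrhenius",
    "gammastar",
    "gammastar_arrhenius",
    "effective_K",
    "viscosity_ratio",
    "xi",
    "ci_leaf",
    "co2_limitation",
    "drought_factor",
    "cica_from_discrimination",
    "annual_cica",
    "run_pmodel",
    "annual_potential_gpp",
    "annual_summaries",
]
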