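"""The experiment suite: validation, ci/ca profiles and swaps, CO2-gradient
allocation optimization, climate-variable substitution, and the
accumulation-window regression diagnostic.

Every experiment is a pure function over prepared forcing series, so the
analysis drivers, the CLI and the tests all call the same code.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import pmodel, prep
from .abc import ABCConfig, optimize_allocation
from .tmodel import RingSeries, SpeciesParams, simulate_growth
from .types import ForcingSeries, SiteMeta


def percent_change(baseline: float, experiment: float) -> float:
    """100 (experiment - baseline) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return 100.0 * (experiment - baseline) / baseline


# ----------------------------------------------------------------------
# modern validation
# ----------------------------------------------------------------------

def run_modern_validation(forcing: ForcingSeries, observed: RingSeries,
                          params: SpeciesParams, d0: float = 0.3,
                          smooth_years: int = 10) -> dict:
    """Simulate rings under the modern forcing and compare with observations.

    Reports simulated and observed mean widths over the overlap, the Pearson
    correlation of the annual series, and the correlation of ``smooth_years``
    rolling means (the decadal-trend skill).  Degenerate (constant) series
    report NaN correlations rather than failing.
    """
    simulated = simulate_growth(forcing, params, d0=d0)
    overlap = simulated.widths.index.intersection(observed.widths.index)
    if len(overlap) < 10:
        raise ValueError(f"only {len(overlap)} overlapping ring years (need >= 10)")
    sim = simulated.widths.loc[overlap]
    obs = observed.widths.loc[overlap]
    r_annual = _safe_pearson(sim, obs)
    sim_s = sim.rolling(smooth_years, center=True).mean().dropna()
    obs_s = obs.rolling(smooth_years, center=True).mean().dropna()
    r_smooth = _safe_pearson(sim_s, obs_s)
    return {
        "n_years": int(len(overlap)),
        "mean_simulated_mm": float(sim.mean()),
        "mean_observed_mm": float(obs.mean()),
        "r_annual": r_annual,
        "r_smoothed": r_smooth,
        "simulated": simulated,
    }


def _safe_pearson(a: pd.Series, b: pd.Series) -> float:
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


# ----------------------------------------------------------------------
# ci/ca experiments
# ----------------------------------------------------------------------

def site_annual_cica(forcing: ForcingSeries, averaging_years: int | None = None) -> dict:
    """Mean and 2-SD interannual band of annual GPP-weighted ci/ca for one site.

    ``averaging_years`` takes the last N calendar years (the study convention:
    50 for modern, 100 for glacial) when the series is long enough; otherwise
    the full series is used.
    """
    summaries = pmodel.annual_summaries(pmodel.run_pmodel(forcing))
    cica = summaries["cica"].dropna()
    if averaging_years is not None and len(cica) >= averaging_years:
        cica = cica.iloc[-averaging_years:]
    return {
        "cica_mean": float(cica.mean()),
        "cica_2sd": float(2.0 * cica.std()),
        "n_years": int(len(cica)),
        "gpp_mean": float(summaries["gpp"].reindex(cica.index).mean()),
    }


def run_cica_profile(forcings: dict[str, ForcingSeries],
                     averaging_years: int | None = None) -> pd.DataFrame:
    """Annual ci/ca per site (sites keyed by name, forcing already site-adjusted)."""
    rows = {}
    for name, forcing in forcings.items():
        row = site_annual_cica(forcing, averaging_years)
        row["elevation_m"] = forcing.site.elevation
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_values("elevation_m")


def elevation_variant(forcing: ForcingSeries, elevation: float,
                      lapse_rate: float = -6.5e-3, name: str | None = None) -> ForcingSeries:
    """Shift a forcing series to another elevation.

    Temperature follows the lapse rate (deg C per m, default -6.5 K/km);
    vapour pressure is recomputed to conserve relative humidity; pressure and
    PAR transmissivity pick up the new elevation through the site metadata.
    Derived drivers must be (re-)prepared by the caller.
    """
    site = forcing.site
    new_site = SiteMeta(site.latitude, site.longitude, elevation,
                        name=name or f"{site.name}@{elevation:.0f}m")
    out = forcing.with_site(new_site)
    dt = lapse_rate * (elevation - site.elevation)
    tmp_old = out.data["tmp"].to_numpy(float)
    rh = out.data["vap"].to_numpy(float) * 100.0 / prep.saturation_vapour_pressure(tmp_old)
    out.data["tmp"] = tmp_old + dt
    out.data["vap"] = rh * prep.saturation_vapour_pressure(tmp_old + dt) / 100.0
    return prep.prepare_forcing(out) if "vpd" in forcing.data.columns else out


def run_cica_swap(modern: ForcingSeries, glacial: ForcingSeries,
                  averaging_years: int | None = None) -> dict[str, float]:
    """The temperature/VPD swap experiment on annual ci/ca.

    Temperature and VPD are the only climate variables entering the ci/ca
    calculation, so the four combinations {glacial, modern-T + glacial-VPD,
    glacial-T + modern-VPD, modern (= both swapped)} isolate the two
    compensating effects of the glacial climate.  All four runs share the
    glacial scenario's other drivers (PAR, alpha, CO2): everything except the
    swapped variables is held at glacial values, so applying both swaps
    reproduces the full-modern combination exactly by construction.
    """
    combos = {
        "glacial": (None, None),
        "modernT_glacialVPD": (modern, None),
        "glacialT_modernVPD": (None, modern),
        "modern": (modern, modern),
    }
    out = {}
    for name, (temp_source, vpd_source) in combos.items():
        run = glacial.copy()
        if temp_source is not None:
            run.data["tmp"] = temp_source.data["tmp"].reindex(run.data.index).to_numpy()
            # growing-season mask follows the temperature in use
            run.data["growing"] = prep.growing_season_mask(run.data["tmp"])
        if vpd_source is not None:
            run.data["vpd"] = vpd_source.data["vpd"].reindex(run.data.index).to_numpy()
        out[name] = site_annual_cica(run, averaging_years)["cica_mean"]
    return out


# ----------------------------------------------------------------------
# CO2 gradient allocation optimization
# ----------------------------------------------------------------------

def run_co2_gradient(forcing_glacial: ForcingSeries, target_rw: float,
                     fixed: SpeciesParams, abc_config: ABCConfig,
                     co2_levels=None, reference_level: float = 320.0,
                     d0: float = 0.3) -> pd.DataFrame:
    """Optimized (L, zeta) per CO2 level and their % change vs the reference.

    Calls the two-parameter ABC at each level; a level whose ABC fails (zero
    acceptances) is reported as NaN without aborting the other levels.
    """
    if co2_levels is None:
        co2_levels = np.arange(320.0, 159.0, -20.0)
    rows = {}
    for i, level in enumerate(co2_levels):
        cfg = replace(abc_config, seed=abc_config.seed + i)
        try:
            lai, zeta, result = optimize_allocation(
                forcing_glacial, float(level), target_rw, fixed, cfg, d0=d0)
            rows[float(level)] = {
                "lai": lai, "zeta": zeta, "acceptance_rate": result.acceptance_rate}
        except RuntimeError:
            rows[float(level)] = {
                "lai": float("nan"), "zeta": float("nan"), "acceptance_rate": 0.0}
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("co2_ppm").sort_index()
    if float(reference_level) in table.index and np.isfinite(table.loc[reference_level, "lai"]):
        ref = table.loc[reference_level]
        table["lai_pct_change"] = 100.0 * (table["lai"] - ref["lai"]) / ref["lai"]
        table["zeta_pct_change"] = 100.0 * (table["zeta"] - ref["zeta"]) / ref["zeta"]
    return table


# ----------------------------------------------------------------------
# climate-variable substitution
# ----------------------------------------------------------------------

SUBSTITUTION_EXPERIMENTS = {
    "H": frozenset({"humidity"}),
    "P": frozenset({"precipitation"}),
    "T": frozenset({"temperature"}),
    "TP": frozenset({"temperature", "precipitation"}),
    "TPH": frozenset({"temperature", "precipitation", "humidity"}),
    "Full": frozenset({"temperature", "precipitation", "humidity"}),
}


def substitute_variables(glacial: ForcingSeries, modern: ForcingSeries,
                         which: frozenset | set) -> ForcingSeries:
    """Replace selected glacial variables by their modern monthly values.

    Relative humidity (not vapour pressure) is the conserved humidity
    quantity: the substituted series' vapour pressure is recomputed as the
    chosen source's RH times the saturation pressure of the resulting
    temperature, so a humidity substitution changes VPD only through
    humidity.  CO2 always stays glacial.  Derived drivers are re-prepared.
    """
    unknown = set(which) - {"temperature", "precipitation", "humidity"}
    if unknown:
        raise ValueError(f"unknown substitution variables: {sorted(unknown)}")
    out = glacial.copy()
    idx = out.data.index
    tmp = (modern if "temperature" in which else glacial).data["tmp"].reindex(idx).to_numpy(float)
    pre = (modern if "precipitation" in which else glacial).data["pre"].reindex(idx).to_numpy(float)
    rh_source = modern if "humidity" in which else glacial
    rh = (
        rh_source.data["vap"].reindex(idx).to_numpy(float) * 100.0
        / prep.saturation_vapour_pressure(rh_source.data["tmp"].reindex(idx).to_numpy(float))
    )
    out.data["tmp"] = tmp
    out.data["pre"] = pre
    out.data["vap"] = np.clip(rh, 0.0, 1.0) * prep.saturation_vapour_pressure(tmp) / 100.0
    return prep.prepare_forcing(out)


def run_climate_substitution(glacial: ForcingSeries, modern: ForcingSeries,
                             params: SpeciesParams, d0: float = 0.3,
                             experiments: dict[str, frozenset] | None = None) -> pd.DataFrame:
    """Ring-width % change vs the glacial baseline for each substitution experiment.

    The glacial baseline and all substituted runs keep glacial CO2 and the
    LGM-optimized allocation parameters in ``params``.
    """
    experiments = experiments or SUBSTITUTION_EXPERIMENTS
    glacial_prep = prep.prepare_forcing(glacial)
    baseline = simulate_growth(glacial_prep, params, d0=d0).mean_width()
    if baseline <= 0:
        raise ValueError(
            "glacial baseline mean ring width is zero: the allocation parameters "
            "do not sustain growth at glacial CO2 — calibrate (L, zeta) first")
    rows = {"glacial": {"mean_rw_mm": baseline, "pct_change": 0.0}}
    for name, which in experiments.items():
        run = substitute_variables(glacial, modern, which)
        mean_rw = simulate_growth(run, params, d0=d0).mean_width()
        rows[name] = {"mean_rw_mm": mean_rw,
                      "pct_change": percent_change(baseline, mean_rw)}
    return pd.DataFrame.from_dict(rows, orient="index")


# ----------------------------------------------------------------------
# accumulation-window regression diagnostic
# ----------------------------------------------------------------------

def _window_accumulate(monthly: pd.Series, ring_year: int, n_months: int,
                       mode: str) -> float:
    """Accumulate over the n_months ending June of the ring year."""
    end = (ring_year, 6)
    idx = monthly.index
    pos = idx.get_loc(end)
    if pos + 1 < n_months:
        raise KeyError(f"series too short for a {n_months}-month window at {ring_year}")
    vals = monthly.iloc[pos + 1 - n_months: pos + 1]
    return float(vals.sum() * (12.0 / n_months)) if mode == "sum" else float(vals.mean())


def accumulation_window_regression(observed: RingSeries, forcing: ForcingSeries,
                                   windows=(12, 24, 36)) -> pd.DataFrame:
    """OLS of ring width on climate drivers accumulated over candidate windows.

    For each window length the five drivers (total PAR, mean temperature,
    mean alpha, mean VPD, mean CO2) are accumulated over the months ending in
    June of the ring year and regressed (with intercept) against the observed
    widths.  Reports R^2 per window and flags the maximizer; an
    ill-conditioned design triggers a warning column, not a failure.
    """
    if "vpd" not in forcing.data.columns:
        forcing = prep.prepare_forcing(forcing)
    co2_monthly = forcing.monthly_co2()
    drivers = {
        "par": (forcing.data["par"], "sum"),
        "mat": (forcing.data["tmp"], "mean"),
        "alpha": (forcing.data["alpha"], "mean"),
        "vpd": (forcing.data["vpd"], "mean"),
        "co2": (co2_monthly, "mean"),
    }
    rows = {}
    for w in windows:
        if w in rows:  # duplicate window lengths give identical fits
            continue
        records = []
        for year in observed.widths.index:
            try:
                row = {k: _window_accumulate(s, int(year), w, mode) for k, (s, mode) in drivers.items()}
            except KeyError:
                continue
            row["rw"] = float(observed.widths.loc[year])
            records.append(row)
        frame = pd.DataFrame(records)
        if len(frame) < 20:
            raise ValueError(f"only {len(frame)} usable ring years for the {w}-month window (need >= 20)")
        X = sm.add_constant(frame[["par", "mat", "alpha", "vpd", "co2"]])
        fit = sm.OLS(frame["rw"], X).fit()
        rows[w] = {
            "r2": float(fit.rsquared),
            "n": int(fit.nobs),
            "condition_number": float(fit.condition_number),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("window_months")
    table["best"] = table["r2"] == table["r2"].max()
    return table


__all__ = [
    "percent_change",
    "run_modern_validation",
    "site_annual_cica",
    "run_cica_profile",
    "elevation_variant",
    "run_cica_swap",
    "run_co2_gradient",
    "SUBSTITUTION_EXPERIMENTS",
    "substitute_variables",
    "run_climate_substitution",
    "accumulation_window_regression",
]
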