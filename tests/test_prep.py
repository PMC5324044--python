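"""Forcing preparation: VPD, PAR, pressure, alpha bucket, corrections, windows."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ptgrowth import prep, synthetic
from ptgrowth.synthetic import SyntheticClimateConfig
from ptgrowth.types import MONTH_DAYS, SiteMeta


class TestVPD:
    def test_saturated_air_gives_zero(self):
        esat_hpa = prep.saturation_vapour_pressure(12.0) / 100.0
        assert prep.vpd_from_vapour_pressure(12.0, esat_hpa) == pytest.approx(0.0, abs=1e-9)

    def test_magnus_value_at_20C(self):
        # independent Magnus evaluation: e_sat(20 C) = 611.21 exp(17.502*20/260.97)
        esat = 611.21 * np.exp(17.502 * 20.0 / (20.0 + 240.97))
        expected = esat - 1000.0  # vap = 10 hPa
        assert prep.vpd_from_vapour_pressure(20.0, 10.0) == pytest.approx(expected)
        assert expected == pytest.approx(1337.0, abs=1.0)

    def test_supersaturation_clipped_not_negative(self):
        assert prep.vpd_from_vapour_pressure(10.0, 50.0) == 0.0

    def test_negative_vapour_pressure_rejected(self):
        with pytest.raises(ValueError):
            prep.vpd_from_vapour_pressure(10.0, -1.0)


class TestPAR:
    def test_polar_night_is_zero(self):
        site = SiteMeta(90.0, 0.0, 0.0)
        assert prep.monthly_par(site, 0.0, 12) == 0.0

    def test_cloud_strictly_reduces_par(self):
        site = SiteMeta(34.0, -118.0, 100.0)
        assert prep.monthly_par(site, 1.0, 6) < prep.monthly_par(site, 0.0, 6)

    def test_june_clear_sky_matches_quadrature_oracle(self):
        """Closed-form daily insolation vs. brute-force quadrature of the
        instantaneous solar-geometry flux, June at 34 N, within 1%."""
        site = SiteMeta(34.0, -118.0, 0.0)
        phi = np.deg2rad(34.0)
        total = 0.0
        for day in range(152, 152 + 30):  # June days of the 365-day calendar
            delta = prep.solar_declination(day)
            ecc = 1.0 + 0.033 * np.cos(2 * np.pi * day / 365.0)

            def flux(hour_angle):
                mu = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)
                return max(0.0, mu)

            integral, _ = quad(flux, -np.pi, np.pi, limit=200)
            total += prep.SOLAR_CONSTANT * ecc * integral * 86400.0 / (2 * np.pi)
        oracle_par = total * prep.transmissivity(0.0, 0.0) * prep.PAR_PHOTON_PER_J
        assert prep.monthly_par(site, 0.0, 6) == pytest.approx(oracle_par, rel=0.01)

    def test_invalid_cloud_rejected(self):
        with pytest.raises(ValueError):
            prep.transmissivity(1.5, 0.0)


class TestAtmosphericPressure:
    def test_sea_level_standard(self):
        assert prep.atmospheric_pressure(0.0) == pytest.approx(101325.0)

    def test_montane_value_from_barometric_formula(self):
        # independent evaluation of the standard-atmosphere formula at 2630 m
        expected = 101325.0 * (1.0 - 2.25577e-5 * 2630.0) ** 5.25588
        got = prep.atmospheric_pressure(2630.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(73.1e3, rel=0.01)  # the conventional quoted value

    def test_monotone_decreasing_in_elevation(self):
        elevs = np.linspace(-100, 5000, 40)
        p = np.array([prep.atmospheric_pressure(e) for e in elevs])
        assert (np.diff(p) < 0).all()


class TestMoistureIndex:
    def _series(self, precip_scale=1.0, **kw):
        cfg = SyntheticClimateConfig(n_years=5, noise_sd_temp=0.0,
                                     noise_sd_precip_lognormal=0.0, **kw)
        f = synthetic.generate_monthly_climate(cfg)
        f.data["pre"] *= precip_scale
        return f

    def test_abundant_water_saturates_at_cap(self):
        f = self._series(precip_scale=50.0)
        alpha = prep.moisture_index_alpha(f)
        np.testing.assert_allclose(alpha, prep.PT_COEFF)

    def test_no_water_empty_bucket_gives_zero(self):
        f = self._series(precip_scale=0.0)
        alpha = prep.moisture_index_alpha(f)
        # after the dry spin-up the store is empty: every demand month has alpha 0
        demand_months = f.data["tmp"] > 5.0
        assert (alpha[demand_months.to_numpy()] == 0.0).all()

    @pytest.mark.parametrize("seed", [0, 4])
    def test_more_precipitation_never_lowers_alpha(self, seed):
        cfg = SyntheticClimateConfig(n_years=6, seed=seed)
        f = synthetic.generate_monthly_climate(cfg)
        a1 = prep.moisture_index_alpha(f)
        f2 = f.copy()
        f2.data["pre"] *= 2.0
        a2 = prep.moisture_index_alpha(f2)
        assert (a2.to_numpy() >= a1.to_numpy() - 1e-12).all()

    def test_alpha_within_bounds(self):
        f = self._series()
        alpha = prep.moisture_index_alpha(f)
        assert alpha.between(0.0, prep.PT_COEFF).all()


def _normals(frame, **overrides):
    clim = frame.climatology()
    for k, v in overrides.items():
        clim[k] = v
    return clim


class TestElevationCorrect:
    def test_identical_normals_is_identity(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        clim = f.climatology()
        out = prep.elevation_correct(f, clim, clim)
        pd.testing.assert_frame_equal(out.data, f.data, check_exact=False, atol=1e-9)

    def test_cooler_fine_normals_shift_temperature(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        coarse = f.climatology()
        fine = coarse.copy()
        fine["tmp"] -= 3.0
        out = prep.elevation_correct(f, coarse, fine)
        np.testing.assert_allclose(out.data["tmp"], f.data["tmp"] - 3.0)

    def test_precipitation_ratio_applies_per_month(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        coarse = f.climatology()
        fine = coarse.copy()
        fine.loc[1, "pre"] = coarse.loc[1, "pre"] * 1.5
        out = prep.elevation_correct(f, coarse, fine)
        jan = out.data["pre"].xs(1, level="month")
        np.testing.assert_allclose(jan, f.data["pre"].xs(1, level="month") * 1.5)

    def test_zero_coarse_normal_falls_back_to_additive(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        f.data.loc[pd.IndexSlice[:, 7], "pre"] = 0.0
        coarse = f.climatology()
        assert coarse.loc[7, "pre"] == 0.0
        fine = coarse.copy()
        fine.loc[7, "pre"] = 10.0
        out = prep.elevation_correct(f, coarse, fine)
        np.testing.assert_allclose(out.data["pre"].xs(7, level="month"), 10.0)


class TestBiasCorrectLGM:
    def test_matching_normals_is_identity(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        clim = f.climatology()
        out = prep.bias_correct_lgm(f, clim, clim)
        pd.testing.assert_frame_equal(out.data, f.data, check_exact=False, atol=1e-9)

    def test_warm_bias_cools_the_corrected_series(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=3, seed=1))
        modern = f.climatology()
        picontrol = modern.copy()
        picontrol.loc[7, "tmp"] += 2.0  # control run 2 C too warm in July
        out = prep.bias_correct_lgm(f, picontrol, modern)
        julys = out.data["tmp"].xs(7, level="month")
        np.testing.assert_allclose(julys, f.data["tmp"].xs(7, level="month") - 2.0)

    def test_correction_shifts_climatology_by_exactly_the_bias(self):
        f = synthetic.generate_monthly_climate(SyntheticClimateConfig(n_years=5, seed=3))
        modern = f.climatology() + 1.7
        picontrol = f.climatology() - 0.4
        out = prep.bias_correct_lgm(f, picontrol, modern)
        delta = out.climatology(["tmp"]) - f.climatology(["tmp"])
        np.testing.assert_allclose(delta["tmp"], (modern - picontrol)["tmp"], atol=1e-9)


class TestGrowingSeason:
    def test_threshold_is_strict(self):
        flags = prep.growing_season_mask([10.0, -1.0, -0.9, -5.0])
        assert flags.tolist() == [True, False, True, False]


class TestAccumulationWindow:
    @staticmethod
    def _series(first_year=1903, n_years=10):
        idx = pd.MultiIndex.from_product(
            [range(first_year, first_year + n_years), range(1, 13)],
            names=["year", "month"])
        return pd.Series([y * 100 + m for y, m in idx], index=idx, dtype=float)

    def test_constant_series_annualizes_to_12v(self):
        s = self._series()
        s[:] = 3.0
        assert prep.accumulation_window(s, 1950 - 45, mode="sum") == pytest.approx(36.0)

    def test_window_spans_exact_months(self):
        s = self._series(first_year=1948)
        got = prep.accumulation_window(s, 1950, mode="sum")
        months = [(1948, m) for m in range(7, 13)] + \
                 [(1949, m) for m in range(1, 13)] + [(1950, m) for m in range(1, 7)]
        expected = sum(y * 100 + m for y, m in months) / 2.0
        assert got == pytest.approx(expected)

    def test_first_reportable_ring_year(self):
        s = self._series(first_year=1903)
        assert prep.available_ring_years(s.index)[0] == 1905
        with pytest.raises(KeyError):
            prep.accumulation_window(s, 1904)

    def test_mean_mode(self):
        s = self._series()
        s[:] = 7.0
        assert prep.accumulation_window(s, 1906, mode="mean") == pytest.approx(7.0)


class TestPrepareForcing:
    def test_all_derived_drivers_finite(self, montane_forcing):
        d = montane_forcing.data
        assert np.isfinite(d[["vpd", "par", "alpha"]].to_numpy()).all()
        assert (d["vpd"] >= 0).all()
        assert d["alpha"].between(0, prep.PT_COEFF).all()
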