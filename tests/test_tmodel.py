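"""T-model: geometry, pools, carbon budget, the growth solver and rings."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from ptgrowth import tmodel
from ptgrowth.tmodel import SpeciesParams, biomass_pools


@pytest.fixture
def params():
    return SpeciesParams()


class TestGeometry:
    def test_height_zero_at_zero_diameter(self, params):
        assert tmodel.height_from_diameter(0.0, params) == 0.0

    def test_height_asymptote(self, params):
        assert tmodel.height_from_diameter(1e3, params) == pytest.approx(params.h_max)

    def test_height_initial_slope(self, params):
        d = 1e-5  # a*d/h_max ~ 5e-5, deep in the linear regime
        assert tmodel.height_from_diameter(d, params) == pytest.approx(params.a * d, rel=1e-2)

    def test_crown_area_zero_at_zero_diameter(self, params):
        assert tmodel.crown_area(0.0, 0.0, params) == 0.0

    def test_crown_initial_ratio(self, params):
        d = 1e-5
        h = tmodel.height_from_diameter(d, params)
        ac = tmodel.crown_area(d, h, params)
        stem_section = np.pi * d * d / 4.0
        assert ac / stem_section == pytest.approx(params.c_ratio, rel=1e-2)

    def test_crown_linear_in_c_ratio(self, params):
        h = tmodel.height_from_diameter(0.2, params)
        a1 = tmodel.crown_area(0.2, h, params)
        a2 = tmodel.crown_area(0.2, h, params.with_(c_ratio=2 * params.c_ratio))
        assert a2 == pytest.approx(2 * a1)


class TestBiomassPools:
    def test_stem_mass_hand_value(self):
        # paraboloid form factor 1/2: W = (pi/8) rho d^2 H = 72.5 kg C
        # for d = 0.3 m, H = 10 m, rho = 205 kg C m-3
        assert (np.pi / 8) * 205.0 * 0.3**2 * 10.0 == pytest.approx(72.47, abs=0.05)
        p = SpeciesParams()
        state = biomass_pools(0.3, p)
        h = tmodel.height_from_diameter(0.3, p)
        assert state.w_stem == pytest.approx((np.pi / 8) * p.rho_s * 0.09 * h)

    def test_vanishing_lai_empties_foliage_and_roots(self, params):
        state = biomass_pools(0.3, params.with_(lai=1e-12))
        assert state.w_foliage == pytest.approx(0.0, abs=1e-9)
        assert state.w_root == pytest.approx(0.0, abs=1e-9)

    def test_zeta_scales_roots_only(self, params):
        s1 = biomass_pools(0.3, params)
        s2 = biomass_pools(0.3, params.with_(zeta=2 * params.zeta))
        assert s2.w_root == pytest.approx(2 * s1.w_root)
        assert s2.w_stem == s1.w_stem and s2.w_foliage == s1.w_foliage


class TestFapar:
    def test_zero_lai(self):
        assert tmodel.fapar(0.0, 0.5) == 0.0

    def test_beer_law_value(self):
        assert tmodel.fapar(2.0, 0.5) == pytest.approx(1 - np.exp(-1.0))

    def test_always_below_one(self):
        assert tmodel.fapar(20.0, 0.5) < 1.0


class TestNPP:
    def test_zero_gpp_gives_zero(self, params):
        state = biomass_pools(0.3, params)
        assert tmodel.npp_annual(0.0, state, params) == 0.0

    def test_ideal_efficiency_returns_gross_uptake(self, params):
        p = params.with_(yield_=1.0, r_s=1e-12, r_r=1e-12, foliage_resp_frac=0.0)
        state = biomass_pools(0.3, p)
        p_tree = 4.0 * tmodel.fapar(p.lai, p.k_ext) * state.crown_area
        assert tmodel.npp_annual(4.0, state, p) == pytest.approx(p_tree)

    def test_decreasing_in_respiration_rates(self, params):
        state = biomass_pools(0.3, params)
        base = tmodel.npp_annual(4.0, state, params)
        p_rs = params.with_(r_s=params.r_s * 2)
        p_rr = params.with_(r_r=params.r_r * 2)
        assert tmodel.npp_annual(4.0, biomass_pools(0.3, p_rs), p_rs) < base
        assert tmodel.npp_annual(4.0, biomass_pools(0.3, p_rr), p_rr) < base


class TestDiameterIncrement:
    def test_zero_when_npp_equals_turnover(self, params):
        state = biomass_pools(0.3, params)
        turnover = state.w_foliage / params.tau_f + state.w_root / params.tau_r
        assert tmodel.diameter_increment(turnover, state, params) == 0.0

    @pytest.mark.parametrize("d,npp_scale", [(0.2, 1.2), (0.3, 1.5), (0.5, 2.0)])
    def test_matches_bisection_oracle_within_1pct(self, params, d, npp_scale):
        """The analytic-start Newton solver against an independent bisection
        root of the exact finite mass balance W(d+Dd) - W(d) + turnover = NPP."""
        state = biomass_pools(d, params)
        turnover = state.w_foliage / params.tau_f + state.w_root / params.tau_r
        npp = turnover * npp_scale

        def total_mass(x):
            s = biomass_pools(x, params)
            return s.w_stem + s.w_foliage + s.w_root

        def residual(dd):
            return total_mass(d + dd) - total_mass(d) + turnover - npp

        oracle = brentq(residual, 0.0, 0.5 * d)
        got = tmodel.diameter_increment(npp, state, params)
        assert got / d < 0.05  # inside the linearization regime
        assert got == pytest.approx(oracle, rel=0.01)

    def test_monotone_in_npp_above_turnover(self, params):
        state = biomass_pools(0.3, params)
        turnover = state.w_foliage / params.tau_f + state.w_root / params.tau_r
        npps = np.linspace(turnover * 1.05, turnover * 3.0, 20)
        dds = [tmodel.diameter_increment(n, state, params) for n in npps]
        assert (np.diff(dds) > 0).all()
        # below turnover the increment is floored at zero
        assert tmodel.diameter_increment(turnover * 0.5, state, params) == 0.0


class TestAllocationFractions:
    def test_fractions_sum_to_one(self, params):
        state = biomass_pools(0.3, params)
        npp = 10.0
        dd = tmodel.diameter_increment(npp, state, params)
        frac = tmodel.allocation_fractions(npp, state, dd, params)
        assert frac["foliage"] + frac["root"] + frac["stem"] == pytest.approx(1.0, abs=1e-9)

    def test_higher_zeta_raises_root_fraction(self, params):
        fracs = []
        for zeta in (0.3, 0.6, 0.9):
            p = params.with_(zeta=zeta)
            state = biomass_pools(0.3, p)
            npp = 10.0
            dd = tmodel.diameter_increment(npp, state, p)
            fracs.append(tmodel.allocation_fractions(npp, state, dd, p)["root"])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_undefined_at_zero_npp(self, params):
        state = biomass_pools(0.3, params)
        frac = tmodel.allocation_fractions(0.0, state, 0.0, params)
        assert all(np.isnan(v) for v in frac.values())


class TestSimulateRings:
    def test_zero_gpp_gives_zero_widths(self, params):
        gpp = pd.Series(0.0, index=range(1905, 1930))
        rings = tmodel.simulate_rings(gpp, params)
        assert (rings.widths == 0).all()

    def test_carbon_balance_closes_each_year(self, gpp_annual, species):
        rings, budget = tmodel.simulate_rings(gpp_annual, species, record_budget=True)
        active = budget[~budget["floored"]]
        assert len(active) > 0
        np.testing.assert_allclose(active["npp"],
                                   active["increment"] + active["turnover"],
                                   rtol=1e-6)

    def test_cumulative_widths_equal_diameter_change(self, gpp_annual, species):
        rings = tmodel.simulate_rings(gpp_annual, species)
        total_mm = 2.0 * rings.widths.sum()
        assert total_mm == pytest.approx(
            (rings.meta["d_final"] - rings.meta["d0"]) * 1000.0, rel=1e-12)

    def test_doubling_co2_widens_every_ring(self, montane_forcing, species):
        import ptgrowth.synthetic as syn

        low = montane_forcing.copy()
        low.co2 = syn.generate_co2_series(low.years, "constant", 200.0)
        high = montane_forcing.copy()
        high.co2 = syn.generate_co2_series(high.years, "constant", 400.0)
        w_low = tmodel.simulate_growth(low, species).widths
        w_high = tmodel.simulate_growth(high, species).widths
        assert (w_high.to_numpy() > w_low.to_numpy()).all()

    def test_constant_climatology_rings_smooth_and_bounded(self, species):
        """Under a repeated climatology rings stay non-negative, vary smoothly
        and level off as the geometry approaches self-similar growth."""
        import ptgrowth.prep as prep
        import ptgrowth.synthetic as syn

        cfg = syn.SyntheticClimateConfig(n_years=120, seed=2, noise_sd_temp=0.0,
                                         noise_sd_precip_lognormal=0.0)
        f = syn.generate_monthly_climate(cfg)
        f.co2 = syn.generate_co2_series(f.years, "constant", 320.0)
        w = tmodel.simulate_growth(prep.prepare_forcing(f), species).widths.to_numpy()
        assert (w >= 0).all()
        rel_step = np.abs(np.diff(w)) / w[:-1].clip(min=1e-9)
        assert rel_step.max() < 0.05  # smooth year-to-year
        late = np.abs(np.diff(w[-20:])).mean()
        early = np.abs(np.diff(w[:20])).mean()
        assert late < early  # approaching the plateau

    def test_short_forcing_yields_empty_series(self, species):
        gpp = pd.Series(dtype=float)
        rings = tmodel.simulate_rings(gpp, species)
        assert len(rings.widths) == 0


class TestSpeciesParamsValidation:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            SpeciesParams(zeta=-0.1)

    def test_yield_above_one_rejected(self):
        with pytest.raises(ValueError):
            SpeciesParams(yield_=1.2)
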