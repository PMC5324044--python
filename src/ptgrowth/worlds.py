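"""The two synthetic stated worlds the analyses and tests run on.

``montane_world`` emulates a high-elevation dry-summer conifer site in the
southern Sierra Nevada (the kind of site that anchors modern validation and
calibration: 36.95 N, 2630 m, MAT 7.5 C, 600 mm of winter-dominated
precipitation, 1903-1985 with a 296->339 ppm CO2 ramp).

``lowland_pair`` emulates a warm low-elevation coastal-plain site
(34.06 N, 80 m, MAT 16.6 C, 380 mm) and its glacial counterpart built by the
mid-range glacial anomaly (-4 C, +200 mm/yr, +0.05 RH) with CO2 fixed at
180 ppm; the modern member runs at the 20th-century reference 320 ppm.
"""

from __future__ import annotations

from . import prep, synthetic
from .types import ForcingSeries, SiteMeta

LOWLAND_SITE = SiteMeta(34.06, -118.36, 80.0, name="lowland")


def montane_world(seed: int = 1, prepared: bool = True) -> ForcingSeries:
    cfg = synthetic.SyntheticClimateConfig(seed=seed)
    forcing = synthetic.generate_monthly_climate(cfg)
    forcing.co2 = synthetic.generate_co2_series(forcing.years, "ramp", (296.0, 339.0))
    return prep.prepare_forcing(forcing) if prepared else forcing


def lowland_pair(seed: int = 1, prepared: bool = True) -> tuple[ForcingSeries, ForcingSeries]:
    cfg = synthetic.SyntheticClimateConfig(
        seed=seed, mean_annual_temp=16.6, seasonal_amplitude=7.0,
        annual_precip=380.0, precip_winter_fraction=0.85,
        mean_relative_humidity=0.6, cloud_fraction=0.3)
    modern = synthetic.generate_monthly_climate(cfg, LOWLAND_SITE)
    modern.co2 = synthetic.generate_co2_series(modern.years, "constant", 320.0)
    glacial = synthetic.apply_anomalies(modern, synthetic.AnomalyConfig())
    glacial.co2 = synthetic.generate_co2_series(glacial.years, "constant", 180.0)
    if prepared:
        return prep.prepare_forcing(modern), prep.prepare_forcing(glacial)
    return modern, glacial


__all__ = ["LOWLAND_SITE", "montane_world", "lowland_pair"]
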