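#!/usr/bin/env python
"""Generate the synthetic forcing worlds and truth-known ring series.

Writes the montane modern forcing (1903-1985, CO2 ramp 296->339 ppm), the
lowland modern/glacial pair (320 vs 180 ppm; glacial = -4 C, +200 mm/yr,
+0.05 RH) and a noisy "observed" ring file, all in the package's text
dialects, under results/.
"""

from pathlib import Path

from ptgrowth import io, synthetic, tmodel, worlds

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    prov = {"seed": SEED, "script": "01_synthesize_forcing"}

    montane = worlds.montane_world(seed=SEED, prepared=False)
    io.write_climate_table(montane, OUT / "forcing_montane_modern.txt", prov)
    io.write_co2_table(montane.co2, OUT / "co2_montane_modern.txt", prov)

    modern, glacial = worlds.lowland_pair(seed=SEED, prepared=False)
    io.write_climate_table(modern, OUT / "forcing_lowland_modern.txt", prov)
    io.write_climate_table(glacial, OUT / "forcing_lowland_glacial.txt", prov)
    io.write_co2_table(glacial.co2, OUT / "co2_lowland_glacial.txt", prov)

    prepared = worlds.montane_world(seed=SEED)
    rings = synthetic.generate_synthetic_rings(
        tmodel.SpeciesParams(), prepared, obs_noise_sd=0.3, seed=SEED)
    io.write_rwl(rings, OUT / "rings_montane_observed.rwl",
                 series_id="SYN001", header=f"synthetic observations seed={SEED}")

    print(f"montane modern: {montane.n_years} years, "
          f"mean T {montane.data['tmp'].mean():.1f} C, "
          f"annual precip {montane.data['pre'].groupby(level='year').sum().mean():.0f} mm")
    print(f"lowland glacial anomaly check: "
          f"dT = {glacial.data['tmp'].mean() - modern.data['tmp'].mean():+.2f} C, "
          f"dP = {(glacial.data['pre'].groupby(level='year').sum().mean() - modern.data['pre'].groupby(level='year').sum().mean()):+.0f} mm/yr")
    print(f"synthetic observed rings: {len(rings.widths)} years, "
          f"mean {rings.mean_width():.3f} mm -> {OUT}")


if __name__ == "__main__":
    main()
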