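#!/usr/bin/env python
"""Which glacial climate changes propped up growth? Variable substitution.

Holding CO2 at 180 ppm and the allocation parameters at their LGM-optimized
values, each experiment replaces one glacial variable (or a combination) by
its modern monthly values: H = relative humidity, P = precipitation,
T = temperature, plus TP, TPH and Full.  Ring-width changes relative to the
glacial baseline show that the cool, wet glacial climate was essential to
maintaining growth at low CO2: imposing the warmer, drier modern climate
collapses simulated rings.
"""

from pathlib import Path

from ptgrowth import abc, experiments, tmodel, worlds

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
TARGET_RW = 1.83


def main() -> None:
    OUT.mkdir(exist_ok=True)
    modern, glacial = worlds.lowland_pair(seed=SEED, prepared=False)
    modern_prep, glacial_prep = worlds.lowland_pair(seed=SEED)

    # LGM allocation: ABC at 180 ppm reproducing the target ring width
    lai, zeta, _ = abc.optimize_allocation(
        glacial_prep, 180.0, TARGET_RW, tmodel.SpeciesParams(),
        abc.ABCConfig(n_draws=1500, seed=SEED))
    lgm_params = tmodel.SpeciesParams().with_(lai=lai, zeta=zeta)
    print(f"LGM-optimized allocation: L = {lai:.3f}, zeta = {zeta:.4f}")

    table = experiments.run_climate_substitution(glacial, modern, lgm_params)
    table.to_csv(OUT / "climate_substitution.csv")
    print("ring-width response to substituting modern climate variables "
          "(CO2 held at 180 ppm):")
    for name, row in table.iterrows():
        print(f"  {name:>8}: {row['mean_rw_mm']:.3f} mm ({row['pct_change']:+.1f}%)")
    print("  -> modern temperature alone, and especially the full modern "
          "climate, sharply reduce glacial-CO2 growth")


if __name__ == "__main__":
    main()
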