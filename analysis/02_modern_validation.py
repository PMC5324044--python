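#!/usr/bin/env python
"""Modern validation and the accumulation-window diagnostic.

Simulates annual ring widths at the montane site, compares them with the
noisy synthetic "observations" (mean width, interannual and decadal
correlations), and scans 12/24/36-month climate-accumulation windows to
confirm that the 24-month window best explains ring variance.
"""

from pathlib import Path

import pandas as pd

from ptgrowth import experiments, io, synthetic, tmodel, worlds

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    forcing = worlds.montane_world(seed=SEED)
    params = tmodel.SpeciesParams()
    observed = synthetic.generate_synthetic_rings(params, forcing,
                                                  obs_noise_sd=0.3, seed=SEED)

    report = experiments.run_modern_validation(forcing, observed, params)
    table = pd.DataFrame([{k: v for k, v in report.items() if k != "simulated"}])
    table.to_csv(OUT / "modern_validation.csv", index=False)
    print("modern validation (simulated vs noisy truth-known observations):")
    print(f"  mean width: simulated {report['mean_simulated_mm']:.3f} mm vs "
          f"observed {report['mean_observed_mm']:.3f} mm over {report['n_years']} years")
    print(f"  interannual r = {report['r_annual']:.2f}; "
          f"10-yr smoothed r = {report['r_smoothed']:.2f}")

    windows = experiments.accumulation_window_regression(observed, forcing,
                                                         windows=(12, 24, 36))
    windows.to_csv(OUT / "window_scan.csv")
    best = windows["r2"].idxmax()
    print("accumulation-window scan (OLS of ring width on PAR/MAT/alpha/VPD/CO2):")
    for w, row in windows.iterrows():
        print(f"  {w:>2}-month window: R^2 = {row['r2']:.3f}")
    print(f"  -> the {best}-month window explains ring variance best, as the "
          f"2-year carbon-accumulation treatment assumes")


if __name__ == "__main__":
    main()
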