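"""Survivorship, cumulative hazard and the Gompertz slope of the cohort."""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import json

import pandas as pd

from mpsr.survival import gompertz_slope, survival_curves

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    lifespans = pd.read_csv(ROOT / "lifespans.csv")
    curve = survival_curves(lifespans["lifespan_h"], lifespans["censored"],
                            n_boot=1000, seed=2)
    curve.to_frame().to_csv(ROOT / "survival.csv", index=False)
    slope, ci = gompertz_slope(curve, n_boot=500, seed=2)
    out = {
        "lifespan_mean_h": curve.lifespan_mean,
        "lifespan_cv": curve.lifespan_cv,
        "quantiles_h": curve.quantiles,
        "gompertz_slope_per_h": slope,
        "gompertz_slope_ci": ci,
    }
    with open(ROOT / "gompertz.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"mean lifespan {curve.lifespan_mean:.1f} h "
          f"(CV {curve.lifespan_cv:.2f}); 5%/50%/95% quantiles "
          f"{curve.quantiles[0.05]:.0f}/{curve.quantiles[0.5]:.0f}/"
          f"{curve.quantiles[0.95]:.0f} h")
    print(f"Gompertz slope {slope:.3f} /h (95% CI {ci[0]:.3f}-{ci[1]:.3f}): "
          "the cumulative risk of death rises exponentially with age")


if __name__ == "__main__":
    main()
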