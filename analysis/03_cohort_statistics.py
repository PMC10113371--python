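"""Cross-sectional damage statistics and initial-condition analysis.

Computes per-age mean/SD/CV/skewness of the uptake rate with bootstrap
errors, the 7 h damage autocorrelation, the remaining-lifespan alignment,
the twilight regression, and the lifespan-vs-initial-conditions report
(correlations, group split at uptake 4, multiple-regression R^2).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import json

import numpy as np
import pandas as pd

from mpsr.cohort_stats import (
    autocorrelation,
    cross_sectional_stats,
    initial_condition_analysis,
    remaining_lifespan_view,
    twilight,
)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    windows = pd.read_csv(ROOT / "windows.csv")
    lifespans = pd.read_csv(ROOT / "lifespans.csv")
    covariates = pd.read_csv(ROOT / "cohort" / "covariates.csv")

    ages = sorted(windows["window_center_h"].unique())[:9]
    rows = []
    for age in ages:
        try:
            (sec,) = cross_sectional_stats(windows, lifespans, [age],
                                           "uptake", n_boot=1000, seed=1)
        except ValueError:
            continue
        rows.extend(sec.to_rows())
    stats = pd.DataFrame(rows)
    stats.to_csv(ROOT / "cross_sections.csv", index=False)
    cv = stats[stats["stat"] == "cv"].set_index("age_h")["estimate"]
    print("CV of uptake by age (falls with age = increasing determinism):")
    print("  " + "  ".join(f"{a:.0f}h:{v:.2f}" for a, v in cv.items()))

    ac = []
    for age in ages[:-1]:
        try:
            r, se, n = autocorrelation(windows, lifespans, age, 7.0,
                                       n_boot=1000, seed=1)
            ac.append({"age_h": age, "r": r, "se": se, "n_pairs": n})
        except ValueError:
            pass
    pd.DataFrame(ac).to_csv(ROOT / "autocorrelation.csv", index=False)
    if len(ac) >= 2:
        print(f"autocorrelation (lag 7 h): {ac[0]['r']:.2f} at "
              f"{ac[0]['age_h']:.0f} h -> {ac[-1]['r']:.2f} at "
              f"{ac[-1]['age_h']:.0f} h")

    view = remaining_lifespan_view(windows, lifespans)
    view.to_csv(ROOT / "remaining_lifespan.csv", index=False)

    # twilight from the windowed damage estimates of dead cells
    dead = lifespans[~lifespans["censored"]]
    series, deaths = [], []
    for cid, grp in windows[windows["valid"]].groupby("cell_id"):
        row = dead[dead["cell_id"] == cid]
        if row.empty:
            continue
        grp = grp.sort_values("window_center_h")
        series.append((grp["window_center_h"].to_numpy(),
                       grp["damage_kBT"].to_numpy()))
        deaths.append(float(row["lifespan_h"].iloc[0]))
    tw = twilight(series, np.array(deaths), threshold_x=2.0, seed=1)
    tw["table"].to_csv(ROOT / "twilight.csv", index=False)
    print(f"twilight slope {tw['slope']:.2f} h/h "
          f"(95% CI {tw['ci'][0]:.2f} to {tw['ci'][1]:.2f}, "
          f"n={tw['n']}; negative = twilight shortens with age)")

    # initial conditions: first valid window's uptake per cell
    first = (windows[windows["valid"]]
             .sort_values("window_center_h")
             .groupby("cell_id").first().reset_index())
    init = first[["cell_id", "uptake"]].rename(
        columns={"uptake": "initial_uptake"})
    rep = initial_condition_analysis(lifespans, init, covariates)
    report = {
        "spearman": {k: {"r": v[0], "n": v[1], "p": v[2]}
                     for k, v in rep.spearman.items()},
        "r_high": rep.r_high, "r_low": rep.r_low,
        "regression_r2_all": rep.regression_r2_all,
        "regression_r2_low": rep.regression_r2_low,
    }
    with open(ROOT / "initial_conditions.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"initial damage vs lifespan: Spearman r = "
          f"{rep.spearman['initial_uptake'][0]:.2f}; regression R^2 "
          f"all/low-damage = {rep.regression_r2_all:.2f}/"
          f"{rep.regression_r2_low:.2f}")


if __name__ == "__main__":
    main()
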