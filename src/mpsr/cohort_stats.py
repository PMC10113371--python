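"""Cross-sectional cohort statistics of damage, and initial-condition analysis.

All functions operate on the tidy tables produced by the extraction module
(or on simulated ensembles converted with :func:`windows_from_ensemble`):

* ``windows``:  cell_id, window_center_h, uptake, damage_kBT, valid
* ``lifespans``: cell_id, lifespan_h, censored

The per-age population is "all cells alive at that age": called lifespan
greater than the age and a valid window there.  Error bars are bootstrap
standard errors resampling cells, not windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossSection",
    "InitialConditionReport",
    "windows_from_ensemble",
    "cross_sectional_stats",
    "autocorrelation",
    "initial_condition_analysis",
    "remaining_lifespan_view",
    "twilight",
]

STAT_NAMES = ("mean", "sd", "cv", "skewness")


@dataclass
class CrossSection:
    """Damage statistics among cells alive at one age, with bootstrap SEs."""

    age_h: float
    n_alive: int
    stats: dict  # stat name -> (estimate, bootstrap_se)

    def to_rows(self):
        return [
            {"age_h": self.age_h, "stat": k, "estimate": v[0],
             "bootstrap_se": v[1], "n_alive": self.n_alive}
            for k, v in self.stats.items()
        ]


@dataclass
class InitialConditionReport:
    """Lifespan vs initial-condition analysis: correlations and regression R^2."""

    spearman: dict            # label -> (r, n, p)
    group_split_threshold: float
    r_high: tuple             # (r, n, p) for initial uptake > split
    r_low: tuple
    regression_r2_all: float
    regression_r2_low: float
    n_all: int = 0
    warnings: list = field(default_factory=list)


def windows_from_ensemble(ens, ages, rule=None):
    """Convert a simulated :class:`~mpsr.simulate.TrajectoryEnsemble` into the
    tidy (windows, lifespans) tables, sampling damage at the grid times
    nearest each requested age.

    If the ensemble was run with an absorbing rule, crossing times become
    lifespans; cells that never crossed are censored at the last grid time.
    """
    ages = np.asarray(ages, dtype=float)
    n = ens.n_cells
    horizon = float(ens.times[-1])
    rows = []
    for age in ages:
        x = ens.at_age(age)
        rows.append(pd.DataFrame({
            "cell_id": np.arange(n), "window_center_h": age,
            "uptake": np.exp(x), "damage_kBT": x,
            "valid": np.isfinite(x),
        }))
    windows = pd.concat(rows, ignore_index=True)
    if ens.crossing_times is not None:
        ct = ens.crossing_times
        dead = np.isfinite(ct)
        lifespans = pd.DataFrame({
            "cell_id": np.arange(n),
            "lifespan_h": np.where(dead, ct, horizon),
            "censored": ~dead,
        })
    else:
        lifespans = pd.DataFrame({
            "cell_id": np.arange(n),
            "lifespan_h": np.full(n, horizon),
            "censored": np.ones(n, dtype=bool),
        })
    return windows, lifespans


def _sample_stats(values: np.ndarray) -> dict:
    mean = float(np.mean(values))
    if values.size < 2:
        raise ValueError("need >= 2 values for dispersion statistics")
    sd = float(np.std(values, ddof=1))
    cv = sd / mean if mean != 0 else np.nan
    # adjusted Fisher--Pearson sample skewness; 0 for degenerate samples
    skw = float(stats.skew(values, bias=False)) if sd > 0 else 0.0
    return {"mean": mean, "sd": sd, "cv": cv, "skewness": skw}


def _alive_values(windows, lifespans, age, observable):
    col = "uptake" if observable == "uptake" else "damage_kBT"
    w = windows[(windows["window_center_h"] == age) & windows["valid"]]
    merged = w.merge(lifespans, on="cell_id")
    alive = merged[merged["lifespan_h"] > age]
    return alive["cell_id"].to_numpy(), alive[col].to_numpy()


def cross_sectional_stats(
    windows: pd.DataFrame,
    lifespans: pd.DataFrame,
    ages,
    observable: str = "uptake",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[CrossSection]:
    """Mean, SD, CV and skewness of the damage observable per age.

    ``observable`` is "uptake" (e^X, the display convention for mean/SD/CV/
    skewness panels) or "damage" (X itself).  Bootstrap resamples cells.
    """
    if observable not in ("uptake", "damage"):
        raise ValueError("observable must be 'uptake' or 'damage'")
    known_ages = set(windows["window_center_h"].unique())
    rng = np.random.default_rng(seed)
    out = []
    for age in np.atleast_1d(ages):
        if age not in known_ages:
            raise ValueError(f"age {age} is not on the window grid")
        _, vals = _alive_values(windows, lifespans, age, observable)
        if vals.size < 2:
            raise ValueError(f"fewer than 2 alive cells at age {age}")
        if observable == "uptake" and np.mean(vals) <= 0:
            raise ValueError("uptake mean must be positive for CV")
        est = _sample_stats(vals)
        boots = {k: np.empty(n_boot) for k in STAT_NAMES}
        for b in range(n_boot):
            res = vals[rng.integers(0, vals.size, vals.size)]
            if np.std(res) == 0:
                bs = {"mean": float(np.mean(res)), "sd": 0.0, "cv": 0.0,
                      "skewness": 0.0}
            else:
                bs = _sample_stats(res)
            for k in STAT_NAMES:
                boots[k][b] = bs[k]
        out.append(CrossSection(
            age_h=float(age), n_alive=int(vals.size),
            stats={k: (est[k], float(np.nanstd(boots[k], ddof=1)))
                   for k in STAT_NAMES},
        ))
    return out


def autocorrelation(
    windows: pd.DataFrame,
    lifespans: pd.DataFrame,
    age: float,
    lag_h: float = 7.0,
    observable: str = "damage",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Pearson correlation of the damage observable between ``age`` and
    ``age + lag_h`` over cells alive and valid at both ages.

    Returns ``(r, bootstrap_se, n_pairs)``.
    """
    ids1, v1 = _alive_values(windows, lifespans, age, observable)
    ids2, v2 = _alive_values(windows, lifespans, age + lag_h, observable)
    s1 = pd.Series(v1, index=ids1)
    s2 = pd.Series(v2, index=ids2)
    shared = s1.index.intersection(s2.index)
    if shared.size < 3:
        raise ValueError(f"fewer than 3 cells shared between ages {age} and "
                         f"{age + lag_h}")
    x, y = s1[shared].to_numpy(), s2[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r = 1.0 if np.std(x) == 0 and np.std(y) == 0 else np.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        xb, yb = x[idx], y[idx]
        boots[b] = (np.corrcoef(xb, yb)[0, 1]
                    if np.std(xb) > 0 and np.std(yb) > 0 else np.nan)
    return r, float(np.nanstd(boots, ddof=1)), int(shared.size)


def initial_condition_analysis(
    lifespans: pd.DataFrame,
    initial_uptake: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    split: float = 4.0,
) -> InitialConditionReport:
    """Do initial conditions explain lifespan?  Correlations and regression.

    ``initial_uptake`` needs columns cell_id, initial_uptake.  ``covariates``
    (optional) needs cell_id, initial_size_um, division_times_h
    (semicolon-joined), n_divisions.  Spearman uses average ranks for ties;
    missing covariate values are dropped pairwise with counts reported.
    The multiple regression is OLS of lifespan on all initial conditions,
    reported as R^2 for all cells and for the low-initial-damage group.
    """
    import statsmodels.api as sm

    df = lifespans.merge(initial_uptake, on="cell_id")
    df = df[~df["censored"]]
    if len(df) < 10:
        raise ValueError("need >= 10 uncensored cells")
    warnings_list = []

    def _last_division(s):
        if isinstance(s, str) and s.strip():
            return float(s.split(";")[-1])
        return np.nan

    if covariates is not None:
        cov = covariates.copy()
        cov["last_division_h"] = cov["division_times_h"].map(_last_division)
        df = df.merge(
            cov[["cell_id", "initial_size_um", "last_division_h", "n_divisions"]],
            on="cell_id", how="left",
        )

    spearman = {}
    labels = ["initial_uptake"]
    if covariates is not None:
        labels += ["initial_size_um", "last_division_h", "n_divisions"]
    for lab in labels:
        sub = df[["lifespan_h", lab]].dropna()
        if len(sub) >= 3 and sub[lab].nunique() > 1:
            r, p = stats.spearmanr(sub[lab], sub["lifespan_h"])
            spearman[lab] = (float(r), int(len(sub)), float(p))
        else:
            spearman[lab] = (np.nan, int(len(sub)), np.nan)
            warnings_list.append(f"degenerate or missing covariate {lab!r}")

    hi = df[df["initial_uptake"] > split]
    lo = df[df["initial_uptake"] <= split]

    def _grp(sub):
        if len(sub) >= 3 and sub["initial_uptake"].nunique() > 1:
            r, p = stats.spearmanr(sub["initial_uptake"], sub["lifespan_h"])
            return (float(r), int(len(sub)), float(p))
        return (np.nan, int(len(sub)), np.nan)

    def _r2(sub):
        cols = [c for c in ["initial_uptake", "initial_size_um",
                            "last_division_h", "n_divisions"] if c in sub]
        data = sub[["lifespan_h"] + cols].dropna()
        use = [c for c in cols if data[c].nunique() > 1]
        dropped = set(cols) - set(use)
        if dropped:
            warnings_list.append(f"dropped constant regressors {sorted(dropped)}")
        if not use or len(data) <= len(use) + 1:
            return np.nan
        model = sm.OLS(data["lifespan_h"], sm.add_constant(data[use])).fit()
        return float(model.rsquared)

    return InitialConditionReport(
        spearman=spearman,
        group_split_threshold=split,
        r_high=_grp(hi),
        r_low=_grp(lo),
        regression_r2_all=_r2(df),
        regression_r2_low=_r2(lo),
        n_all=int(len(df)),
        warnings=warnings_list,
    )


def remaining_lifespan_view(
    windows: pd.DataFrame,
    lifespans: pd.DataFrame,
    observable: str = "damage",
    bin_h: float = 7.0,
) -> pd.DataFrame:
    """Align dead cells on their death time and report dispersion of damage.

    Returns one row per remaining-lifespan bin: time_before_death_h (bin
    center), sd of the observable, mean, and n.  Damage converges as death
    approaches, so sd should fall towards zero remaining lifespan.
    """
    col = "uptake" if observable == "uptake" else "damage_kBT"
    dead = lifespans[~lifespans["censored"]]
    m = windows[windows["valid"]].merge(dead, on="cell_id")
    m = m[m["window_center_h"] < m["lifespan_h"]].copy()
    m["time_before_death_h"] = m["lifespan_h"] - m["window_center_h"]
    bins = np.arange(0, m["time_before_death_h"].max() + bin_h, bin_h)
    m["bin"] = pd.cut(m["time_before_death_h"], bins)
    rows = []
    for iv, grp in m.groupby("bin", observed=True):
        if len(grp) < 2:
            continue
        rows.append({
            "time_before_death_h": iv.mid,
            "sd": float(np.std(grp[col], ddof=1)),
            "mean": float(np.mean(grp[col])),
            "n": int(len(grp)),
        })
    return pd.DataFrame(rows).sort_values("time_before_death_h",
                                          ignore_index=True)


def _crossing_age(times, damage, threshold):
    """First time a (interpolated) damage series reaches ``threshold``."""
    ok = np.isfinite(damage)
    t, x = np.asarray(times)[ok], np.asarray(damage)[ok]
    if t.size == 0:
        return np.nan
    above = x >= threshold
    if not above.any():
        return np.nan
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    frac = (threshold - x[k - 1]) / (x[k] - x[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def twilight(
    damage_series: list,
    lifespans: np.ndarray,
    threshold_x: float,
    x_c: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Remaining lifespan after first crossing a sub-lethal damage threshold.

    ``damage_series`` is a list of ``(times, damage)`` pairs (dense latent
    paths or windowed estimates), ``lifespans`` the matching death times (NaN
    for censored cells, which are skipped).  Returns the per-cell table and
    the OLS slope of remaining lifespan vs crossing age with a bootstrap CI.
    A negative slope is the "shortening twilight" signature.
    """
    if x_c is not None and threshold_x >= x_c:
        raise ValueError("twilight threshold must be below the death threshold")
    rows = []
    for (t, x), life in zip(damage_series, np.asarray(lifespans, dtype=float)):
        if not np.isfinite(life):
            continue
        age = _crossing_age(t, x, threshold_x)
        if np.isfinite(age) and age < life:
            rows.append((age, life - age))
    if len(rows) < 10:
        raise ValueError("fewer than 10 cells cross the twilight threshold")
    tab = pd.DataFrame(rows, columns=["crossing_age_h", "remaining_lifespan_h"])
    x = tab["crossing_age_h"].to_numpy()
    y = tab["remaining_lifespan_h"].to_numpy()
    if np.var(x) == 0:
        slope, lo, hi = 0.0, 0.0, 0.0
    else:
        slope = float(np.polyfit(x, y, 1)[0])
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            boots[b] = (np.polyfit(x[idx], y[idx], 1)[0]
                        if np.var(x[idx]) > 0 else np.nan)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"table": tab, "slope": slope, "ci": (float(lo), float(hi)),
            "n": int(len(tab))}
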