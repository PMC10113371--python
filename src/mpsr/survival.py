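"""Survivorship, cumulative hazard, Gompertz slope, and cohort comparison.

The cumulative risk of death is the negative log of survivorship,
``H(t) = -ln S(t)``, the integral of the hazard.  A Gompertz process (hazard
``h0 * e^{g t}``) has ``H(t) = (h0/g)(e^{g t} - 1)``, so ``ln H`` is
asymptotically linear in age with slope ``g``; the Gompertz slope is
estimated as the OLS slope of ``ln H`` vs age inside the death regime.
Product-limit estimation is delegated to lifelines; confidence intervals are
percentile bootstrap over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["SurvivalCurve", "survival_curves", "gompertz_slope",
           "compare_cohorts"]


@dataclass
class SurvivalCurve:
    """Product-limit survivorship with bootstrap bands and lifespan summaries."""

    times_h: np.ndarray
    survival: np.ndarray
    cumulative_hazard: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    lifespan_mean: float
    lifespan_cv: float
    quantiles: dict            # 0.05 / 0.5 / 0.95 -> h
    lifespans: np.ndarray = field(repr=False, default=None)
    censored: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times_h, "S": self.survival,
            "cumhaz": self.cumulative_hazard,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_at_risk": self.n_at_risk,
        })


def _km(times, events, grid):
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return kmf.survival_function_at_times(grid).to_numpy()


def survival_curves(
    lifespans,
    censored=None,
    n_boot: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> SurvivalCurve:
    """Kaplan--Meier survivorship and cumulative hazard with bootstrap CIs.

    With no censoring this reduces to the empirical survival function.
    Summary statistics (mean, CV, quantiles) are computed on uncensored
    lifespans only.
    """
    times = np.asarray(lifespans, dtype=float)
    cens = (np.zeros(times.size, dtype=bool) if censored is None
            else np.asarray(censored, dtype=bool))
    events = ~cens
    if events.sum() < 10:
        raise ValueError("need >= 10 observed deaths")
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], times]))
    s = _km(times, events, grid)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, times.size, times.size)
        boots[b] = _km(times[idx], events[idx], grid)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    n_at_risk = np.array([(times >= t).sum() for t in grid])
    obs = times[events]
    with np.errstate(divide="ignore"):
        cumhaz = -np.log(s)
    return SurvivalCurve(
        times_h=grid, survival=s, cumulative_hazard=cumhaz,
        ci_low=lo, ci_high=hi, n_at_risk=n_at_risk,
        lifespan_mean=float(obs.mean()),
        lifespan_cv=float(obs.std(ddof=1) / obs.mean()),
        quantiles={q: float(np.quantile(obs, q)) for q in (0.05, 0.5, 0.95)},
        lifespans=times, censored=cens,
    )


def _lnH_slope(times, events, window):
    """OLS slope of ln cumulative hazard vs age on an hourly grid in window."""
    t0, t1 = window
    grid = np.arange(np.floor(t0), np.ceil(t1) + 1.0)
    s = _km(times, events, grid)
    with np.errstate(divide="ignore"):
        lnH = np.log(-np.log(s))
    ok = np.isfinite(lnH)
    if ok.sum() < 5:
        raise ValueError("fewer than 5 grid ages with events in the fit window")
    return float(np.polyfit(grid[ok], lnH[ok], 1)[0])


def gompertz_slope(
    curve: SurvivalCurve,
    fit_window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Gompertz slope (1/h) from the log cumulative hazard, with bootstrap CI.

    The default fit window spans the 10% to 90% lifespan quantiles -- the
    regime where deaths accumulate exponentially before the old-age slowdown.
    """
    times, cens = curve.lifespans, curve.censored
    events = ~cens
    obs = times[events]
    if fit_window is None:
        fit_window = (float(np.quantile(obs, 0.10)),
                      float(np.quantile(obs, 0.90)))
    slope = _lnH_slope(times, events, fit_window)
    rng = np.random.default_rng(seed)
    boots = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, times.size, times.size)
        try:
            boots[b] = _lnH_slope(times[idx], events[idx], fit_window)
        except ValueError:
            pass
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return slope, (float(lo), float(hi))


def compare_cohorts(
    curve_a: SurvivalCurve,
    curve_b: SurvivalCurve,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Two-cohort report: lifespan ratio, Gompertz-slope ratio, overlay distance.

    The normalized-age overlay rescales each cohort's age axis by its mean
    lifespan; the overlay distance is the maximum vertical gap between the
    two rescaled survival curves.  A pure production-rate (eta) change
    rescales lifespans without changing the curve's shape, so it leaves the
    overlay distance near zero while the mean ratio drops below 1.
    """
    mean_ratio = curve_b.lifespan_mean / curve_a.lifespan_mean
    slope_a, _ = gompertz_slope(curve_a, n_boot=10, seed=seed)
    slope_b, _ = gompertz_slope(curve_b, n_boot=10, seed=seed)

    def _overlay_distance(ta, ea, tb, eb):
        ma, mb = ta[ea].mean(), tb[eb].mean()
        grid = np.linspace(0.0, 2.0, 201)
        sa = _km(ta / ma, ea, grid)
        sb = _km(tb / mb, eb, grid)
        return float(np.max(np.abs(sa - sb)))

    ta, ea = curve_a.lifespans, ~curve_a.censored
    tb, eb = curve_b.lifespans, ~curve_b.censored
    overlay = _overlay_distance(ta, ea, tb, eb)

    rng = np.random.default_rng(seed)
    mr = np.empty(n_boot)
    ov = np.empty(n_boot)
    for b in range(n_boot):
        ia = rng.integers(0, ta.size, ta.size)
        ib = rng.integers(0, tb.size, tb.size)
        mr[b] = tb[ib][eb[ib]].mean() / ta[ia][ea[ia]].mean()
        ov[b] = _overlay_distance(ta[ia], ea[ia], tb[ib], eb[ib])
    return {
        "mean_lifespan_ratio": float(mean_ratio),
        "mean_lifespan_ratio_ci": tuple(np.percentile(mr, [2.5, 97.5])),
        "gompertz_slope_ratio": float(slope_b / slope_a),
        "overlay_distance": overlay,
        "overlay_distance_ci": tuple(np.percentile(ov, [2.5, 97.5])),
    }
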