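"""From fluorescence traces to PI-uptake rates, damage X, and death times.

The measurement model: normalized fluorescence ``s(t)`` obeys
``ds/dt = A1 * e^{X(t)} * (1 - s)``, so the normalized uptake rate is
``e^{X} = (ds/dt) / (A1 * (1 - s))`` and damage is ``X = ln`` of that.
The numerical pipeline follows the membrane-damage measurement procedure:
log-transform, Wiener-smooth, estimate ``d ln s / dt`` by ordinary least
squares in non-overlapping 7 h windows, and convert with ``s/(1-s)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .core import DeathRule

__all__ = [
    "FluorescenceSeries",
    "NormalizedSeries",
    "UptakeTrajectory",
    "normalize_series",
    "wiener_smooth",
    "estimate_uptake",
    "dense_damage",
    "call_death",
    "calibrate_threshold",
    "extract_cohort",
]

_EPS = 1e-6
DEFAULT_WINDOW_H = 7.0
DEFAULT_ANCHOR_H = 20.0
DEFAULT_A1 = 1.0 / 600.0


@dataclass
class FluorescenceSeries:
    """Raw per-cell fluorescence on a uniform hourly grid."""

    cell_id: int
    times: np.ndarray
    intensity: np.ndarray
    background: float | None = None  # default: mean of the first 3 frames

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size != self.intensity.size:
            raise ValueError("times and intensity must have equal length")
        d = np.diff(self.times)
        if self.times.size >= 2 and not np.allclose(d, d[0]):
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class NormalizedSeries:
    """Background-subtracted, max-normalized signal ``s(t)``, clamped to (0, 1)."""

    cell_id: int
    times: np.ndarray
    s: np.ndarray
    clamped: np.ndarray  # frames pinned at the clamp bounds


@dataclass
class UptakeTrajectory:
    """Windowed uptake-rate estimates for one cell.

    ``uptake`` is the normalized PI uptake rate ``e^X`` (dimensionless),
    ``damage`` its log in kBT; invalid windows (saturated, post-death, or
    non-positive slope) are masked and carry NaN.
    """

    cell_id: int
    window_centers: np.ndarray
    uptake: np.ndarray
    damage: np.ndarray
    valid: np.ndarray


def normalize_series(raw: FluorescenceSeries) -> NormalizedSeries:
    """``s = (I - background) / max(I - background)``, clamped into (0, 1).

    Invariant under affine gain/offset changes of the raw intensity (the
    offset via the background estimate, the gain via max-normalization).
    """
    if raw.times.size < 10:
        raise ValueError("need at least 10 frames")
    bg = raw.background
    if bg is None:
        bg = float(np.mean(raw.intensity[:3]))
    net = np.maximum(raw.intensity - bg, 0.0)
    peak = net.max()
    if peak <= 0:
        raise ValueError("flat series: maximum does not exceed background")
    s = net / peak
    clamped = (s < _EPS) | (s > 1.0 - _EPS)
    s = np.clip(s, _EPS, 1.0 - _EPS)
    return NormalizedSeries(cell_id=raw.cell_id, times=raw.times.copy(), s=s,
                            clamped=clamped)


def _noise_power(y: np.ndarray) -> float:
    """Frame-noise variance from the MAD of first differences.

    For frame-uncorrelated noise riding on a slowly varying signal the first
    differences are noise-dominated; the median absolute deviation around the
    median difference is robust to the death jump and to slow trends, and
    vanishes for noiseless smooth series (so the filter reduces to identity).
    """
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = float(np.median(np.abs(d - np.median(d))))
    return (mad / 0.6745) ** 2 / 2.0


def wiener_smooth(y: np.ndarray, size: int = 7, noise: float | None = None) -> np.ndarray:
    """Adaptive local-variance (Wiener) smoother with a local-linear signal model.

    The signal estimate is a local linear fit over ``size`` samples
    (Savitzky--Golay, order 1), which preserves slopes -- the quantity the
    downstream derivative step needs.  Residuals around it are shrunk by the
    Wiener gain ``max(0, 1 - noise/v)`` with ``v`` the local residual
    variance, so genuine excursions (e.g. the death jump) pass through while
    noise-level residuals collapse onto the fit.  The noise floor defaults to
    :func:`_noise_power` and is zero for noiseless series, making the filter
    the identity there.
    """
    y = np.asarray(y, dtype=float)
    if y.size < size:
        return y.copy()
    m = savgol_filter(y, size, 1, mode="nearest")
    r = y - m
    v = uniform_filter1d(r * r, size=size, mode="nearest")
    if noise is None:
        noise = _noise_power(y)
    if noise == 0.0:
        return y.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(v > noise, 1.0 - noise / v, 0.0)
    return m + gain * r


def _window_edges(t_min, t_max, window_h, anchor_h):
    # windows tile forward from the anchor (the start of the analysis range);
    # frames before the anchor are not windowed
    k0 = max(int(np.ceil((t_min - anchor_h) / window_h - 1e-9)), 0)
    starts = []
    s0 = anchor_h + k0 * window_h
    while s0 + window_h <= t_max + 1e-9:
        starts.append(s0)
        s0 += window_h
    return np.asarray(starts)


def _slope_noise_factor(n_window: int, smooth_size: int, dt: float) -> float:
    """Std-dev factor of the window OLS slope under unit white frame noise.

    The window slope is OLS over ``n_window`` frames of a series pre-smoothed
    with a ``smooth_size`` local-linear fit (moving-average equivalent at the
    center); the composite kernel gives the noise gain of the estimator.
    """
    j = np.arange(n_window) - (n_window - 1) / 2.0
    w = j / np.sum(j * j) / dt
    k = np.convolve(w, np.ones(smooth_size) / smooth_size)
    return float(np.sqrt(np.sum(k * k)))


def estimate_uptake(
    series: NormalizedSeries,
    window_h: float = DEFAULT_WINDOW_H,
    a1: float = DEFAULT_A1,
    anchor_h: float = DEFAULT_ANCHOR_H,
    wiener_size: int = 9,
    slope_se_mult: float = 2.0,
) -> UptakeTrajectory:
    """Windowed uptake-rate estimates from a normalized series.

    Pipeline: ``ln s`` -> adaptive Wiener smoothing -> per-window OLS slope of
    ``ln s`` vs ``t`` in non-overlapping windows -> uptake
    ``slope * s_bar / (1 - s_bar) / a1`` with ``s_bar`` the smoothed signal at
    the window center.  Windows are masked invalid when saturated
    (``s_bar > 1 - 10*eps``, post-death), or when the slope is not positive by
    more than ``slope_se_mult`` standard errors of the frame noise -- the log
    of a rate indistinguishable from zero carries no information.
    """
    t, s = series.times, series.s
    dt = t[1] - t[0]
    starts = _window_edges(t[0], t[-1] + dt, window_h, anchor_h)
    if starts.size < 2:
        raise ValueError("series must span at least 2 windows")
    y_raw = np.log(s)
    y = wiener_smooth(y_raw, size=wiener_size)
    noise_sd = np.sqrt(_noise_power(y_raw))
    centers = starts + window_h / 2.0
    uptake = np.full(starts.size, np.nan)
    damage = np.full(starts.size, np.nan)
    valid = np.zeros(starts.size, dtype=bool)
    for j, s0 in enumerate(starts):
        in_win = (t >= s0 - 1e-9) & (t < s0 + window_h - 1e-9)
        n_win = int(in_win.sum())
        if n_win < 3:
            continue
        slope = np.polyfit(t[in_win], y[in_win], 1)[0]
        slope_se = noise_sd * _slope_noise_factor(n_win, wiener_size, dt)
        # the OLS slope applies at the centroid of the window's frames;
        # pairing s_bar with the same age makes the conversion exact for
        # constant uptake, so windows are labeled by the centroid
        centers[j] = float(np.mean(t[in_win]))
        s_bar = float(np.exp(np.interp(centers[j], t, y)))
        if s_bar > 1.0 - 10.0 * _EPS:
            continue
        rate = slope * s_bar / (1.0 - s_bar) / a1
        if rate <= 0 or not np.isfinite(rate) or slope <= slope_se_mult * slope_se:
            continue
        uptake[j] = rate
        damage[j] = np.log(rate)
        valid[j] = True
    return UptakeTrajectory(
        cell_id=series.cell_id, window_centers=centers,
        uptake=uptake, damage=damage, valid=valid,
    )


def dense_damage(
    series: NormalizedSeries,
    a1: float = DEFAULT_A1,
    wiener_size: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame damage estimate used for ~1 h resolution death calling.

    Central differences of the Wiener-smoothed ``ln s`` converted through
    ``s/(1-s)``; frames with non-positive slope or saturated signal are NaN.
    Frames adjacent to low-clamped frames (signal indistinguishable from
    background, typical of the first frames before any uptake) are masked:
    a log-gradient across the clamp floor is an artifact, not uptake.
    """
    t, s = series.times, series.s
    y = wiener_smooth(np.log(s), size=wiener_size)
    # backward differences: the estimate at frame k covers (t_{k-1}, t_k], so
    # the death jump raises the estimate only after the true crossing
    slope = np.empty_like(y)
    slope[1:] = np.diff(y) / np.diff(t)
    slope[0] = slope[1]
    s_sm = np.exp(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = slope * s_sm / (1.0 - s_sm) / a1
    damage = np.where(
        (rate > 0) & (s_sm <= 1.0 - 10.0 * _EPS), np.log(np.maximum(rate, 1e-300)),
        np.nan,
    )
    # saturated frames are post-death: pin them above any finite estimate
    damage[s_sm > 1.0 - 10.0 * _EPS] = np.inf
    low = series.s <= 2.0 * _EPS
    near_clamp = uniform_filter1d(low.astype(float), size=3, mode="nearest") > 0
    damage[near_clamp] = np.nan
    return t.copy(), damage


def call_death(
    traj,
    rule: DeathRule,
    horizon: float | None = None,
) -> tuple[float, bool]:
    """First time the interpolated damage estimate reaches ``rule.x_c``.

    ``traj`` is either an :class:`UptakeTrajectory` (coarse windows) or a
    ``(times, damage)`` pair from :func:`dense_damage`.  Returns
    ``(lifespan_h, censored)``; censored cells report the horizon (last
    observation time if no horizon is given).
    """
    if isinstance(traj, UptakeTrajectory):
        t = traj.window_centers[traj.valid]
        x = traj.damage[traj.valid]
    else:
        t, x = traj
        keep = ~np.isnan(x)
        t, x = t[keep], x[keep]
    end = horizon if horizon is not None else (t[-1] if t.size else np.nan)
    if t.size == 0:
        return float(end), True
    above = x >= rule.x_c
    if not np.any(above):
        return float(end), True
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0]), False
    x0, x1 = x[k - 1], x[k]
    if not np.isfinite(x1):  # jump into saturation: crossing within the frame
        return float(t[k]), False
    frac = (rule.x_c - x0) / (x1 - x0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1])), False


def calibrate_threshold(damage_series: list, lifespans) -> float:
    """Calibration mode: given known lifespans, return the implied threshold.

    The threshold is the maximal damage estimate observed before death across
    cells (the convention used to place the death threshold on the damage
    scale when lifespans are known from an independent criterion).
    """
    x_c = -np.inf
    for (t, x), life in zip(damage_series, np.asarray(lifespans, dtype=float)):
        pre = (t < life) & np.isfinite(x)
        if np.any(pre):
            x_c = max(x_c, float(np.nanmax(x[pre])))
    if not np.isfinite(x_c):
        raise ValueError("no pre-death finite damage estimates")
    return x_c


def extract_cohort(
    traces: pd.DataFrame,
    rule: DeathRule,
    a1: float = DEFAULT_A1,
    window_h: float = DEFAULT_WINDOW_H,
    anchor_h: float = DEFAULT_ANCHOR_H,
    horizon: float | None = None,
    background: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full extraction on a long-format trace table.

    ``traces`` needs columns ``cell_id, time_h, fluorescence`` (as written by
    the synthetic generator).  Returns the windowed per-cell table
    (``cell_id, window_center_h, uptake, damage_kBT, valid``) and the lifespan
    table (``cell_id, lifespan_h, censored``).
    """
    win_rows, life_rows = [], []
    for cid, grp in traces.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_h")
        raw = FluorescenceSeries(
            cell_id=cid, times=grp["time_h"].to_numpy(),
            intensity=grp["fluorescence"].to_numpy(), background=background,
        )
        ns = normalize_series(raw)
        traj = estimate_uptake(ns, window_h=window_h, a1=a1, anchor_h=anchor_h)
        for c, u, x, v in zip(traj.window_centers, traj.uptake, traj.damage,
                              traj.valid):
            win_rows.append((cid, c, u, x, v))
        life, cens = call_death(dense_damage(ns, a1=a1), rule, horizon=horizon)
        life_rows.append((cid, life, cens))
    windows = pd.DataFrame(
        win_rows, columns=["cell_id", "window_center_h", "uptake", "damage_kBT",
                           "valid"]
    )
    lifespans = pd.DataFrame(life_rows,
                             columns=["cell_id", "lifespan_h", "censored"])
    return windows, lifespans
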