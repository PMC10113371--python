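"""Sample-path simulation and first-passage death times for the MP-SR model.

Paths are integrated with a Heun (drift predictor-corrector) variant of
Euler--Maruyama; with additive noise this keeps strong order 1 while making
the deterministic limit second-order accurate.  Per-cell noise streams are derived
from one master seed through ``numpy`` seed-sequence spawning, so the path of
cell ``i`` does not depend on how many cells are simulated alongside it.
Death is the first passage of damage across ``DeathRule.x_c``; the
age-dependent escape rate over the potential barrier is also available in
closed form through the Kramers approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DeathRule,
    MPSRParams,
    NoQuasiSteadyStateError,
    drift,
    potential,
    qss_rvs,
    removal_fraction,
)

__all__ = [
    "TrajectoryEnsemble",
    "FirstPassageSample",
    "BeyondKramersRegimeError",
    "simulate_paths",
    "sample_first_passage",
    "kramers_hazard",
    "empirical_hazard",
    "make_x0_sampler",
]


class BeyondKramersRegimeError(ValueError):
    """Raised when the potential has no confining minimum below the threshold."""


@dataclass
class TrajectoryEnsemble:
    """Ensemble of damage paths on a shared time grid.

    ``paths`` has shape ``(n_cells, n_times)``; entries after an absorbing
    crossing (if any) hold the threshold value.  ``crossing_times`` is NaN for
    cells that never crossed.
    """

    times: np.ndarray
    paths: np.ndarray
    params: MPSRParams
    seed: int
    dt: float
    crossing_times: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.paths.shape[0]

    def at_age(self, age: float) -> np.ndarray:
        """Damage values of all cells at the grid time nearest ``age``."""
        k = int(np.argmin(np.abs(self.times - age)))
        return self.paths[:, k]

    def to_frame(self) -> pd.DataFrame:
        n, m = self.paths.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n), m),
                "time_h": np.tile(self.times, n),
                "X": self.paths.ravel(),
            }
        )

    def write_csv(self, path, sidecar_path=None) -> None:
        """Long-format CSV plus a JSON sidecar with params, seed and dt."""
        self.to_frame().to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "eta0": self.params.eta0, "eta": self.params.eta,
                "beta": self.params.beta, "sigma": self.params.sigma,
                "a": self.params.a, "kappa": self.params.kappa,
                "seed": int(self.seed), "dt": self.dt,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


@dataclass
class FirstPassageSample:
    """Death (first-passage) times of an ensemble, with censoring bookkeeping."""

    death_times: np.ndarray  # uncensored only
    censored: int
    horizon: float
    rule: DeathRule
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.death_times.size + self.censored

    def to_frame(self) -> pd.DataFrame:
        times = np.concatenate(
            [self.death_times, np.full(self.censored, self.horizon)]
        )
        cens = np.concatenate(
            [np.zeros(self.death_times.size, bool), np.ones(self.censored, bool)]
        )
        return pd.DataFrame(
            {"cell_id": np.arange(times.size), "death_time_h": times,
             "censored": cens}
        )


def make_x0_sampler(spec, params: MPSRParams, t0: float):
    """Build an initial-damage sampler ``f(n, rng) -> array``.

    ``spec`` may be "qss" (quasi-steady density at ``t0``, the default initial
    condition after the adaptation period), a scalar (point mass), an array
    (empirical sample, drawn with replacement), or a callable passed through.
    """
    if callable(spec):
        return spec
    if isinstance(spec, str):
        if spec != "qss":
            raise ValueError(f"unknown x0 sampler spec {spec!r}")
        return lambda n, rng: qss_rvs(t0, params, n, rng)
    if np.ndim(spec) == 0:
        x0 = float(spec)
        return lambda n, rng: np.full(n, x0)
    arr = np.asarray(spec, dtype=float)
    return lambda n, rng: rng.choice(arr, size=n, replace=True)


def _cell_draws(seed: int, n: int, n_steps: int, sampler) -> tuple:
    """Per-cell initial damage and noise increments from independent streams.

    Cell ``i`` uses the child stream ``SeedSequence(seed, spawn_key=(i,))``
    and draws its initial condition before its increments, so every cell's
    path is invariant to how many other cells are simulated.
    """
    z = np.empty((n_steps, n))
    x0 = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        x0[i] = sampler(1, rng)[0]
        z[:, i] = rng.standard_normal(n_steps)
    return x0, z


def simulate_paths(
    params: MPSRParams,
    x0_sampler="qss",
    t0: float = 20.0,
    t1: float = 80.0,
    dt: float = 0.05,
    n: int = 100,
    seed: int = 0,
    rule: DeathRule | None = None,
    freeze_age: bool = False,
) -> TrajectoryEnsemble:
    """Sample paths ``X_{k+1} = X_k + G dt + sqrt(2 sigma dt) z`` (Heun drift).

    Parameters
    ----------
    x0_sampler
        Initial-damage distribution; see :func:`make_x0_sampler`.
    rule
        If given, paths are absorbed (held) at ``rule.x_c``; crossing times are
        linearly interpolated within the crossing step.
    freeze_age
        If True the drift is evaluated at fixed age ``t0`` throughout
        (frozen-parameter process, used to check the quasi-steady density).
    """
    if not (t1 > t0 >= 0):
        raise ValueError("need t1 > t0 >= 0")
    if n < 1:
        raise ValueError("need n >= 1")
    if not (0 < dt < 1.0):
        raise ValueError("dt must be in (0, 1) h: coarser steps than the "
                         "hourly observation scale are rejected")
    # grid covers [t0, t1]; the last point may overshoot t1 by < dt
    n_steps = int(np.ceil((t1 - t0) / dt - 1e-9))
    times = t0 + dt * np.arange(n_steps + 1)

    if isinstance(x0_sampler, np.ndarray) and x0_sampler.shape == (n,):
        # explicit per-cell initial values (e.g. the cohort generator's mixture)
        fixed_x0 = np.asarray(x0_sampler, dtype=float)
        x, z = _cell_draws(seed, n, n_steps, lambda _n, _rng: [0.0])
        x = fixed_x0.copy()
    else:
        sampler = make_x0_sampler(x0_sampler, params, t0)
        x, z = _cell_draws(seed, n, n_steps, sampler)
    paths = np.empty((n, n_steps + 1))
    paths[:, 0] = x
    crossing = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)
    x_c = rule.x_c if rule is not None else None
    if x_c is not None:
        hit0 = x >= x_c
        crossing[hit0] = t0
        alive &= ~hit0
        x = np.where(hit0, x_c, x)
        paths[:, 0] = x

    noise_scale = np.sqrt(2.0 * params.sigma * dt)
    for k in range(n_steps):
        # midpoint age for the production term: integrates eta*t exactly
        t_k = t0 if freeze_age else times[k] + 0.5 * dt
        xa = x[alive]
        dw = noise_scale * z[k, alive]
        # Heun predictor-corrector on the drift (additive noise): strong
        # order 1, second-order deterministic limit
        g1 = drift(xa, t_k, params)
        g2 = drift(xa + g1 * dt + dw, t_k, params)
        x_new = x.copy()
        x_new[alive] = xa + 0.5 * (g1 + g2) * dt + dw
        if x_c is not None:
            hit = alive & (x_new >= x_c)
            if np.any(hit):
                # linear interpolation inside the crossing step removes O(dt) bias
                frac = (x_c - x[hit]) / (x_new[hit] - x[hit])
                crossing[hit] = times[k] + frac * dt
                x_new[hit] = x_c
                alive &= ~hit
        x = x_new
        paths[:, k + 1] = x

    return TrajectoryEnsemble(
        times=times, paths=paths, params=params, seed=seed, dt=dt,
        crossing_times=crossing if x_c is not None else None,
    )


def sample_first_passage(
    params: MPSRParams,
    rule: DeathRule,
    x0_sampler="qss",
    t0: float = 20.0,
    horizon: float = 120.0,
    dt: float = 0.05,
    n: int = 1000,
    seed: int = 0,
) -> FirstPassageSample:
    """Sample death times as first passages of ``X`` across ``rule.x_c``."""
    ens = simulate_paths(
        params, x0_sampler, t0=t0, t1=horizon, dt=dt, n=n, seed=seed, rule=rule
    )
    ct = ens.crossing_times
    dead = np.isfinite(ct)
    result = FirstPassageSample(
        death_times=np.sort(ct[dead]),
        censored=int(np.sum(~dead)),
        horizon=horizon,
        rule=rule,
    )
    if result.death_times.size == 0:
        msg = "no cells were absorbed by the horizon; hazard estimation will refuse"
        result.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return result


def kramers_hazard(params: MPSRParams, rule: DeathRule, t) -> float | np.ndarray:
    """Kramers escape rate over the barrier between the potential minimum and ``x_c``.

    For ``dX = -U'(X) dt + sqrt(2 sigma) xi`` with an interior barrier top
    ``x_max`` the escape rate is the classical

        (1/2pi) * sqrt(U''(x_min) * |U''(x_max)|) * exp(-[U(x_max)-U(x_min)]/sigma).

    The MP-SR potential has ``U'' > 0`` everywhere, so there is never an
    interior saddle: the exit point is the absorbing threshold ``x_c`` on a
    rising slope.  The matched-asymptotics escape rate for that geometry
    (saddle-point evaluation of the mean-first-passage double integral) is

        U'(x_c) * sqrt(U''(x_min) / (2 pi sigma)) * exp(-[U(x_c)-U(x_min)]/sigma),

    which is what this function returns when no interior maximum exists.
    Either way the rate rises with age because the linear production term
    tilts the potential, shrinking the barrier.

    Raises
    ------
    BeyondKramersRegimeError
        If at age ``t`` the potential has no interior minimum below ``x_c``
        (production rate outside ``(0, beta)``, or minimum at/above threshold).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    rates = np.empty(t_arr.shape)
    for i, ti in enumerate(t_arr):
        eta_t = float(params.production_rate(ti))
        if not (0.0 < eta_t < params.beta):
            raise BeyondKramersRegimeError(
                f"no interior potential minimum at t={ti}: production rate "
                f"{eta_t:.4g} outside (0, beta)"
            )
        frac = eta_t / params.beta
        x_min = params.kappa + np.log(frac / (1.0 - frac)) / params.a
        if x_min >= rule.x_c:
            raise BeyondKramersRegimeError(
                f"potential minimum {x_min:.3g} at or above threshold {rule.x_c}"
            )
        x_max = rule.x_c

        def u_curv(x):
            f = removal_fraction(x, params)
            return params.beta * params.a * f * (1.0 - f)

        du = float(potential(x_max, ti, params) - potential(x_min, ti, params))
        u_slope_exit = -float(drift(x_max, ti, params))  # U'(x_c) > 0 here
        if u_slope_exit <= 0:
            # threshold beyond a genuine saddle: classical Kramers form
            pref = np.sqrt(u_curv(x_min) * abs(u_curv(x_max))) / (2.0 * np.pi)
        else:
            pref = u_slope_exit * np.sqrt(
                u_curv(x_min) / (2.0 * np.pi * params.sigma))
        rates[i] = pref * np.exp(-du / params.sigma)
    return rates if np.ndim(t) else float(rates[0])


def empirical_hazard(
    sample: FirstPassageSample, bin_h: float = 1.0
) -> pd.DataFrame:
    """Nelson--Aalen-style hazard increments on fixed-width age bins.

    Returns a frame with ``age_h`` (bin centers), ``hazard`` (events per cell
    per hour among cells at risk), and ``n_at_risk``.
    """
    if sample.death_times.size == 0:
        raise ValueError("cannot estimate a hazard from zero observed deaths")
    t_start = min(sample.death_times.min(), sample.horizon)
    edges = np.arange(np.floor(t_start), sample.horizon + bin_h, bin_h)
    deaths, _ = np.histogram(sample.death_times, bins=edges)
    # at risk at bin start: everyone not yet dead (censoring only at horizon)
    n_total = sample.n
    dead_before = np.concatenate([[0], np.cumsum(deaths)[:-1]])
    at_risk = n_total - dead_before
    with np.errstate(invalid="ignore", divide="ignore"):
        hz = deaths / (at_risk * bin_h)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = at_risk > 0
    return pd.DataFrame(
        {"age_h": centers[keep], "hazard": hz[keep], "n_at_risk": at_risk[keep],
         "events": deaths[keep]}
    )
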