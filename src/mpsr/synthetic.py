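"""Synthetic mother-machine-like cohorts with a known ground truth.

Each synthetic cell carries a latent MP-SR damage path ``X(t)``; the observed
channel is hourly PI-like fluorescence obtained by integrating the saturating
uptake kinetics

    ds/dt = A1 * e^{X(t)} * (1 - s),    s(0) = 0,

and multiplying each frame by independent multiplicative measurement noise
(log-normal, ~6% CV by default, uncorrelated between frames).  Death is the
first passage of ``X`` across the cohort's death threshold; after death the
latent state jumps to ``x_c + post_death_boost`` ("membrane collapse") so the
fluorescence channel saturates within a few hours, as observed cells do.

A small fraction of cells (3% by default) starts with high damage (normalized
uptake above 4); the rest start log-normally around a mean uptake of 0.87.
Covariates (initial size, reductive-division times) are generated independent
of lifespan by default; a configurable association coefficient exists to
exercise the correlation machinery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DeathRule, MPSRParams, WILDTYPE_PARAMS, params_to_json
from .simulate import simulate_paths

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "SyntheticCell",
    "generate_cohort",
    "write_truth",
    "read_truth",
]

#: Death threshold used for synthetic cohorts.  Chosen so that, under the
#: wildtype parameters, simulated mean lifespan is ~80 h with a sigmoidal
#: survival curve (see docs/methods.md for the calibration argument).
COHORT_X_C = 3.0


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions for per-cell covariates and their lifespan association.

    ``lifespan_association`` linearly mixes a lifespan-rank component into the
    log initial size (0 = independent, the default, matching the observation
    that initial size and division timing barely correlate with lifespan).
    """

    initial_size_mean_um: float = 2.5
    initial_size_cv: float = 0.2
    division_rate_per_h: float = 0.15   # reductive divisions on-chip, first hours
    division_window_h: float = 10.0
    lifespan_association: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    """Generation settings for one synthetic cohort."""

    n_cells: int = 635
    horizon_h: float = 120.0
    frame_interval_h: float = 1.0
    params: MPSRParams = WILDTYPE_PARAMS
    rule: DeathRule = DeathRule(COHORT_X_C)
    noise_cv: float = 0.06
    high_damage_fraction: float = 0.03
    high_damage_uptake_min: float = 4.0
    high_damage_log_excess_scale: float = 0.4
    baseline_uptake_mean: float = 0.87
    baseline_uptake_cv: float = 0.4
    a1: float = 1.0 / 600.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    post_death_boost: float = 2.0
    latent_dt: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.high_damage_fraction <= 1 and 0 <= self.noise_cv):
            raise ValueError("fractions must lie in [0, 1] and noise_cv >= 0")
        if self.frame_interval_h <= 0 or self.a1 <= 0:
            raise ValueError("frame_interval_h and a1 must be > 0")
        n_frames = self.horizon_h / self.frame_interval_h
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("frame_interval_h must divide horizon_h")


@dataclass
class SyntheticCell:
    """One generated cell: observed fluorescence plus the generator's truth."""

    cell_id: int
    times: np.ndarray            # frame grid, h
    fluorescence: np.ndarray     # noisy normalized signal in [0, 1.05]
    truth_damage: np.ndarray     # latent X on the frame grid (NaN after death)
    truth_lifespan_h: float      # NaN if censored
    censored: bool
    initial_damage: float        # latent X at t=0
    covariates: dict


def _initial_damage(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Mixture initial condition on X = ln(uptake) at loading time."""
    n = config.n_cells
    cv = config.baseline_uptake_cv
    s2 = np.log1p(cv * cv)
    mu = np.log(config.baseline_uptake_mean) - 0.5 * s2
    x = rng.normal(mu, np.sqrt(s2), size=n)
    hi = rng.random(n) < config.high_damage_fraction
    n_hi = int(hi.sum())
    if n_hi:
        excess = rng.exponential(config.high_damage_log_excess_scale, size=n_hi)
        x[hi] = np.log(config.high_damage_uptake_min) + excess
    return x


def _covariates(
    config: CohortConfig, lifespans: np.ndarray, rng: np.random.Generator
) -> list[dict]:
    spec = config.covariate_spec
    n = config.n_cells
    s2 = np.log1p(spec.initial_size_cv**2)
    z_ind = rng.standard_normal(n)
    rho = spec.lifespan_association
    if rho != 0.0:
        # rank-normal lifespan score so Spearman(size, lifespan) ~ rho
        ranks = pd.Series(lifespans).rank().to_numpy()
        z_life = (ranks - 0.5) / len(ranks)
        from scipy.stats import norm
        z_life = norm.ppf(z_life)
        z = rho * z_life + np.sqrt(1 - rho * rho) * z_ind
    else:
        z = z_ind
    size = np.exp(np.log(spec.initial_size_mean_um) - 0.5 * s2 + np.sqrt(s2) * z)
    out = []
    for i in range(n):
        n_div = rng.poisson(spec.division_rate_per_h * spec.division_window_h)
        div_times = np.sort(rng.uniform(0, spec.division_window_h, size=n_div))
        out.append(
            {
                "initial_size_um": float(size[i]),
                "division_times_h": [float(t) for t in div_times],
                "n_divisions": int(n_div),
            }
        )
    return out


def generate_cohort(config: CohortConfig) -> list[SyntheticCell]:
    """Generate a cohort of synthetic cells; reproducible under ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    x0 = _initial_damage(config, rng)

    ens = simulate_paths(
        config.params,
        x0_sampler=x0,
        t0=0.0,
        t1=config.horizon_h,
        dt=config.latent_dt,
        n=config.n_cells,
        seed=config.seed,
        rule=config.rule,
    )
    crossing = ens.crossing_times
    dead = np.isfinite(crossing)

    # latent state actually driving uptake: collapses above threshold at death
    x_eff = ens.paths.copy()
    t_grid = ens.times
    for i in np.where(dead)[0]:
        x_eff[i, t_grid >= crossing[i]] = config.rule.x_c + config.post_death_boost

    # stiff-safe exact integration of ds = a1 e^X (1-s) dt for piecewise-const X
    rate = config.a1 * np.exp(x_eff)
    dt_steps = np.diff(t_grid)
    log_one_minus_s = np.zeros_like(x_eff)
    log_one_minus_s[:, 1:] = -np.cumsum(rate[:, :-1] * dt_steps, axis=1)
    s = 1.0 - np.exp(log_one_minus_s)

    n_frames = int(round(config.horizon_h / config.frame_interval_h)) + 1
    frame_times = config.frame_interval_h * np.arange(n_frames)
    frame_idx = np.rint(frame_times / config.latent_dt).astype(int)
    frame_idx = np.clip(frame_idx, 0, t_grid.size - 1)

    sd = np.log1p(config.noise_cv)
    eps = rng.normal(0.0, sd, size=(config.n_cells, n_frames)) if config.noise_cv > 0 \
        else np.zeros((config.n_cells, n_frames))
    fluo = np.clip(s[:, frame_idx] * np.exp(eps), 0.0, 1.05)

    lifespans = np.where(dead, crossing, np.nan)
    covs = _covariates(config, np.where(dead, crossing, config.horizon_h), rng)

    cells = []
    for i in range(config.n_cells):
        truth_x = ens.paths[i, frame_idx].copy()
        if dead[i]:
            truth_x[frame_times > crossing[i]] = np.nan
        cells.append(
            SyntheticCell(
                cell_id=i,
                times=frame_times.copy(),
                fluorescence=fluo[i],
                truth_damage=truth_x,
                truth_lifespan_h=float(lifespans[i]),
                censored=not bool(dead[i]),
                initial_damage=float(x0[i]),
                covariates=covs[i],
            )
        )
    return cells


def write_truth(cells: list[SyntheticCell], out_dir: str, config: CohortConfig | None = None,
                overwrite: bool = False) -> dict:
    """Write traces CSV, covariates CSV and truth JSON; returns the file map."""
    if not cells:
        raise ValueError("no cells to write")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "traces": os.path.join(out_dir, "traces.csv"),
        "covariates": os.path.join(out_dir, "covariates.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    if not overwrite:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists (pass overwrite=True)")

    traces = pd.DataFrame(
        {
            "cell_id": np.concatenate([np.full(c.times.size, c.cell_id) for c in cells]),
            "time_h": np.concatenate([c.times for c in cells]),
            "fluorescence": np.concatenate([c.fluorescence for c in cells]),
        }
    )
    traces.to_csv(paths["traces"], index=False, float_format="%.17g")

    cov = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "initial_size_um": [c.covariates["initial_size_um"] for c in cells],
            "division_times_h": [
                ";".join(repr(t) for t in c.covariates["division_times_h"])
                for c in cells
            ],
            "n_divisions": [c.covariates["n_divisions"] for c in cells],
        }
    )
    cov.to_csv(paths["covariates"], index=False, float_format="%.17g")

    truth = {
        "params": (
            json.loads(params_to_json(config.params, config.rule))
            if config is not None else None
        ),
        "seed": config.seed if config is not None else None,
        "cells": [
            {
                "cell_id": c.cell_id,
                "truth_lifespan_h": None if c.censored else c.truth_lifespan_h,
                "censored": c.censored,
                "initial_damage": c.initial_damage,
            }
            for c in cells
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def read_truth(out_dir: str) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Load the three artifacts written by :func:`write_truth`."""
    traces = pd.read_csv(os.path.join(out_dir, "traces.csv"),
                         float_precision="round_trip")
    cov = pd.read_csv(os.path.join(out_dir, "covariates.csv"),
                      float_precision="round_trip")
    with open(os.path.join(out_dir, "truth.json")) as fh:
        truth = json.load(fh)
    return traces, cov, truth
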