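"""End-to-end orchestration: generate -> extract -> stats -> survival ->
dist-fit -> model-fit, with a manifest, per-stage seeds, and resumability.

The pipeline is driven as a library function (the numbered scripts under
``analysis/`` are thin wrappers around the same stages).  One master seed
spawns deterministic per-stage child seeds, so a rerun with the same config
reproduces every artifact; the manifest records inputs, outputs, checksums
and wall times per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import DeathRule, params_to_json
from .synthetic import CohortConfig, generate_cohort, write_truth
from .extraction import extract_cohort
from .cohort_stats import cross_sectional_stats, autocorrelation
from .survival import survival_curves, gompertz_slope
from .dist_fit import fit_marginal, fit_gb2_by_age, gb2_to_mpsr
from .inference import FitConfig, fit_mpsr, transitions_from_windows

logger = logging.getLogger("mpsr.pipeline")

STAGES = ("generate", "extract", "stats", "survival", "distfit", "fit")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple = STAGES
    seed: int = 0
    traces_path: str | None = None   # use existing traces instead of generating
    window_ages: tuple | None = None  # None: all window centers in the table
    n_boot: int = 200
    fit: FitConfig = field(default_factory=FitConfig)
    resume: bool = False

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(STAGES.index(stage),))
        return int(ss.generate_state(1)[0] % (2**31))

    def config_hash(self) -> str:
        def _enc(o):
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
            return str(o)
        blob = json.dumps(asdict(self), default=_enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    With ``resume=True`` a stage whose outputs already exist is skipped, so
    deleting one intermediate re-executes only that stage and those after it.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": []}
    order = [s for s in STAGES if s in config.stages]
    ctx: dict = {}

    for stage in order:
        t_start = time.time()
        outputs = _STAGE_FUNCS[stage](config, ctx)
        entry = {
            "stage": stage,
            "seed": config.stage_seed(stage),
            "outputs": {k: _checksum(p) for k, p in outputs.items()},
            "paths": outputs,
            "wall_s": round(time.time() - t_start, 3),
        }
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", stage, entry["wall_s"])

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _p(config, name):
    return os.path.join(config.out_dir, name)


def _load_traces(config, ctx):
    if "traces" not in ctx:
        path = config.traces_path or _p(config, "traces.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"missing upstream artifact {path}: run the generate stage "
                "or point traces_path at existing data")
        ctx["traces"] = pd.read_csv(path)
    return ctx["traces"]


def _stage_generate(config, ctx):
    cc = config.cohort
    cohort = CohortConfig(**{**cc.__dict__, "seed": config.stage_seed("generate")})
    done = all(os.path.exists(_p(config, f)) for f in
               ("traces.csv", "covariates.csv", "truth.json"))
    if config.resume and done:
        return {f: _p(config, f) for f in ("traces.csv", "covariates.csv",
                                           "truth.json")}
    cells = generate_cohort(cohort)
    paths = write_truth(cells, config.out_dir, config=cohort, overwrite=True)
    ctx["cells"] = cells
    return {os.path.basename(v): v for v in paths.values()}


def _stage_extract(config, ctx):
    out_w, out_l = _p(config, "windows.csv"), _p(config, "lifespans.csv")
    if config.resume and os.path.exists(out_w) and os.path.exists(out_l):
        ctx["windows"] = pd.read_csv(out_w)
        ctx["lifespans"] = pd.read_csv(out_l)
        return {"windows.csv": out_w, "lifespans.csv": out_l}
    traces = _load_traces(config, ctx)
    windows, lifespans = extract_cohort(
        traces, config.cohort.rule, a1=config.cohort.a1,
        horizon=config.cohort.horizon_h)
    windows.to_csv(out_w, index=False)
    lifespans.to_csv(out_l, index=False)
    ctx["windows"], ctx["lifespans"] = windows, lifespans
    return {"windows.csv": out_w, "lifespans.csv": out_l}


def _require(ctx, config, key, fname):
    if key not in ctx:
        path = _p(config, fname)
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing upstream artifact {path}")
        ctx[key] = pd.read_csv(path)
    return ctx[key]


def _stage_stats(config, ctx):
    windows = _require(ctx, config, "windows", "windows.csv")
    lifespans = _require(ctx, config, "lifespans", "lifespans.csv")
    seed = config.stage_seed("stats")
    present = sorted(windows["window_center_h"].unique())
    ages = (present if config.window_ages is None
            else [a for a in config.window_ages if a in set(present)])
    rows, kept = [], []
    for age in ages:
        try:
            (sec,) = cross_sectional_stats(windows, lifespans, [age],
                                           "uptake", n_boot=config.n_boot,
                                           seed=seed)
        except ValueError:  # too few cells alive at late ages
            continue
        rows.extend(sec.to_rows())
        kept.append(age)
    ages = kept
    out_s = _p(config, "cross_sections.csv")
    pd.DataFrame(rows).to_csv(out_s, index=False)
    ac_rows = []
    for age in ages[:-1]:
        try:
            r, se, n = autocorrelation(windows, lifespans, age,
                                       n_boot=config.n_boot, seed=seed)
            ac_rows.append({"age_h": age, "r": r, "se": se, "n_pairs": n})
        except ValueError:
            pass
    out_a = _p(config, "autocorrelation.csv")
    pd.DataFrame(ac_rows).to_csv(out_a, index=False)
    return {"cross_sections.csv": out_s, "autocorrelation.csv": out_a}


def _stage_survival(config, ctx):
    lifespans = _require(ctx, config, "lifespans", "lifespans.csv")
    seed = config.stage_seed("survival")
    curve = survival_curves(lifespans["lifespan_h"], lifespans["censored"],
                            n_boot=config.n_boot, seed=seed)
    out_c = _p(config, "survival.csv")
    curve.to_frame().to_csv(out_c, index=False)
    slope, ci = gompertz_slope(curve, n_boot=config.n_boot, seed=seed)
    out_g = _p(config, "gompertz.json")
    with open(out_g, "w") as fh:
        json.dump({"slope_per_h": slope, "ci": ci,
                   "lifespan_mean_h": curve.lifespan_mean,
                   "lifespan_cv": curve.lifespan_cv,
                   "quantiles_h": curve.quantiles}, fh, indent=1)
    return {"survival.csv": out_c, "gompertz.json": out_g}


def _stage_distfit(config, ctx):
    windows = _require(ctx, config, "windows", "windows.csv")
    lifespans = _require(ctx, config, "lifespans", "lifespans.csv")
    seed = config.stage_seed("distfit")
    alive = windows[windows["valid"]].merge(lifespans, on="cell_id")
    alive = alive[alive["lifespan_h"] > alive["window_center_h"]]
    rows, samples = [], {}
    for age, grp in alive.groupby("window_center_h"):
        z = grp["uptake"].to_numpy()
        if z.size < 30:
            continue
        for rank, res in enumerate(fit_marginal(z, seed=seed, age_h=age)):
            rows.append({"age_h": age, "family": res.family, "rank": rank,
                         "ks_stat": res.ks_stat, "ks_p": res.ks_p,
                         "loglik": res.loglik, "n": res.n,
                         "converged": res.converged,
                         **{f"param_{k}": v for k, v in res.params.items()}})
        samples[age] = z
    out_f = _p(config, "marginal_fits.csv")
    pd.DataFrame(rows).to_csv(out_f, index=False)
    mapping = gb2_to_mpsr(fit_gb2_by_age(samples, seed=seed),
                          sigma=config.cohort.params.sigma)
    out_t = _p(config, "gb2_trend.json")
    with open(out_t, "w") as fh:
        json.dump({"trend": mapping["trend"],
                   "table": mapping["table"].to_dict(orient="records")},
                  fh, indent=1)
    return {"marginal_fits.csv": out_f, "gb2_trend.json": out_t}


def _stage_fit(config, ctx):
    windows = _require(ctx, config, "windows", "windows.csv")
    fit_cfg = FitConfig(**{**config.fit.__dict__,
                           "seed": config.stage_seed("fit")})
    data = transitions_from_windows(windows)
    res = fit_mpsr(data, fit_cfg)
    out = _p(config, "fit_result.json")
    with open(out, "w") as fh:
        json.dump({
            "theta_hat": json.loads(params_to_json(res.theta_hat)),
            "loglik": res.loglik, "iterations": res.iterations,
            "converged": res.converged, "n_transitions": res.n_transitions,
            "boundary": res.boundary, "seed": fit_cfg.seed,
            "backend": fit_cfg.backend,
        }, fh, indent=1)
    return {"fit_result.json": out}


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "extract": _stage_extract,
    "stats": _stage_stats,
    "survival": _stage_survival,
    "distfit": _stage_distfit,
    "fit": _stage_fit,
}
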