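"""Maximum-likelihood fitting of the MP-SR parameters to damage trajectories.

The likelihood of a set of per-cell damage observations is a product of
Markov transition densities,

    LL(theta) = sum_i sum_j ln P[(t_j, X_ij) | (t_{j-1}, X_i(j-1)); theta],

maximized over theta = (eta, beta, sigma, a, kappa, eta0) by an iterative
interval-halving grid search.  Two transition-density backends are provided:

* ``sim_kde`` -- the reference backend: simulate the SDE from each observed
  start point many times and estimate the endpoint density by Gaussian KDE
  (Silverman bandwidth).  Faithful but expensive; common random numbers
  across theta keep grid comparisons stable.
* ``euler_gauss`` -- fast deterministic backend: propagate a Gaussian
  (mean/variance) approximation of the transition through sub-stepped
  linearized moment equations ``m' = G(m, t)``, ``v' = 2 G_x(m, t) v + 2
  sigma``.  Exact for linear drift; the desk-scale default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import MPSRParams, drift

try:  # optional fast path for the Gaussian backend
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "FitConfig",
    "FitResult",
    "TransitionData",
    "transitions_from_windows",
    "transitions_from_paths",
    "transition_loglik",
    "fit_mpsr",
    "DEFAULT_GRID",
]

_LOG_FLOOR = np.log(1e-300)

#: Initial search ranges (generic order-of-magnitude brackets for hourly
#: damage dynamics in kBT units).
DEFAULT_GRID = {
    "eta": (1e-3, 2e-2),
    "beta": (0.2, 5.0),
    "sigma": (0.03, 0.8),
    "a": (0.08, 1.2),
    "kappa": (-2.0, 2.0),
    "eta0": (0.05, 1.5),
}

_PARAM_ORDER = ("eta", "beta", "sigma", "a", "kappa", "eta0")
_LOG_SCALE = {"eta": True, "beta": True, "sigma": True, "a": True,
              "kappa": False, "eta0": True}


@dataclass
class TransitionData:
    """Flattened observation pairs: cell i goes from (t0, x0) to (t1, x1)."""

    cell_ids: np.ndarray
    t0: np.ndarray
    x0: np.ndarray
    t1: np.ndarray
    x1: np.ndarray

    def __post_init__(self):
        n = self.t0.size
        if not all(a.size == n for a in (self.cell_ids, self.x0, self.t1,
                                         self.x1)):
            raise ValueError("transition arrays must share a length")
        if n == 0:
            raise ValueError("no transitions")
        if np.any(self.t1 <= self.t0):
            raise ValueError("transitions must advance in time")

    @property
    def n(self) -> int:
        return self.t0.size

    def subset(self, mask) -> "TransitionData":
        return TransitionData(self.cell_ids[mask], self.t0[mask],
                              self.x0[mask], self.t1[mask], self.x1[mask])


def transitions_from_windows(windows: pd.DataFrame) -> TransitionData:
    """Consecutive valid-window pairs per cell from the extraction table."""
    rows = []
    for cid, grp in windows[windows["valid"]].groupby("cell_id"):
        grp = grp.sort_values("window_center_h")
        t = grp["window_center_h"].to_numpy()
        x = grp["damage_kBT"].to_numpy()
        for j in range(1, t.size):
            rows.append((cid, t[j - 1], x[j - 1], t[j], x[j]))
    if not rows:
        raise ValueError("no consecutive valid observation pairs")
    arr = np.asarray(rows, dtype=float)
    return TransitionData(arr[:, 0].astype(int), arr[:, 1], arr[:, 2],
                          arr[:, 3], arr[:, 4])


def transitions_from_paths(times, paths, obs_interval_h: float = 1.0
                           ) -> TransitionData:
    """Observation pairs from dense simulated paths at a fixed sampling step."""
    times = np.asarray(times, dtype=float)
    stride = int(round(obs_interval_h / (times[1] - times[0])))
    idx = np.arange(0, times.size, stride)
    t_obs = times[idx]
    x_obs = np.asarray(paths)[:, idx]
    n_cells, m = x_obs.shape
    cid = np.repeat(np.arange(n_cells), m - 1)
    t0 = np.tile(t_obs[:-1], n_cells)
    t1 = np.tile(t_obs[1:], n_cells)
    x0 = x_obs[:, :-1].ravel()
    x1 = x_obs[:, 1:].ravel()
    return TransitionData(cid, t0, x0, t1, x1)


@dataclass
class FitConfig:
    """Settings for the grid-search maximum-likelihood fit."""

    backend: str = "euler_gauss"
    sims_per_transition: int = 1000
    sim_dt: float = 0.1
    substep_h: float = 0.5
    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    points: int = 3
    halving_factor: float = 2.0
    max_iterations: int = 40
    min_span: float = 1e-4
    n_restarts: int = 2
    restart_span_frac: float = 0.5
    simplex_polish: bool = True
    n_boot: int = 200
    seed: int = 0
    include_initial_qss: bool = False

    def __post_init__(self):
        if self.backend not in ("euler_gauss", "sim_kde"):
            raise ValueError("backend must be 'euler_gauss' or 'sim_kde'")
        if self.backend == "sim_kde" and self.sims_per_transition < 100:
            raise ValueError("sim_kde needs >= 100 simulations per transition")
        for k, (lo, hi) in self.grid.items():
            if _LOG_SCALE[k] and lo <= 0:
                raise ValueError(f"grid bounds for {k} must be positive")
            if hi <= lo:
                raise ValueError(f"empty grid range for {k}")


@dataclass
class FitResult:
    """Outcome of :func:`fit_mpsr`."""

    theta_hat: MPSRParams
    loglik: float
    ci: dict
    iterations: int
    converged: bool
    n_transitions: int
    boundary: str | None = None
    floored_transitions: int = 0


def _theta_from_vec(vec) -> MPSRParams:
    d = dict(zip(_PARAM_ORDER, vec))
    return MPSRParams(**d)


def _loglik_euler_gauss_numpy(eta, beta, sigma, a, kappa, eta0,
                              t0, x0, t1, x1, substep_h):
    # midpoint RK2 on the mean, exponential (exact-for-frozen-rate) steps on
    # the variance: plain Euler substeps at h=0.25 leave O(h^2) moment errors
    # (~2% on the variance) that masquerade as parameter shifts at large n
    gap = t1 - t0
    n_sub = max(1, int(np.ceil(gap.max() / substep_h)))
    h = gap / n_sub
    m = x0.copy()
    v = np.zeros_like(m)
    t = t0.copy()
    ba = beta * a
    for _ in range(n_sub):
        # half step to the midpoint state
        f = 1.0 / (1.0 + np.exp(-a * (m - kappa)))
        g = eta0 + eta * t - beta * f
        gx = np.minimum(-ba * f * (1.0 - f), -1e-12)
        gxx = -ba * a * f * (1.0 - f) * (1.0 - 2.0 * f)
        em = np.expm1(gx * h)  # 2*gx*(h/2)
        m_mid = m + (g + 0.5 * gxx * v) * (0.5 * h)
        v_mid = v * (1.0 + em) + sigma * em / gx
        # full step with midpoint rates
        f = 1.0 / (1.0 + np.exp(-a * (m_mid - kappa)))
        g = eta0 + eta * (t + 0.5 * h) - beta * f
        gx = np.minimum(-ba * f * (1.0 - f), -1e-12)
        gxx = -ba * a * f * (1.0 - f) * (1.0 - 2.0 * f)
        em = np.expm1(2.0 * gx * h)
        m = m + (g + 0.5 * gxx * v_mid) * h
        v = v * (1.0 + em) + sigma * em / gx
        t = t + h
    v = np.maximum(v, 1e-12)
    ll = -0.5 * np.log(2.0 * np.pi * v) - (x1 - m) ** 2 / (2.0 * v)
    return np.maximum(ll, _LOG_FLOOR)


if _njit is not None:
    _loglik_euler_gauss_kernel = _njit(cache=False, fastmath=True)(
        _loglik_euler_gauss_numpy)
else:  # pragma: no cover
    _loglik_euler_gauss_kernel = _loglik_euler_gauss_numpy


def _loglik_euler_gauss(theta: MPSRParams, data: TransitionData,
                        substep_h: float) -> np.ndarray:
    """Per-transition Gaussian transition log-densities (vectorized).

    Moment equations are closed at second order: the mean picks up the
    Jensen correction ``0.5 * G_xx * v`` (the removal sigmoid's curvature
    shifts the conditional mean once the transition has spread), without
    which the likelihood is biased toward flatter removal functions.
    """
    return _loglik_euler_gauss_kernel(
        theta.eta, theta.beta, theta.sigma, theta.a, theta.kappa, theta.eta0,
        data.t0, data.x0, data.t1, data.x1, substep_h)


def _loglik_sim_kde(theta: MPSRParams, data: TransitionData, config: FitConfig
                    ) -> np.ndarray:
    """Simulated-likelihood transition log-densities with Gaussian KDE.

    The RNG is re-seeded from ``config.seed`` on every call, so all theta on
    a grid see the same noise (common random numbers).
    """
    rng = np.random.default_rng(config.seed)
    n_sims = config.sims_per_transition
    gap = data.t1 - data.t0
    n_steps = max(1, int(np.ceil(gap.max() / config.sim_dt)))
    h = gap / n_steps
    x = np.tile(data.x0, (n_sims, 1))
    t = np.tile(data.t0, (n_sims, 1))
    scale = np.sqrt(2.0 * theta.sigma * h)
    for _ in range(n_steps):
        x = x + drift(x, t, theta) * h + scale * rng.standard_normal(x.shape)
        t = t + h
    sd = np.std(x, axis=0, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25], axis=0))
    spread = np.minimum(sd, iqr / 1.34)
    spread = np.where(spread > 0, spread, np.maximum(sd, 1e-6))
    bw = 0.9 * spread * n_sims ** (-0.2)
    z = (data.x1[None, :] - x) / bw[None, :]
    ll = logsumexp(-0.5 * z * z, axis=0) - np.log(
        n_sims * bw * np.sqrt(2.0 * np.pi)
    )
    return np.maximum(ll, _LOG_FLOOR)


def _first_observations(data: TransitionData):
    """(t, x) of each cell's earliest observation, ordered by unique cell id."""
    cells = np.unique(data.cell_ids)
    t_arr = np.empty(cells.size)
    x_arr = np.empty(cells.size)
    for j, c in enumerate(cells):
        mask = data.cell_ids == c
        k = np.argmin(data.t0[mask])
        t_arr[j] = data.t0[mask][k]
        x_arr[j] = data.x0[mask][k]
    return t_arr, x_arr


def _initial_state_loglik(theta: MPSRParams, t_arr, x_arr) -> np.ndarray:
    """Log-density of each cell's first observation under the quasi-steady law.

    When trajectories are known to start from the quasi-steady density (as in
    simulation experiments), the initial states carry direct information on
    the stationary shape -- in particular on ``kappa`` and ``a``, which hourly
    transitions constrain only weakly.  Returns one value per cell; a large
    negative constant if the potential is non-confining at the start age.
    """
    from scipy.special import betaln

    eta_t = theta.production_rate(t_arr)
    if np.any(eta_t <= 0) or np.any(eta_t >= theta.beta):
        return np.full(t_arr.size, -1e6)
    p = eta_t / (theta.a * theta.sigma)
    q = (theta.beta - eta_t) / (theta.a * theta.sigma)
    y = theta.a * (x_arr - theta.kappa)
    ll = (np.log(theta.a) + p * y - (p + q) * np.logaddexp(0.0, y)
          - betaln(p, q))
    return np.maximum(ll, _LOG_FLOOR)


def transition_loglik(data: TransitionData, theta: MPSRParams,
                      config: FitConfig | None = None,
                      per_transition: bool = False):
    """Total (or per-transition) transition log-likelihood under ``theta``.

    With ``config.include_initial_qss`` the quasi-steady log-density of each
    cell's first observation is added (only to the total)."""
    config = config or FitConfig()
    if config.backend == "euler_gauss":
        ll = _loglik_euler_gauss(theta, data, config.substep_h)
    else:
        ll = _loglik_sim_kde(theta, data, config)
    if per_transition:
        return ll
    total = float(ll.sum())
    if config.include_initial_qss:
        t_arr, x_arr = _first_observations(data)
        total += float(_initial_state_loglik(theta, t_arr, x_arr).sum())
    return total


def _to_search(vec):
    return np.array([np.log(v) if _LOG_SCALE[k] else v
                     for k, v in zip(_PARAM_ORDER, vec)])


def _from_search(svec):
    return np.array([np.exp(v) if _LOG_SCALE[k] else v
                     for k, v in zip(_PARAM_ORDER, svec)])


def _cell_sums(ll_per_transition, cell_ids, n_cells):
    return np.bincount(cell_ids, weights=ll_per_transition,
                       minlength=n_cells)


def _grid_search(data: TransitionData, config: FitConfig,
                 center: np.ndarray, span: np.ndarray):
    """Interval-halving grid search in the (log-scaled) parameter space.

    Each iteration evaluates a ``points``-per-dimension grid around the
    center, recenters on the best point, and halves every span.  The
    contraction bounds the total excursion from the initial ranges -- an
    essential property here, because the likelihood has a long, nearly flat
    curved ridge in (beta, a, kappa, eta0) along which an unconstrained
    optimizer drifts arbitrarily far for a negligible likelihood gain.
    Convergence requires an interior optimum whose log-likelihood advantage
    over every neighbor is within the bootstrap CI of zero.
    """
    cell_index = {c: i for i, c in enumerate(np.unique(data.cell_ids))}
    cid = np.array([cell_index[c] for c in data.cell_ids])
    n_cells = len(cell_index)
    init_tx = (_first_observations(data) if config.include_initial_qss
               else None)
    rng = np.random.default_rng(config.seed)
    boot_idx = (rng.integers(0, n_cells, (config.n_boot, n_cells))
                if config.n_boot else None)

    offsets = np.linspace(-1.0, 1.0, config.points)
    mid = config.points // 2
    best_global = (-np.inf, None, None)  # (ll, svec, per-transition ll)
    converged = False
    boundary = None
    it = 0
    for it in range(1, config.max_iterations + 1):
        axes = [center[d] + offsets * span[d] for d in range(6)]
        combos = list(itertools.product(*(range(config.points),) * 6))
        lls = np.full(len(combos), -np.inf)
        per_ll = {}
        per_init = {}
        for ci, combo in enumerate(combos):
            svec = np.array([axes[d][combo[d]] for d in range(6)])
            try:
                theta = _theta_from_vec(_from_search(svec))
            except ValueError:
                continue
            ll_t = transition_loglik(data, theta, config, per_transition=True)
            lls[ci] = ll_t.sum()
            per_ll[ci] = ll_t
            if init_tx is not None:
                init_ll = _initial_state_loglik(theta, *init_tx)
                per_init[ci] = init_ll
                lls[ci] += init_ll.sum()
        best_ci = int(np.argmax(lls))
        best_combo = combos[best_ci]
        best_svec = np.array([axes[d][best_combo[d]] for d in range(6)])
        if lls[best_ci] > best_global[0]:
            best_global = (lls[best_ci], best_svec, per_ll[best_ci])

        interior = [best_combo[d] == mid for d in range(6)]
        # convergence: interior optimum, neighbor LL gaps within bootstrap CI
        if all(interior) and boot_idx is not None:
            best_cells = _cell_sums(per_ll[best_ci], cid, n_cells)
            if init_tx is not None:
                best_cells = best_cells + per_init[best_ci]
            within = True
            for d in range(6):
                for step in (-1, 1):
                    nb = list(best_combo)
                    nb[d] += step
                    nb_ci = combos.index(tuple(nb))
                    if not np.isfinite(lls[nb_ci]):
                        continue
                    nb_cells = _cell_sums(per_ll[nb_ci], cid, n_cells)
                    if init_tx is not None:
                        nb_cells = nb_cells + per_init[nb_ci]
                    diff = best_cells - nb_cells
                    boot = np.sum(diff[boot_idx], axis=1)
                    if np.percentile(boot, 2.5) > 0:
                        within = False
                        break
                if not within:
                    break
            if within:
                center = best_svec
                converged = True
                break
        center = best_svec
        span /= config.halving_factor
        if np.all(span < config.min_span):
            converged = all(interior)
            break
    else:
        it = config.max_iterations
    if not converged:
        edges = [
            _PARAM_ORDER[d] for d in range(6)
            if best_global[1] is not None and abs(
                best_global[1][d] - center[d]) >= span[d] * 0.99
        ]
        boundary = ",".join(edges) if edges else None
    return best_global, it, converged, boundary


def fit_mpsr(data: TransitionData, config: FitConfig | None = None,
             n_boot_theta: int = 0) -> FitResult:
    """Fit the six MP-SR parameters by interval-halving grid search.

    ``n_boot_theta`` > 0 additionally refits bootstrap resamples of cells
    (warm-started near the point estimate) for percentile CIs of theta.
    """
    config = config or FitConfig()
    lo = np.array([config.grid[k][0] for k in _PARAM_ORDER])
    hi = np.array([config.grid[k][1] for k in _PARAM_ORDER])
    s_lo, s_hi = _to_search(lo), _to_search(hi)
    center = (s_lo + s_hi) / 2.0
    span = (s_hi - s_lo) / 2.0

    (ll, svec, ll_t), iters, converged, boundary = _grid_search(
        data, config, center.copy(), span.copy())
    # contraction restarts: re-run the halving around the incumbent with a
    # reduced span.  The fresh grid geometry frees optima frozen on dyadic
    # points of an earlier contraction; stop once the gain is negligible.
    for _ in range(config.n_restarts):
        (ll_r, svec_r, ll_t_r), it_r, conv_r, bnd_r = _grid_search(
            data, config, svec.copy(), span * config.restart_span_frac)
        iters += it_r
        if ll_r > ll:
            improved = ll_r - ll > 0.05
            ll, svec, ll_t = ll_r, svec_r, ll_t_r
            converged, boundary = conv_r, bnd_r
            if not improved:
                break
        else:
            break
    if config.simplex_polish:
        # derivative-free simplex descent from the grid optimum: the
        # axis-aligned contraction freezes on the curved (beta, a, kappa,
        # eta0) likelihood valley, whose floor only coordinated moves follow
        from scipy import optimize as _opt

        def _negll(sv):
            try:
                th = _theta_from_vec(_from_search(sv))
            except ValueError:
                return 1e15
            return -transition_loglik(data, th, config)

        res = _opt.minimize(_negll, svec, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6,
                                     "fatol": 1e-4})
        if -res.fun > ll:
            ll, svec = -res.fun, res.x
            ll_t = transition_loglik(
                data, _theta_from_vec(_from_search(svec)), config,
                per_transition=True)
    theta_hat = _theta_from_vec(_from_search(svec))
    floored = int(np.sum(ll_t <= _LOG_FLOOR + 1e-9))

    ci = {}
    if n_boot_theta > 0:
        rng = np.random.default_rng(config.seed + 1)
        cells = np.unique(data.cell_ids)
        draws = []
        for b in range(n_boot_theta):
            chosen = rng.choice(cells, size=cells.size, replace=True)
            parts = [data.subset(data.cell_ids == c) for c in chosen]
            boot_data = TransitionData(
                np.concatenate([np.full(p.n, i) for i, p in enumerate(parts)]),
                np.concatenate([p.t0 for p in parts]),
                np.concatenate([p.x0 for p in parts]),
                np.concatenate([p.t1 for p in parts]),
                np.concatenate([p.x1 for p in parts]),
            )
            warm = FitConfig(**{**config.__dict__,
                                "max_iterations": 10, "n_boot": 0,
                                "seed": config.seed + 100 + b})
            (ll_b, svec_b, _), _, _, _ = _grid_search(
                boot_data, warm, svec.copy(), span / 8.0)
            draws.append(_from_search(svec_b))
        draws = np.asarray(draws)
        for d, name in enumerate(_PARAM_ORDER):
            ci[name] = tuple(np.percentile(draws[:, d], [2.5, 97.5]))

    return FitResult(
        theta_hat=theta_hat, loglik=float(ll), ci=ci, iterations=iters,
        converged=converged, n_transitions=data.n, boundary=boundary,
        floored_transitions=floored,
    )
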