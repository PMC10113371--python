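"""Core definitions of the membrane-potential saturating-repair (MP-SR) model.

The model describes membrane damage ``X`` (log normalized PI uptake rate, in
units of kBT) of a starving cell as a one-dimensional stochastic process

    dX/dt = eta0 + eta*t - beta * f(X) + sqrt(2*sigma) * xi,

where damage production rises linearly with age ``t`` while removal
``beta*f(X)`` saturates in ``X`` through the two-state partition function
``f(X) = e^{aX} / (e^{aX} + e^{a*kappa})``.  On the fast timescale of damage
turnover the population distribution of ``X`` at a fixed age is the Boltzmann
form ``P(X) ~ exp(-U(X, t)/sigma)`` of the frozen-age potential ``U``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "MPSRParams",
    "DeathRule",
    "NoQuasiSteadyStateError",
    "WILDTYPE_PARAMS",
    "removal_fraction",
    "drift",
    "drift_dx",
    "potential",
    "potential_and_density",
    "qss_shape_parameters",
    "qss_rvs",
    "params_to_json",
    "params_from_json",
]


class NoQuasiSteadyStateError(ValueError):
    """Raised when the frozen-age potential is non-confining.

    The Boltzmann quasi-steady density exists only while
    ``0 < eta0 + eta*t < beta``; outside that range the potential has no
    normalizable minimum and the quasi-steady approximation breaks down.
    """


@dataclass(frozen=True)
class MPSRParams:
    """The six MP-SR model parameters.

    Parameters
    ----------
    eta0 : float
        Constant damage-production offset, kBT/h (accounts for the unknown
        biological age at the start of observation).
    eta : float
        Production slope with age, kBT/h^2.
    beta : float
        Maximal damage-removal rate, kBT/h.
    sigma : float
        White-noise intensity, (kBT)^2/h.
    a : float
        Removal cooperativity, 1/kBT.
    kappa : float
        Removal half-saturation point, kBT: ``f(kappa) = 1/2``.
    """

    eta: float
    beta: float
    sigma: float
    a: float
    kappa: float
    eta0: float = 0.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v!r}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.eta < 0 or self.eta0 < 0:
            raise ValueError("eta and eta0 must be >= 0")

    def production_rate(self, t):
        """Age-dependent damage production rate ``eta0 + eta*t``."""
        return self.eta0 + self.eta * np.asarray(t, dtype=float)

    def replace(self, **kwargs) -> "MPSRParams":
        d = asdict(self)
        d.update(kwargs)
        return MPSRParams(**d)


@dataclass(frozen=True)
class DeathRule:
    """Death as first passage of damage across a threshold ``x_c`` (kBT)."""

    x_c: float = 50.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_c) and self.x_c > 0):
            raise ValueError("x_c must be finite and > 0")


#: Maximum-likelihood wildtype parameter set (starved E. coli, PI-uptake damage).
WILDTYPE_PARAMS = MPSRParams(
    eta=5.1e-3, beta=1.12, sigma=0.157, a=0.33, kappa=0.29, eta0=0.36
)


def removal_fraction(x, params: MPSRParams):
    """Saturating removal fraction ``f(x) = e^{ax} / (e^{ax} + e^{a*kappa})``.

    Strictly increasing in ``x``, bounded in (0, 1), with ``f(kappa) = 1/2``.
    Computed as a logistic in ``a*(x - kappa)`` for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    return expit(params.a * (x - params.kappa))


def drift(x, t, params: MPSRParams):
    """Deterministic drift ``G(x, t) = eta0 + eta*t - beta*f(x)`` in kBT/h."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    return params.production_rate(t) - params.beta * removal_fraction(x, params)


def drift_dx(x, t, params: MPSRParams):
    """Derivative of the drift with respect to damage, ``dG/dx = -beta*a*f(1-f)``."""
    f = removal_fraction(x, params)
    return -params.beta * params.a * f * (1.0 - f)


def qss_shape_parameters(t, params: MPSRParams) -> tuple[float, float]:
    """GB2 shape parameters ``(p, q)`` of the frozen-age damage distribution.

    At age ``t`` the quasi-steady density of uptake ``Z = e^X`` is GB2 with
    ``p = (eta0 + eta*t)/(a*sigma)`` and ``q = (beta - eta0 - eta*t)/(a*sigma)``
    (scale ``b = e^kappa``, cooperativity ``a``).

    Raises
    ------
    NoQuasiSteadyStateError
        If the production rate at ``t`` is not inside ``(0, beta)``.
    """
    eta_t = float(params.production_rate(t))
    if not (0.0 < eta_t < params.beta):
        raise NoQuasiSteadyStateError(
            f"no quasi-steady state at t={t}: production rate {eta_t:.4g} "
            f"outside (0, beta={params.beta:.4g})"
        )
    p = eta_t / (params.a * params.sigma)
    q = (params.beta - eta_t) / (params.a * params.sigma)
    return p, q


def potential(x, t, params: MPSRParams):
    """Frozen-age potential ``U(x, t)`` with ``-dU/dx = drift``; ``U(kappa, t) = 0``.

    ``U(x, t) = (beta/a) * ln(e^{a*kappa} + e^{a*x}) - (eta0 + eta*t)*x``,
    shifted so that ``U(kappa, t) = 0``.  Units (kBT)^2 (the SDE's natural
    energy-squared scale, since sigma carries (kBT)^2/h).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    a, kap = params.a, params.kappa
    eta_t = params.production_rate(t)
    u = (params.beta / a) * np.logaddexp(a * kap, a * x) - eta_t * x
    u0 = (params.beta / a) * np.logaddexp(a * kap, a * kap) - eta_t * kap
    return u - u0


def potential_and_density(t, params: MPSRParams, x_grid):
    """Potential values and normalized quasi-steady density on ``x_grid``.

    Returns ``(U, density)`` where ``density = exp(-U/sigma)`` normalized to
    unit trapezoid integral over the grid.

    Raises
    ------
    NoQuasiSteadyStateError
        If the potential is non-confining at age ``t`` (production rate
        outside ``(0, beta)``), in which case ``exp(-U/sigma)`` is not
        normalizable.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.ndim != 1 or x_grid.size < 2 or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be a strictly increasing 1-D array")
    qss_shape_parameters(t, params)  # raises if non-confining
    u = potential(x_grid, t, params)
    log_dens = -u / params.sigma
    log_dens -= log_dens.max()  # avoid overflow; constant cancels
    dens = np.exp(log_dens)
    z = np.trapezoid(dens, x_grid)
    if not (np.isfinite(z) and z > 0):
        raise NoQuasiSteadyStateError("density not normalizable on this grid")
    return u, dens / z


def qss_rvs(t, params: MPSRParams, size, rng):
    """Draw damage values ``X`` from the quasi-steady density at age ``t``.

    Uses the exact GB2 representation of the uptake ``Z = e^X``:
    ``(Z/b)^a ~ betaprime(p, q)`` with ``b = e^kappa``.
    """
    p, q = qss_shape_parameters(t, params)
    y = stats.betaprime.rvs(p, q, size=size, random_state=rng)
    return params.kappa + np.log(y) / params.a


def params_to_json(params: MPSRParams, rule: DeathRule | None = None) -> str:
    """Serialize parameters (and optionally the death threshold) to flat JSON."""
    d = {
        "units": "eta0 kBT/h; eta kBT/h^2; beta kBT/h; sigma (kBT)^2/h; "
        "a 1/kBT; kappa kBT; x_c kBT",
        "eta0": params.eta0,
        "eta": params.eta,
        "beta": params.beta,
        "sigma": params.sigma,
        "a": params.a,
        "kappa": params.kappa,
    }
    if rule is not None:
        d["x_c"] = rule.x_c
    return json.dumps(d, indent=1)


def params_from_json(text: str) -> tuple[MPSRParams, DeathRule | None]:
    d = json.loads(text)
    params = MPSRParams(
        eta=d["eta"], beta=d["beta"], sigma=d["sigma"],
        a=d["a"], kappa=d["kappa"], eta0=d.get("eta0", 0.0),
    )
    rule = DeathRule(d["x_c"]) if "x_c" in d else None
    return params, rule
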