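"""Path simulation, first-passage sampling, and the Kramers escape rate."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from mpsr.core import DeathRule, MPSRParams, WILDTYPE_PARAMS, drift, qss_rvs
from mpsr.dist_fit import GB2Params, gb2_cdf
from mpsr.core import qss_shape_parameters
from mpsr.simulate import (
    BeyondKramersRegimeError,
    empirical_hazard,
    kramers_hazard,
    sample_first_passage,
    simulate_paths,
)


class TestSimulatePaths:
    def test_zero_noise_matches_ode_oracle(self, wildtype):
        p = wildtype.replace(sigma=1e-300)  # sigma=0 limit (sigma must be >0)
        ens = simulate_paths(p, x0_sampler=0.5, t0=20, t1=60, dt=0.01, n=1,
                             seed=0)
        sol = solve_ivp(lambda t, x: drift(x, t, wildtype), (20, ens.times[-1]),
                        [0.5], t_eval=ens.times, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(ens.paths[0] - sol.y[0])) < 1e-4

    def test_no_removal_closed_form(self):
        # beta=0, sigma=0: X(t) = c + eta0*(t-t0) + eta*(t^2-t0^2)/2
        p = MPSRParams(eta=4e-3, beta=1e-300, sigma=1e-300, a=0.3, kappa=0.0,
                       eta0=0.2)
        # beta must be > 0; use a negligible beta instead of exactly zero
        ens = simulate_paths(p, x0_sampler=1.0, t0=0, t1=50, dt=0.05, n=1,
                             seed=0)
        t = ens.times
        expected = 1.0 + 0.2 * t + 4e-3 * t**2 / 2
        assert np.allclose(ens.paths[0], expected, atol=1e-9)

    def test_frozen_age_ensemble_matches_qss_density(self, wildtype):
        """Long-run frozen-parameter ensemble vs the Boltzmann density."""
        t_frozen = 40.0
        ens = simulate_paths(wildtype, "qss", t0=t_frozen, t1=t_frozen + 30,
                             dt=0.05, n=10_000, seed=3, freeze_age=True)
        p, q = qss_shape_parameters(t_frozen, wildtype)
        g = GB2Params(a=wildtype.a, b=np.exp(wildtype.kappa), p=p, q=q)
        ks = kstest(np.exp(ens.paths[:, -1]), lambda z: gb2_cdf(z, g))
        assert ks.statistic < 0.02

    def test_reproducible_and_n_invariant(self, wildtype):
        a = simulate_paths(wildtype, "qss", n=20, seed=5, t1=25.0)
        b = simulate_paths(wildtype, "qss", n=20, seed=5, t1=25.0)
        c = simulate_paths(wildtype, "qss", n=40, seed=5, t1=25.0)
        assert np.array_equal(a.paths, b.paths)
        # per-cell seed streams: adding cells does not change existing paths
        assert np.allclose(a.paths, c.paths[:20])

    def test_coarse_dt_rejected(self, wildtype):
        with pytest.raises(ValueError):
            simulate_paths(wildtype, "qss", dt=1.0)

    def test_export_round_trip(self, wildtype, tmp_path):
        ens = simulate_paths(wildtype, "qss", n=5, t1=23.0, seed=1)
        csv, meta = tmp_path / "e.csv", tmp_path / "e.json"
        ens.write_csv(csv, meta)
        frame = ens.to_frame()
        assert len(frame) == 5 * ens.times.size
        assert meta.exists() and csv.exists()


class TestFirstPassage:
    def test_ballistic_crossing(self):
        # pure production at rate 1 from x0=0 to x_c=10: death at 10 h
        p = MPSRParams(eta=0.0, beta=1e-300, sigma=1e-9, a=0.3, kappa=0.0,
                       eta0=1.0)
        fp = sample_first_passage(p, DeathRule(10.0), x0_sampler=0.0, t0=0,
                                  horizon=40, dt=0.01, n=200, seed=0)
        assert fp.censored == 0
        assert fp.death_times.mean() == pytest.approx(10.0, abs=0.05)

    def test_drifted_brownian_mean_first_passage(self):
        # Wald: E[T] = (x_c - x0)/eta0 for drifted Brownian motion
        p = MPSRParams(eta=0.0, beta=1e-300, sigma=0.2, a=0.3, kappa=0.0,
                       eta0=0.5)
        fp = sample_first_passage(p, DeathRule(5.0), x0_sampler=0.0, t0=0,
                                  horizon=200, dt=0.02, n=2000, seed=1)
        assert fp.censored == 0
        expected = 5.0 / 0.5
        se = fp.death_times.std(ddof=1) / np.sqrt(fp.death_times.size)
        assert abs(fp.death_times.mean() - expected) < 4 * se + 0.05

    def test_censored_counted_not_dropped(self, wildtype):
        fp = sample_first_passage(wildtype, DeathRule(3.0), t0=20,
                                  horizon=60, dt=0.05, n=300, seed=2)
        assert fp.n == 300
        assert fp.censored > 0
        assert np.all(fp.death_times <= 60.0)
        assert np.all(fp.death_times >= 20.0)

    def test_zero_absorption_warns_and_hazard_refuses(self, wildtype):
        with pytest.warns(UserWarning):
            fp = sample_first_passage(wildtype, DeathRule(50.0), t0=20,
                                      horizon=30, dt=0.05, n=50, seed=0)
        assert fp.censored == 50
        with pytest.raises(ValueError):
            empirical_hazard(fp)

    def test_gompertz_signature_log_hazard_linear(self, wildtype):
        """Barrier escape: empirical log-hazard approximately linear in age."""
        rule = DeathRule(3.0)
        fp = sample_first_passage(wildtype, rule, t0=20, horizon=110,
                                  dt=0.05, n=4000, seed=4)
        hz = empirical_hazard(fp, bin_h=5.0)
        hz = hz[(hz["events"] >= 10) & (hz["age_h"] < 95)]
        lnh = np.log(hz["hazard"])
        coef = np.polyfit(hz["age_h"], lnh, 1)
        resid = lnh - np.polyval(coef, hz["age_h"])
        r2 = 1 - resid.var() / lnh.var()
        assert coef[0] > 0
        assert r2 > 0.8


class TestKramersHazard:
    def test_hazard_rises_with_age(self, wildtype):
        rule = DeathRule(3.0)
        rates = kramers_hazard(wildtype, rule, np.array([30.0, 50.0, 70.0]))
        assert np.all(np.diff(rates) > 0)

    def test_log_hazard_linear_where_barrier_linear(self, wildtype):
        # a high threshold keeps the barrier (hence ln-hazard) linear in age
        rule = DeathRule(4.0)
        ts = np.linspace(30, 70, 9)
        lnh = np.log(kramers_hazard(wildtype, rule, ts))
        coef = np.polyfit(ts, lnh, 1)
        resid = lnh - np.polyval(coef, ts)
        assert 1 - resid.var() / lnh.var() > 0.95

    def test_matches_monte_carlo_within_factor_two(self, wildtype):
        """Frozen-age escape at a ~4 sigma barrier: rate vs Monte Carlo."""
        t_frozen, rule = 45.0, DeathRule(4.5)
        kr = kramers_hazard(wildtype, rule, t_frozen)
        ens = simulate_paths(wildtype, "qss", t0=t_frozen, t1=t_frozen + 80,
                             dt=0.05, n=20_000, seed=9, rule=rule,
                             freeze_age=True)
        ct = ens.crossing_times
        started_below = ct != t_frozen
        burn = t_frozen + 10.0  # let the sub-threshold population equilibrate
        dead = np.isfinite(ct) & started_below & (ct > burn)
        at_risk = (~np.isfinite(ct) | (ct > burn)) & started_below
        exposure = np.where(np.isfinite(ct), np.clip(ct - burn, 0, None),
                            70.0)[at_risk].sum()
        rate = dead.sum() / exposure
        assert 0.5 < kr / rate < 2.0

    def test_beyond_regime_raises(self, wildtype):
        t_bad = (wildtype.beta - wildtype.eta0) / wildtype.eta + 5.0
        with pytest.raises(BeyondKramersRegimeError):
            kramers_hazard(wildtype, DeathRule(3.0), t_bad)
        # minimum above threshold at late ages
        with pytest.raises(BeyondKramersRegimeError):
            kramers_hazard(wildtype, DeathRule(0.5), 120.0)
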