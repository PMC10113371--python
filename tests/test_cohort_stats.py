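"""Cross-sectional statistics, initial-condition analysis, and twilight."""

import numpy as np
import pandas as pd
import pytest

from mpsr.cohort_stats import (
    autocorrelation,
    cross_sectional_stats,
    initial_condition_analysis,
    remaining_lifespan_view,
    twilight,
    windows_from_ensemble,
)


def _windows(values_by_age, lifespans=None):
    """Build tidy tables from {age: {cell_id: value}} (value = damage X)."""
    rows = []
    for age, vals in values_by_age.items():
        for cid, x in vals.items():
            rows.append((cid, age, np.exp(x), x, True))
    win = pd.DataFrame(rows, columns=["cell_id", "window_center_h", "uptake",
                                      "damage_kBT", "valid"])
    cells = sorted(win["cell_id"].unique())
    if lifespans is None:
        lifespans = {c: 1000.0 for c in cells}
    life = pd.DataFrame({
        "cell_id": cells,
        "lifespan_h": [lifespans[c] for c in cells],
        "censored": [False] * len(cells),
    })
    return win, life


class TestCrossSectionalStats:
    def test_identical_values_degenerate(self):
        win, life = _windows({30.0: {i: 1.7 for i in range(20)}})
        (sec,) = cross_sectional_stats(win, life, [30.0], "damage", n_boot=50)
        assert sec.stats["sd"][0] == 0.0
        assert sec.stats["cv"][0] == 0.0
        assert sec.stats["skewness"][0] == 0.0

    def test_against_direct_formula_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        win, life = _windows({30.0: {i: np.log(v) for i, v in
                                     enumerate(values)}})
        (sec,) = cross_sectional_stats(win, life, [30.0], "uptake",
                                       n_boot=10, seed=0)
        n = len(values)
        mean = values.sum() / n
        sd = np.sqrt(((values - mean) ** 2).sum() / (n - 1))
        m3 = ((values - mean) ** 3).mean()
        m2 = ((values - mean) ** 2).mean()
        g1 = m3 / m2**1.5
        adj_skew = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        assert sec.stats["mean"][0] == pytest.approx(mean)  # 22
        assert sec.stats["sd"][0] == pytest.approx(sd)
        assert sec.stats["cv"][0] == pytest.approx(sd / mean)
        assert sec.stats["skewness"][0] == pytest.approx(adj_skew)

    def test_dead_cells_excluded(self):
        win, life = _windows(
            {30.0: {0: 1.0, 1: 1.0, 2: 5.0}},
            lifespans={0: 100.0, 1: 100.0, 2: 25.0},  # cell 2 dead before 30
        )
        (sec,) = cross_sectional_stats(win, life, [30.0], "damage", n_boot=10)
        assert sec.n_alive == 2
        assert sec.stats["mean"][0] == pytest.approx(1.0)

    def test_unknown_age_rejected(self):
        win, life = _windows({30.0: {0: 1.0, 1: 2.0}})
        with pytest.raises(ValueError, match="window grid"):
            cross_sectional_stats(win, life, [31.0], "damage", n_boot=10)

    def test_bootstrap_se_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        ses = []
        for n in (50, 800):
            win, life = _windows(
                {30.0: dict(enumerate(rng.normal(1.0, 0.5, n)))})
            (sec,) = cross_sectional_stats(win, life, [30.0], "damage",
                                           n_boot=300, seed=1)
            ses.append(sec.stats["mean"][1])
        assert ses[1] < ses[0] / 2.5  # ~ 1/sqrt(16) = 1/4


class TestAutocorrelation:
    def test_persistent_heterogeneity_gives_unity(self):
        vals = {i: float(i) for i in range(12)}
        win, life = _windows({30.0: vals, 37.0: vals})
        r, se, n = autocorrelation(win, life, 30.0, 7.0, n_boot=20)
        assert r == pytest.approx(1.0)
        assert n == 12

    def test_shuffled_values_uncorrelated(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = rng.permutation(x)
        win, life = _windows({30.0: dict(enumerate(x)),
                              37.0: dict(enumerate(y))})
        r, _, n = autocorrelation(win, life, 30.0, 7.0, n_boot=20)
        assert abs(r) < 2.0 / np.sqrt(n)

    def test_too_few_shared_cells(self):
        win, life = _windows({30.0: {0: 1.0, 1: 2.0}, 37.0: {0: 1.0, 2: 2.0}})
        with pytest.raises(ValueError, match="fewer than 3"):
            autocorrelation(win, life, 30.0, 7.0)


class TestInitialConditions:
    def test_perfect_negative_rank_correlation(self):
        n = 40
        uptake = np.linspace(0.5, 3.0, n)
        life = pd.DataFrame({"cell_id": range(n),
                             "lifespan_h": 100.0 - 20 * uptake,
                             "censored": False})
        init = pd.DataFrame({"cell_id": range(n), "initial_uptake": uptake})
        rep = initial_condition_analysis(life, init)
        assert rep.spearman["initial_uptake"][0] == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        n = 100
        uptake = rng.lognormal(0, 0.5, n)
        lifespan = 80 + rng.normal(0, 10, n) - 5 * uptake
        life = pd.DataFrame({"cell_id": range(n), "lifespan_h": lifespan,
                             "censored": False})
        r1 = initial_condition_analysis(
            life, pd.DataFrame({"cell_id": range(n),
                                "initial_uptake": uptake}))
        r2 = initial_condition_analysis(
            life, pd.DataFrame({"cell_id": range(n),
                                "initial_uptake": uptake**3}))
        assert r1.spearman["initial_uptake"][0] == pytest.approx(
            r2.spearman["initial_uptake"][0])

    def test_group_split_sizes(self):
        n = 60
        rng = np.random.default_rng(2)
        uptake = np.concatenate([rng.uniform(0.2, 3.5, n - 6),
                                 rng.uniform(4.5, 9.0, 6)])
        life = pd.DataFrame({"cell_id": range(n),
                             "lifespan_h": rng.uniform(40, 110, n),
                             "censored": False})
        rep = initial_condition_analysis(
            life, pd.DataFrame({"cell_id": range(n),
                                "initial_uptake": uptake}), split=4.0)
        assert rep.r_high[1] == 6
        assert rep.r_low[1] == n - 6
        assert rep.r_high[1] + rep.r_low[1] == rep.n_all

    def test_independent_covariates_explain_little(self):
        rng = np.random.default_rng(7)
        n = 500
        life = pd.DataFrame({"cell_id": range(n),
                             "lifespan_h": rng.normal(80, 15, n),
                             "censored": False})
        init = pd.DataFrame({"cell_id": range(n),
                             "initial_uptake": rng.lognormal(0, 0.4, n)})
        cov = pd.DataFrame({
            "cell_id": range(n),
            "initial_size_um": rng.lognormal(1, 0.2, n),
            "division_times_h": ["1.0;3.0"] * n,
            "n_divisions": rng.poisson(1.5, n),
        })
        rep = initial_condition_analysis(life, init, cov)
        assert rep.regression_r2_all < 0.05

    def test_too_few_cells_rejected(self):
        life = pd.DataFrame({"cell_id": range(5), "lifespan_h": 50.0,
                             "censored": False})
        init = pd.DataFrame({"cell_id": range(5),
                             "initial_uptake": np.arange(5) + 0.5})
        with pytest.raises(ValueError):
            initial_condition_analysis(life, init)


class TestRemainingLifespan:
    def test_identical_cells_zero_dispersion(self):
        ages = [23.0, 30.0, 37.0]
        win, life = _windows(
            {a: {0: 0.1 * a, 1: 0.1 * a} for a in ages},
            lifespans={0: 50.0, 1: 50.0},
        )
        view = remaining_lifespan_view(win, life)
        assert np.allclose(view["sd"], 0.0)

    def test_dispersion_falls_near_death_in_model_cohort(self, wildtype):
        from mpsr.core import DeathRule
        from mpsr.simulate import simulate_paths
        ens = simulate_paths(wildtype, "qss", t0=20, t1=120, dt=0.05,
                             n=1500, seed=6, rule=DeathRule(3.0))
        ages = np.arange(23.0, 110.0, 7.0)
        win, life = windows_from_ensemble(ens, ages)
        view = remaining_lifespan_view(win, life)
        sd_near = view[view["time_before_death_h"] < 10]["sd"].iloc[0]
        sd_far = view[view["time_before_death_h"] > 38]["sd"].iloc[0]
        assert sd_near < sd_far

    def test_shuffled_death_times_destroy_convergence(self, wildtype):
        from mpsr.core import DeathRule
        from mpsr.simulate import simulate_paths
        ens = simulate_paths(wildtype, "qss", t0=20, t1=120, dt=0.05,
                             n=1500, seed=6, rule=DeathRule(3.0))
        ages = np.arange(23.0, 110.0, 7.0)
        win, life = windows_from_ensemble(ens, ages)
        rng = np.random.default_rng(0)
        shuffled = life.copy()
        shuffled["lifespan_h"] = rng.permutation(shuffled["lifespan_h"].values)
        view = remaining_lifespan_view(win, shuffled)
        sd_near = view[view["time_before_death_h"] < 10]["sd"].iloc[0]
        sd_far = view[view["time_before_death_h"] > 38]["sd"].iloc[0]
        assert sd_near > 0.6 * sd_far  # no systematic funneling


class TestTwilight:
    def test_identical_cells_zero_slope(self):
        t = np.arange(0.0, 50.0)
        x = 0.08 * t
        series = [(t, x)] * 12
        res = twilight(series, np.full(12, 45.0), threshold_x=2.0)
        assert res["slope"] == pytest.approx(0.0)

    def test_threshold_above_death_rejected(self):
        t = np.arange(0.0, 50.0)
        series = [(t, 0.1 * t)] * 12
        with pytest.raises(ValueError, match="below the death threshold"):
            twilight(series, np.full(12, 45.0), threshold_x=3.5, x_c=3.0)

    def test_too_few_crossings_rejected(self):
        t = np.arange(0.0, 50.0)
        series = [(t, np.zeros_like(t))] * 12
        with pytest.raises(ValueError, match="fewer than 10"):
            twilight(series, np.full(12, 45.0), threshold_x=2.0)

    def test_model_cohort_twilight_shortens_with_age(self, wildtype):
        from mpsr.core import DeathRule
        from mpsr.simulate import simulate_paths
        rule = DeathRule(3.0)
        ens = simulate_paths(wildtype, "qss", t0=20, t1=140, dt=0.05,
                             n=500, seed=8, rule=rule)
        ct = ens.crossing_times
        series = [(ens.times, ens.paths[i]) for i in range(ens.n_cells)]
        res = twilight(series, ct, threshold_x=2.0, x_c=rule.x_c, seed=1)
        assert res["slope"] < 0
        assert res["ci"][1] < 0  # CI excludes zero
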