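# mpsr — stochastic membrane-damage dynamics and the timing of cell death

Genetically identical starving cells die at very different times. This
package implements a complete analysis of why, for cohorts of carbon-starved
bacteria whose membrane damage is tracked in individual cells over their
whole lives: from hourly PI (propidium-iodide) fluorescence traces, through
damage extraction and cross-sectional cohort statistics, to fitting and
simulating a stochastic model in which chance — not initial conditions —
generates the lifespan distribution.

The model at the core is the **membrane-potential saturating-repair (MP-SR)
model**: damage `X` (log normalized PI uptake rate, in kBT) follows

    dX/dt = η₀ + ηt − β·f(X) + √(2σ)·ξ,      f(X) = e^{aX} / (e^{aX} + e^{aκ})

— production rises linearly with age while removal saturates in damage, so
noise is amplified as cells age. At a frozen age the damage distribution is
the Boltzmann form `P(X) ∝ e^{−U(X,t)/σ}`; equivalently the uptake `e^X` is
GB2-distributed (generalized beta of the second kind) with shape ratio
`p/(p+q) = (η₀+ηt)/β` rising linearly with age. Death is the first passage
of `X` across a threshold, which yields an exponentially rising death
hazard (the Gompertz law) and a sigmoidal survival curve.

## Layout

```
src/mpsr/           the library
  core.py           parameters, drift, removal function, potential, quasi-steady density
  simulate.py       sample paths, first-passage death times, Kramers hazard
  synthetic.py      synthetic mother-machine cohorts with a truth ledger
  extraction.py     fluorescence -> uptake rate -> damage -> death calling
  cohort_stats.py   cross-sectional stats, autocorrelation, initial conditions, twilight
  survival.py       survivorship, cumulative hazard, Gompertz slope, cohort comparison
  dist_fit.py       15-family marginal fits, GB2 likelihood, GB2 -> MP-SR mapping
  inference.py      transition likelihoods (simulated & Gaussian), interval-halving fit
  pipeline.py       orchestration with manifest, per-stage seeds, resume
analysis/           numbered narrative drivers writing results/
scripts/acceptance.py   the parameter-recovery experiment (see below)
docs/methods.md     model, estimators, numerical choices, limitations
tests/              pytest suite
```

## Worked example

Generate a 635-cell synthetic cohort at the published wildtype parameters
and push it through the full chain:

```
python analysis/01_generate_cohort.py
python analysis/02_extract_damage.py
python analysis/03_cohort_statistics.py
python analysis/04_survival_analysis.py
python analysis/05_marginal_distributions.py
python analysis/07_reduced_stress_response.py
```

Output of the first two steps (seed 0):

```
generated 635 cells -> .../results/cohort/traces.csv
  deaths by 120 h: 631 (99%)
  mean lifespan 73.8 h, CV 0.26, 5%/95% quantiles 42/102 h
  high-initial-damage fraction: 4.1%
extracted 635 cells, 65% of windows valid
  called deaths: 635; lifespan error vs latent truth: median -0.37 h, within 1 h 69%
```

The cohort dies with a sigmoidal survival curve (mean ≈74 h, CV 0.26,
quantiles close to the experimental 42/106 h); ~4% of cells start with
high damage, and with 6% measurement noise the called death times sit
within ±1 h of the latent truth for ~70% of cells (≥99% when noise is
switched off). Later steps report the aging signatures — CV of uptake
falling with age, damage autocorrelation rising, twilight (remaining life
after a sub-lethal damage crossing) shortening with age, survivorship with
an exponential cumulative-hazard regime — and the in-silico
reduced-stress-response comparison (doubling η shortens life by ~half,
steepens the Gompertz slope, and leaves the normalized-age survival
overlay nearly unchanged).

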