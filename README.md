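# circmort

Circadian analysis of in-hospital time of death.

Whether deaths cluster at particular clock hours matters for chronobiology
(is there an endogenous ~24 h rhythm in dying?) and for health-care delivery
(do recorded death times instead reflect ward routines such as shift
changes?).  `circmort` packages the statistical pipeline for that question,
aimed at epidemiologists and biostatisticians working with death-registry
extracts: one row per death with a time of day, cause category, age and sex.

## Methods at the core

* **Circular encoding and a sinusoidal circadian test.**  A time of death
  `t` (minutes) becomes the angle `θ = 2πt/1440`.  With mean resultant
  length `R̄ = ‖(mean cos θᵢ, mean sin θᵢ)‖`, the Rayleigh-type statistic is
  `Z = nR̄²` with first-order p-value `P = e^(−Z)` (a higher-order corrected
  formula is available).  This tests uniformity against a unimodal
  sinusoidal rhythm; a cosinor log-linear likelihood-ratio variant on hourly
  counts is included as a sensitivity analysis.
* **Excess-mass test of unimodality.**  The nonparametric statistic
  `Δ = max_{λ>0} [E₂(λ) − E₁(λ)]`, where `E_k(λ)` is the greatest empirical
  mass in excess of `λ×length` achievable by `k` disjoint intervals.  It is
  computed exactly as twice Hartigan's dip (greatest-convex-minorant /
  least-concave-majorant algorithm) and calibrated by a smoothed bootstrap
  from the kernel density estimate at the critical bandwidth — the smallest
  bandwidth at which the estimate is unimodal.
* **Prevalence-ratio regression.**  For each cause, the binary outcome
  `Y = 1{death from that cause}` is fitted over all deaths by the log-link
  working model `log E[Y] = β₀ + Σ_h β_h 1{hour=h} + β_sex 1{male} +
  β_age·age` with heteroskedasticity-robust (sandwich) variance — the
  modified-Poisson prevalence-ratio estimator.  Hour 0:00–0:59 is the
  reference; PR = `exp(β)` with 95% Wald intervals.
* **Restricted cubic splines.**  Three-knot natural cubic splines (linear
  beyond the boundary knots, knots at the 10th/50th/90th count-weighted
  percentiles by default) summarise the 24 hourly counts for the standard
  scatter-plus-smooth figure.
* **Synthetic registry generator.**  Times of day follow a mixture of a
  uniform component and a unimodal circular component — by default the
  cardioid `f(θ) = (1 + 2ρ cos(θ−μ))/2π`, whose density is exactly a
  sinusoid and whose mean resultant length is `ρ` — with demographics
  (cause mix, per-cause age and sex) matching a large in-hospital registry
  profile, and optional count-heaping at chosen hours to mimic registration
  artifacts.  Every downstream method can therefore be validated against
  known ground truth.

## Worked example

Simulate 100,000 deaths with *no* circadian rhythm (`ρ = 0`) but with
registration heaping at the 6 am and 8 pm shift changes, then run the
pipeline on the cancer deaths:

```python
from circmort import (SimConfig, sample_records, rayleigh_test,
                      excess_mass_test, fit_pr)

rec = sample_records(SimConfig(n=100_000, rho=0.0,
                               heap_hours=[(6, 1.24), (20, 1.22)], seed=42))
cancer = rec[rec["cause"] == "cancer"]["time_of_day"].to_numpy()

res = rayleigh_test(cancer)
em  = excess_mass_test(cancer, n_boot=500, seed=0)
pr  = fit_pr(rec, "cancer").table
```

which prints (via f-strings, exactly these values for this seed):

```
circadian test: Z = 1.06, P = 0.345  (n = 16533)
excess mass = 0.0107, P = 0.0020  (500 bootstrap replicates)
cancer 6 am PR = 1.04 (0.95-1.13)
sex (male vs female) PR = 1.06 (1.03-1.09)
```

Read: the sinusoidal circadian test correctly finds no 24 h rhythm
(P = 0.345), while the excess-mass test flags the departure from
unimodality created by the two registration heaps (Δ ≈ 0.011, small P) —
the characteristic signature of shift-change artifacts rather than biology.
The 6 am *prevalence ratio* for cancer stays near 1 because heaping inflates
deaths from all causes equally in that hour; the sex PR reflects the higher
male share among cancer deaths.

A command-line interface mirrors the library:

```bash
circmort simulate cohort.csv --n 100000 --rho 0.0 --seed 42
circmort circtest cohort.csv --cause cancer
circmort multimode cohort.csv --cause cancer --n-boot 500
circmort pr cohort.csv --cause cancer --cause pneumonia --out table.csv
circmort report cohort.csv out/        # figure + JSON summary of everything
```

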