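# Methods

This note records the statistical models implemented in `circmort`, the
choices made where the design was genuinely open, and what the synthetic
test-bed does and does not establish about real registry data.

## Circular encoding and the circadian test

Times of death are kept at minute resolution (registries rarely record
seconds) and mapped to angles `θ = 2πt/1440`, so the day is one turn of the
circle and midnight is the origin.  Hour bins are half-open `[h:00, h+1:00)`:
a death at exactly `h:00` belongs to bin `h`.

The circadian test is the classical resultant-length (Rayleigh-type) test of
circular uniformity against a unimodal alternative: `Z = nR̄²`, default
p-value `e^(−Z)`.  The default was chosen because all three (Z, P) pairs this
pipeline is meant to produce on registry data satisfy `P = e^(−Z)` to printed
precision, which pins the method down uniquely among the common variants; the
higher-order correction

    P = e^(−Z) · [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

is available as `method="corrected"` and differs only at order 1/n (at the
sample sizes of interest, beyond the third decimal).  Angles are computed
from minute-level times, not hour midpoints; no grouping correction is
applied for the minute discretisation (a 1/1440-cycle granularity perturbs
R̄ negligibly).  `cosinor_lrt` offers the other common reading of a
"parametric sinusoidal test" — a log-linear Poisson model of the 24 hourly
counts with one harmonic pair, 2-df likelihood-ratio test — as a clearly
labelled sensitivity method, not the default.

## Excess-mass test of unimodality

The statistic is `Δ = max_{λ>0}[E₂(λ) − E₁(λ)]` with
`E_k(λ) = sup Σⱼ (F_n(Cⱼ) − λ|Cⱼ|)` over k disjoint closed intervals.  It is
computed exactly through the identity `Δ = 2·dip(F_n)`, with the dip obtained
by the iterative GCM/LCM algorithm (O(n) after sorting, numba-compiled).  The
identity and the algorithm are verified in the test-suite against an
exhaustive oracle that enumerates all data-point-bounded interval pairs and
maximises over λ at the breakpoints of the two piecewise-linear envelopes —
an exact, independent computation feasible up to n ≈ 25.

Calibration follows the critical-bandwidth smoothed bootstrap: resamples are
drawn from the Gaussian KDE at the smallest bandwidth producing a unimodal
estimate (bisection to relative tolerance 1e-3, mode counting on a
2048-point grid), rescaled to preserve the sample variance; the p-value is
`(1 + #{Δ_b ≥ Δ_obs})/(n_boot + 1)` with `n_boot = 500` by default, so a
result with zero exceedances reports `P = 1/(n_boot+1)`, i.e. "< 0.002".
This calibration is mildly conservative (null rejection ≈ 0.02–0.04 at
α = 0.05 in the acceptance runs), which is the usual behaviour of the
critical-bandwidth bootstrap.

Clock times are circular, but the statistic is computed on the line
`[0, 1440)` by default — the natural reading of an off-the-shelf multimode
test applied to clock times; `circular=True` instead minimises Δ over all
cut points of the circle (gap midpoints of the sorted sample), the
principled variant for data with no natural origin.  Minute ties are broken
by seeded uniform jitter within ±0.5 minute (the excess-mass machinery
assumes continuous data); the jitter policy is recorded in the result's
`method_notes` and can be disabled.  A constant sample has Δ = 0 (its ECDF
is itself unimodal); any sample with ≥ 2 distinct values has Δ ≥ 1/n.

## Prevalence-ratio regression

Table-style prevalence ratios are estimated with the binary-outcome log-link
working model over all death records (outcome: died of the target cause),
fitted as a modified-Poisson regression with HC0 sandwich variance — the
standard prevalence-ratio estimator when outcomes are common and odds ratios
would mislead.  Covariates: 23 hour indicators (reference 0:00–0:59), sex,
and age entering linearly per year.  Wald 95% intervals use z = 1.96 with no
small-sample correction (registry n is enormous); no multiplicity adjustment
is applied across the 23 hour contrasts, which reports should state.  The
comparison group is "all other deaths", the only denominator available in a
death-only registry.  A `grouped` variant aggregates to (hour, sex, age)
cells with a log-exposure offset; it reproduces the same coefficients (the
likelihoods coincide) with cell-level robust variance, and serves as a
sensitivity check on the model's reading.  An hour with zero records drops
its indicator with a logged warning rather than failing.

## Restricted cubic splines

The hourly-count summary uses a three-knot restricted (natural) cubic
spline: basis `[1, x, s(x)]` with the standard truncated-cube construction
normalised by `(t₃−t₁)²`, linear beyond the boundary knots.  Knots default
to the 10th/50th/90th percentiles of the record-level hour distribution
(count-weighted) — the most widely used rule when knot positions are not
prespecified — and are overridable.  The fit is ordinary least squares on
counts: the curve is descriptive; a log-link Poisson option keeps fits
positive when counts are small.  The seam between hour 23 and hour 0 is
deliberately not stitched, matching the conventional non-periodic overlay.
Consequence (established by simulation): the fitted curve's peak recovers a
true acrophase to within ±2 h only when the acrophase lies in mid-day hours
(~9–15); peaks near midnight are not representable by a 3-parameter
non-periodic spline and migrate to the boundary.  Users who care about
near-midnight acrophases should rotate the time origin before fitting.

## Synthetic registry generator

The generator emulates: minute-resolution times from a
uniform/unimodal-circular mixture (cardioid by default, `ρ ≤ 0.5` enforced
for density non-negativity, von Mises for sharper peaks, with concentration
chosen so its mean resultant length equals `ρ`); cause shares 16.5% cancer,
6.1% ischemic heart disease, 26.0% pneumonia, remainder other; per-cause
truncated-normal ages centred at the registry medians 70/82/85 (SD 13/12/12
years, chosen to respect the registry ranges 18–108 / 19–113 / 18–117 — the
source profile reports only medians and ranges, so the SDs are this
package's realistic choice, and "other" uses centre 80, SD 14); per-cause
male shares 56.7% / 52.0% / 56.0% (54.0% for "other"); and optional
hour-level count heaping applied by acceptance–rejection thinning, so a
multiplier of 1.24 at hour 6 makes the hour-6 density 1.24× its base value.
Cardioid draws use exact rejection sampling; minutes are floored; one integer
seed spawns deterministic per-stage streams, so identical configs give
bit-identical cohorts.

What the generator does **not** emulate: reporting-delay dynamics,
resuscitation-driven time shifts, day-of-week or seasonal structure,
cause-misclassification, or correlation between demographics and time of
day.  Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under clean conditions, not that real registry data
meet those conditions.

## Problem sizes and numerical choices

Monte-Carlo studies in the test-suite and acceptance script use: 2,000
uniform samples of n = 500 for the type-I error of the circadian test; 500
cardioid (ρ = 0.2) samples for its power; 300 unimodal and 200 bimodal
(4 SD separation) samples of n = 300 with 200 bootstrap replicates for
excess-mass calibration; 200 replicates of n = 50,000 for prevalence-ratio
bias and coverage.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping a full run on one CPU in minutes.
Degenerate inputs are handled explicitly: empty circular samples and n < 2
tests raise; empty aggregation selections return zero counts; constant
samples give Δ = 0; zero-record causes are noted as omitted in reports
rather than raising.
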