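# Methods

## The question

Platform trials test several drugs against one shared placebo, with
arms entering the platform over time.  Regulators have suggested
allocating more patients to the shared control than to each drug arm.
This package quantifies, for binary mortality endpoints analyzed with
concurrent controls only, what a dynamic unequal allocation ratio does
to the type I error rate, group-specific and overall power, placebo
sample size and study duration — relative to equal allocation, to a
multi-arm trial, and to separate stand-alone trials.

## Trial model

**Time.**  Discrete months 0, 1, 2, …  The number of patients arriving
in the whole trial each month is Poisson(λ), λ ∈ {100, 200, 300, 400}
by default.  An arm with a continuous entry time t (irregular
staggering draws t ~ Uniform(0, m−1) for m drugs) first participates in
the allocation of month ⌊t⌋; arm 0 always enters at 0.  Nothing in the
analysis uses calendar time beyond the enrollment sequence, so dropout,
treatment duration and outcome latency are out of scope.

**Randomization.**  Patients are allocated one at a time, independently,
with probability proportional to the weights of the arms open at that
instant (per-patient randomization rather than permuted blocks; the
ratio is matched in expectation and mid-month arm closures are handled
naturally).  Drug arms carry weight 1.  The placebo weight is 1 (equal
designs), a fixed constant (the 2 of MAT(1:1:1:1:2)), or √k where k is
the number of drug arms currently enrolling (dynamic designs).  When an
arm reaches its cap it closes immediately and the weights are
re-evaluated before the next patient.  Internally a month is drawn as
one multinomial whenever no cap can be reached, and patient-by-patient
segments otherwise; the two are distributionally identical.

The √k choice deserves a note: it is the square-root allocation rule
(optimal for estimating k drug-placebo contrasts with a shared control
for a fixed total), it reduces to the 2:1 benchmark of the four-drug
multi-arm trial (√4 = 2), and it is the only dynamic weighting we found
consistent with the operating characteristics this simulator is
designed to reproduce — per-drug concurrent-control sizes near 2×435 at
slow accrual, and total placebo enrollment strictly between the
multi-arm and stand-alone extremes and increasing with the accrual
rate.  Proportional weighting (placebo weight k, i.e. half of all
accrual to the placebo once k ≥ 1) is available via
`AllocationRule(dynamic_exponent=1)` for sensitivity analyses.

**Caps and stopping.**  Every drug arm enrolls exactly 435 patients
(spec below).  A capped placebo (435 equal / 870 unequal MAT;
stand-alone controls) enrolls to its cap even if the drug arms finish
first, so planned totals (3480 / 2175 / 2610) are hit exactly.  The
platform-trial placebo is uncapped and closes the moment the last drug
arm fills.  Arrivals after all arms close are not enrolled.  The
stand-alone set is simulated as m independent two-arm trials, each with
its own Poisson stream at the same λ (per-trial accrual is not
otherwise identified; this only affects the stand-alone duration).

**Sample size.**  435 per drug arm comes from the pooled
normal-approximation two-proportion formula without continuity
correction at (p₁, p₂) = (5%, 10%), two-sided α = 5%, power 80%, 1:1
(434.4 → 435).  With a continuity correction the same inputs give
≈ 474, so the no-correction convention is used throughout, including in
the chi-squared test itself.

**Outcomes.**  Each patient dies independently with its arm's true
rate: placebo and ineffective drugs at RP ∈ {5, 7.5, 10, 12.5, 15}%,
effective drugs at RD = RP − 5 points.  Scenario s of the m+1
effectiveness scenarios makes the last s − 1 drugs effective.  Death
counts per arm-month are drawn binomially (equivalent to per-patient
Bernoulli); placebo outcomes are drawn per patient in randomization
order so that sequence windows have well-defined death counts.

**Concurrent controls.**  Drug d's comparison group is the placebo
patients randomized between d's first and last enrolled patient.  For
simultaneous designs the enrollment periods coincide by construction
and every placebo patient is concurrent (exactly 435 or 870 controls
per drug).  In platform trials the window is evaluated on the
randomization sequence: between its endpoints the placebo accrues at
weight-ratio times the drug's own rate, so the equal-allocation
platform trial averages ≈ 435 concurrent controls per drug at any
accrual rate, while the dynamic rule averages up to ≈ 2×435 at slow
accrual, shrinking as faster accrual de-synchronizes the arms.  (A
month-granularity window — all placebo patients whose enrollment month
overlaps the drug's — would add roughly half a month of placebo accrual
at each end and visibly inflate the equal-design control counts at fast
accrual; the sequence definition avoids that boundary artifact.)

**Test.**  Pearson chi-squared on the 2×2 death/survival table, 1 df,
no continuity correction; Fisher's exact test (two-sided,
point-probability method) whenever any expected cell count is below 5
(Cochran's rule — the trigger at the study's rates and sizes is
essentially never hit, but matters for exploratory small runs).
Rejection is two-sided at α = 0.05 with no directionality filter and no
multiplicity adjustment across drugs; with a 5-point mortality
difference the wrong-direction contribution to "power" is far below
Monte Carlo error.  A comparison with an empty group yields no decision
and is excluded from the corresponding denominator (tracked as
`n_invalid`).

## Aggregation

Per (design, scenario, RP, λ) cell: per-drug rejection proportions
(type I error for arms at the placebo rate, group-specific power for
effective arms), overall power (≥ 1 effective drug rejected), mean
per-drug concurrent-control size, mean total placebo enrollment, mean
duration, each proportion with MC SE √(p̂(1−p̂)/n).  Replicates are
streamed; only 2×2 counts and size statistics are kept, and chi-squared
p-values are evaluated vectorized per cell.  For simultaneous designs
the enrollment loop is skipped entirely (group sizes and concurrency
are deterministic) and death counts are drawn directly on the planned
sizes — an exact shortcut, verified against the full simulation in the
test suite.

**Power-gain regression.**  For each grid cell the dynamic and equal
platform designs are simulated with independent seed-derived streams;
one point per cell carries Δx = difference in total placebo enrollment
(option: mean per-drug concurrent-control difference) and Δy =
difference in average group-specific power over the effective arms, in
percentage points.  Cells at RP ≤ 5% are excluded (both designs sit at
100% power; the points carry no information), as is the global-null
scenario.  OLS of Δy on Δx/100 with intercept (a through-origin option
exists) gives the slope per 100 additional placebo patients with a
t-based 95% CI.  The default grid is scenarios with ≥ 1 effective drug
× RP ∈ {7.5, 10, 12.5, 15}% × λ ∈ {100…400}.

## Seeding and reproducibility

A master seed plus counter-based substreams
(`SeedSequence(seed, spawn_key=(cell_index,))`) give every grid cell an
independent stream: adding cells never perturbs existing ones, and a
rerun of the same manifest is bit-identical.  Paired designs within a
cell use independent substreams (no common random numbers), so paired
differences carry the full two-sample Monte Carlo variance — the MC SEs
reported for differences reflect that.

## Problem sizes

Defaults follow the study conditions: 10,000 replicates per cell
(MC SE ≤ 0.5 points on any proportion).  The regression grids in
`scripts/acceptance.py` use 1,000–2,000 replicates per cell — at that
scale the fitted slope carries a Monte Carlo standard error of roughly
0.3–0.5 points per 100 patients, which the test tolerances account
for — and the worst-case-power scan uses 4,000 per accrual rate.

## What the generator does and does not emulate

The simulator reproduces the study's data-generating process exactly as
specified: Poisson accrual, weighted per-patient randomization,
Bernoulli outcomes, concurrent-control chi-squared analysis.  It does
not model interim analyses or early stopping, response-adaptive
randomization, time trends in mortality (the very reason concurrent
controls are used — under a time trend the non-concurrent bias the
design avoids is not simulated here), dropout or missing outcomes,
survival endpoints, or site-level accrual structure.  Passing tests
therefore validate the arithmetic of the designs under ideal
assumptions, not robustness to those departures.

## Known limitations

* The dynamic rule is a one-parameter family k^γ with default γ = ½;
  other weightings (e.g. fixed 2:1 platform) are not built-in labels,
  though `AllocationRule` supports fixed weights.
* The equal/unequal pairing uses independent streams; common random
  numbers would shrink the regression's MC noise but would change the
  declared estimand of the paired-difference SEs.
* Fisher's exact test is conditional (point-probability two-sided);
  unconditional tests (Barnard) are out of scope.
* Exact binomial (rather than asymptotic) sample-size search is not
  implemented; `required_n_per_group` is the standard normal
  approximation that defines the 435-per-arm design.
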