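# Methods

`marsim` is a Monte Carlo microsimulation of female reproductive life
courses with a medically-assisted-reproduction (MAR) treatment pathway. It
estimates what MAR contributes to completed cohort fertility (CCF) within
coresidential unions, and how that contribution responds to policy levers —
treatment uptake, reimbursement age limits, cycle limits, and waiting times
— by running paired counterfactual cohorts.

## The simulation model

Each woman is simulated independently from age 15 (month 180) to age 55
(month 660) in monthly steps, age measured at the start of the month. The
run has two stages, mirroring the life-course structure: the **union
simulation** first produces a full monthly trajectory of coresidential-union
status; the **reproduction simulation** then walks through the months using
that trajectory.

### Union histories

Union formation and dissolution are discrete-time Bernoulli hazards by age
and education (primary / secondary / tertiary). A single woman forms a
union with the formation hazard at her current age; a coresiding woman
dissolves it with the dissolution hazard. Re-partnering reuses the
formation hazard, with an optional refractory period after dissolution
(default 0 months). The postponement lever shifts the formation schedule:
with a shift of `s` months the hazard at age `a` is read from `a − s`.
Unions may dissolve during pregnancy or treatment; a birth after such a
dissolution is recorded as a birth outside a union (the only way one can
occur, since conception requires coresidence).

### Fixed attributes

At entry each woman draws: education; intended family size (default mass on
0–4 children, mean ≈ 1.9); baseline fecundability — her monthly conception
probability at peak age — from a Beta(0.9, 3.6) population distribution
(mean 0.20, heavy subfertile tail); an age of onset of permanent sterility
from a CDF that rises steeply through the forties; and a personal MAR
uptake probability drawn from the bootstrapped uptake distribution.

### Monthly reproductive step

Within a month the event order is fixed: union transition → trying
decision → MAR bookkeeping → conception attempts → contraceptive failure →
pregnancy progression → delivery.

A woman **tries** to conceive iff she is in a union, below her intended
family size, not pregnant, not post-partum, and not sterile; effective
fecundability is baseline × an age-decline multiplier (1 through the
twenties, falling steeply after 35). A woman at or above her intended size
**contracepts**; contraception fails with a small monthly probability
(default 0.004) and an unintended pregnancy is terminated with probability
0.5, modelling induced abortion of unwanted pregnancies.

Pregnancy lasts 9 months of gestation. The age-specific per-pregnancy
probability of intrauterine mortality (foetal death at any point, from
miscarriage to stillbirth) is converted to a constant monthly hazard whose
9-month cumulative risk matches the curve. A delivery draws plurality from
the multiple-birth model; twins count two children, triplets three. A
3-month post-partum non-susceptible period follows delivery.

### The MAR pathway

- **Diagnosis** after 12 consecutive unsuccessful months of trying
  (lever: +0 to +24 months).
- **Entry criterion**: age within the reimbursement window (up to 43 by
  default); below age 38 the woman must additionally have a poor natural
  prognosis — a 12-month cumulative conception probability
  `1 − (1 − f)^12` below 58% (a deliberately lenient Hunault-style rule,
  reflecting observed overtreatment). At 38 and over, diagnosis alone
  suffices.
- **Uptake** is decided once in a lifetime, a Bernoulli draw at the
  woman's bootstrapped uptake probability (share lever replaces it by a
  fixed s). Refusal is permanent.
- **Tracks**: effective fecundability below the ART gate (0.0077/month)
  sends the woman directly to IVF/ICSI; otherwise she starts IUI. Up to 6
  IUI cycles are reimbursed; exhausting them re-tests the gate (age has
  usually lowered fecundability), moving her to ART or back to expectant
  management. Up to 3 fresh IVF/ICSI cycles are reimbursed, each followed
  by one frozen-embryo-transfer (FET) attempt sharing the cycle's
  reimbursement slot (configurable; FET is excluded from lever analyses).
  Waiting clocks (default 1 month to first treatment and between cycles)
  separate cycles; waiting months are ordinary expectant-management months.
- **Reimbursement reset**: cycle counters return to their maxima when a MAR
  pregnancy ends in a live birth *or* intrauterine mortality, so a woman
  can be treated again for the next child.

A treatment cycle runs **in parallel** with the natural channel: the cycle
succeeds with the track's age-specific per-cycle rate (tagging the
conception IUI / IVF-ICSI / FET), and on failure the woman still conceives
naturally with her effective fecundability that month. Because every
random decision is keyed by (woman, month, channel), a run with all
treatment rates set to zero reproduces a treatment-disabled run exactly.

### Randomness

All draws come from a counter-based stream: a splitmix64 hash of
(master seed, replicate, woman, month, decision channel). Runs are
bitwise reproducible, invariant to simulation order and cohort
partitioning, and counterfactual pairs sharing a seed share their natural
randomness — common random numbers (CRN). CRN resolves lever effects of
order 0.005 children per woman at cohort sizes of 50 000, where independent
runs would need millions of women. Independent replicates (distinct
replicate ids) measure Monte Carlo variation, reported as the
(min − mean, max − mean) CCF deviation pair.

## Synthetic default parameters

The packaged defaults are smooth parametric stand-ins for a Dutch-style
1974–1984 birth cohort, built from annual knot tables (shipped as CSV/YAML
under `marsim/data/`, regenerable with `marsim fixtures`) splined to
monthly curves with a natural cubic spline clipped to [0, 1]. Monotone
CDF-like curves are additionally forced non-decreasing. Their documented
structure: fecundability flat through the twenties and declining steeply
after 35; per-cycle treatment success declining with age (IVF reference
curve ~0.29 per cycle at 25, ~0.11 at 40; IUI/ICSI/FET ratio-scaled copies
with means 0.015/0.24/0.17); intrauterine mortality rising from ~11% per
pregnancy at 25 to ~30% at 40; the multiple-birth probability rising with
maternal age, about tenfold higher per IVF/ICSI delivery than naturally,
with a twin:triplet ratio of ~32; union formation peaking in the late
twenties, latest for tertiary-educated women; uptake bootstrapped from a
602/825 binary sample (10 000 resample means around 73%).

Under these defaults a 100 000-woman baseline produces CCF ≈ 1.73 (≈ 1.70
with treatment unavailable), a mean age at first birth of ≈ 28.8, ≈ 2.6% of
births outside unions (from dissolution during pregnancy only), and a MAR
share of births of ≈ 2.7% with ART above IUI. The defaults are a coherent,
transparent parameterisation — not register estimates; analyses of real
cohorts should load their own tables via `load_parameters`.

### What the defaults do and do not emulate

Passing tests show the *mechanics* are right (accounting identities,
distributional oracles, lever directions and saturation patterns), not that
the magnitudes transfer to any real population. Known simplifications: the
IUI level was set low enough that IUI cycle-count and waiting levers sit
inside Monte Carlo noise (its birth share, ~0.7%, is below Dutch-style
estimates); sterile women stop trying and therefore never enter treatment,
which depresses the ART share at high ages; "union formation" is
effectively the start of joint conception attempts, so within-union
childbearing postponement is folded into the union schedule; male-partner
covariates, treatment drop-out, and births outside unions beyond
dissolution during pregnancy are not modelled.

## Numerical and design choices

- Age grid: months 180–660, half-open month intervals, age at month start;
  year thresholds translate to months as `year × 12` (an age cap of 43
  admits treatment through month 527, i.e. while aged 43).
- Spline flavour: natural cubic, the simplest reproducible choice; clipping
  guards edge overshoot.
- Bootstrap: resampling a binary vector with k successes is exactly
  Binomial(n, k/n)/n per resample; the implementation draws binomial counts
  directly. The pseudo-sample uses round(0.73 × 825) = 602 successes.
- The multiple-birth "natural" curve is recovered from an all-births curve
  by removing the treatment-attributable excess at each age
  (mass balance: `natural(a) ≈ all(a) − q(a)·(treated_mean − natural_mean)`
  with q the treated fraction of births), clipping negatives to zero with a
  warning.
- Within-month event order is fixed (union → MAR update → conception →
  progression → delivery) purely for reproducibility; the monthly
  resolution makes the residual ordering freedom immaterial.
- Waiting clocks tick before track assignment, so a wait of w months means
  the first cycle runs w months after assignment.
- Women diagnosed at or above the prognosis-check age limit (38) are
  admitted on diagnosis alone; the prognosis check applies only below it.
- Degenerate inputs: zero cycle limits leave every entrant on expectant
  management; an uptake share of 0 is verified bitwise-identical to
  disabling treatment; relative contributions with a zero denominator are
  reported as NaN, never infinity.

## Problem sizes

Cohort sizes were chosen for desk-scale resolution: paired CRN sweeps use
50 000 women, the packaged net-contribution run 100 000, distributional
oracles 50 000–100 000 trials, and the Monte Carlo scaling check 6
replicates each at 10³/10⁴/10⁵. The engine simulates roughly 15 000
woman-lives per second per core.
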