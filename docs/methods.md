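# Methods

## The demographic model

The analysis treats predation as a demographic process. A cohort of
predator females is followed daily from egg deposition (age x = 0, integer
days) to death. Three age-specific schedules summarise the cohort:

* survival l_x — individuals alive at age x over the starting cohort size,
  so l_0 = 1 and l_x is non-increasing;
* fecundity m_x — mean eggs laid per *living* female per day;
* predation k_x — mean prey killed per living female per day, carried both
  as a total and split by prey stage (egg / immature / adult).

Conditioning m_x and k_x on survival is deliberate: a dead predator cannot
kill, so mortality enters the rates only once, through l_x. A direct
consequence used as an internal oracle is that
K0 = Σ l_x·k_x equals the grand total of recorded kills divided by the
cohort size, exactly.

The pest kill rate k_m solves the Euler–Lotka equation with predation in
the fertility slot:

    Σ_x exp(-k_m x) l_x k_x = 1.

For a schedule with any net kill mass at a positive age the left side is
strictly decreasing in k_m, so the root is unique. It is found by Brent's
method on a bracket grown outward from [-1, 10]; the returned root is
required to leave an equation residual below the tolerance (default 1e-10)
or the solver raises. The same machinery applied to l_x·m_x gives the
intrinsic rate of increase r_m, with R0 = Σ l_x·m_x·f (f = female fraction,
default 1.0 — raw eggs — because no sex ratio is assumed; configurable) and
T = Σ x·l_x·m_x / Σ l_x·m_x. Doubling times are ln 2 / rate.

### Age conventions

Age x = 0 is the day of egg deposition; the first life-cycle period "to day
9" maps to ages 0–9 inclusive (boundaries (9, 29) by default, switchable
through `PeriodPartition`). The Euler–Lotka exponent uses the integer age
with no midpoint (x + ½) shift; this keeps every quantity hand-checkable
and is the convention all reported values use.

### Two generation times

The package reports both generation-time conventions that circulate in the
kill-rate literature:

* `Tk` — the cohort formula Σ x·l_x·k_x / Σ l_x·k_x (kill-weighted mean
  age), and
* `Tk_lotka` — ln(K0)/k_m, derived from the solved rate.

These agree only when net predation is concentrated near a single age; on
realistic spread schedules the cohort Tk is much larger and ln(K0)/Tk is
correspondingly far below the solved k_m. `km_approx` = ln(K0)/Tk is
reported so the user can see the size of that gap; published tables whose
(K0, Tk, km) triples satisfy k_m = ln(K0)/T_k to three decimals were
evidently computed with the Lotka convention, and `Tk_lotka` is the
comparable column.

## Jackknife uncertainty

The rate is a nonlinear functional of the cohort, so its standard error is
estimated by a leave-one-out jackknife over individuals: the schedule is
rebuilt and the rate re-solved n times, pseudovalues
v_i = n·θ_all − (n−1)·θ_(−i) are formed, and the estimate / SE / interval
are mean(v), SD(v)/√n and mean ± t(1−α/2, n−1)·SE (α default 0.05). For the
sample mean the pseudovalues reduce to the data, so the jackknife SE equals
the classical SE exactly — a closed-form agreement the tests assert. A
leave-one-out sub-cohort on which the rate is unsolvable (e.g. all
predation removed with one individual) aborts the procedure with a
diagnostic; pseudovalues are never silently dropped.

## Newman–Keuls sequential comparison

Treatment groups are ranked by jackknife estimate and stretches of r
adjacent ordered means are tested against the studentized-range quantile
q(1−α; r, df) with pooled df = Σ(nᵢ−1); a non-significant stretch is not
subdivided, and a pair differs only if its own stretch and every containing
stretch are significant. Ties in the ranking are broken by label, making
the procedure deterministic. The compact letter display is built from the
maximal non-significant stretches, lettered from the largest mean down, so
two groups share a letter exactly when the procedure did not separate them.

The error term for a stretch is a genuinely open design choice when the
groups are jackknife estimates with visibly unequal SEs. The default
(`error="pairwise"`) studentizes each stretch by the standard error of the
difference of its two extreme estimates, √(SE_min² + SE_max²), which
respects the heteroscedasticity that jackknifed nonlinear rates typically
show; the classical homoscedastic convention — pooled pseudovalue variance
with the harmonic mean n of the extremes — is available as
`error="pooled"`. With equal group variances the two coincide up to the √2
scaling absorbed in the q statistic's definition; with unequal variances
the pooled form can declare a noisy group different from a precise one on
the strength of the *other* groups' small variances, which is exactly the
situation the pairwise default avoids.

## The synthetic cohort generator

`simulate_cohort` emulates a leaf-arena assay in which each replicate
female has unlimited mixed-stage prey (the arena logistics themselves are
not modelled). Per female per day:

* survival — Bernoulli with an age-dependent hazard: a juvenile daily
  hazard set so survival to adult emergence (day 8) equals
  `juvenile_survival` (default 0.98); a small constant adult hazard
  (default 0.002) until day 29; from day 30 a geometric hazard
  1/(1 + residual_life_mean), giving mean residual lifetimes of 13.2 / 13.5
  / 11.3 days for the Ld / Gd / Po presets. The near-unity early survival
  reflects assays in which essentially all replicate females reach the
  third period; both early parameters are free knobs, not claims;
* kills — drawn from a Poisson (default), rounded-normal (using the
  per-period between-female SDs when overdispersion control is wanted) or
  constant distribution at that age's mean. Period means are
  (2.59, 11.64, 8.29) prey/female/day for the Ld preset, with Gd and Po
  analogues. Within the first period the daily means are shaped so that a
  `late_skew` fraction (preset values 0.7302 / 0.7049 / 0.7394) falls on
  the two preoviposition days 8–9, and the remainder ramps up over the
  feeding juvenile ages 2–7 with weight ∝ rank^1.25 — larvae begin feeding
  soon after hatching, and killing grows with body size. The onset age and
  ramp exponent calibrate the presets so that the deterministic
  large-cohort limit of k_m (from `expected_schedule`) lands at
  0.509 / 0.523 / 0.470, inside the published jackknife intervals for the
  three origins;
* prey-stage split — each day's kill total is divided multinomially with
  probabilities (0.41, 0.39, 0.20) for prey eggs / immatures / adults;
* eggs — Poisson at the period fecundity (Ld: 2.50/day over days 10–29,
  0.71/day after), zero before oviposition starts at day 10.

Identical seed and configuration give a byte-identical cohort.

What the generator does *not* emulate: between-female heterogeneity in
kill propensity beyond the chosen count distribution (the published
between-female SDs are not Poisson-consistent; the rounded-normal option
approximates them), prey-stage preferences that vary with predator age,
functional-response saturation, male predation, and any arena/replenishment
bookkeeping. Passing tests therefore demonstrate that the pipeline
recovers the parameters of this generative model, not that the model
captures every feature of real assay data.

## Numerical and degenerate-input choices

* Root bracket [-1, 10], expanded geometrically when needed; Brent xtol
  1e-14; residual checked against the user tolerance.
* K0 = 0 makes the kill rate an error and Tk undefined (NaN plus a
  warning, never silent); 0 < K0 ≤ 1 returns the (non-positive) root with a
  warning.
* Period summaries use SD with n−1 degrees of freedom, defined as 0.0 for
  a single individual; a period no individual survived into is reported
  with n = 0 and NaN (undefined, not zero).
* Individuals last seen alive are treated as dying the following day, with
  a warning — in a followed-to-death design, censoring is a data defect.
* Prey natural mortality is not corrected for (negligible in the emulated
  assay).
* CSV outputs use a fixed decimal format so identical runs are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
cohorts of 15 females (the emulated design) for the jackknife and pipeline
checks, 200-female cohorts (50 seeded replicates) for parameter-recovery
checks, and 200 replicates of 15-female cohorts for the interval-coverage
check. These sizes keep every check at desk scale while leaving the
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Immature and male predation contribute through the single female cohort
  schedule only; no two-sex or stage-structured variants.
* No stable-age-distribution or reproductive-value outputs.
* The Newman–Keuls procedure controls error rates only in the weak sense,
  as any sequential range test does; no Tukey/Bonferroni alternatives are
  exposed.
* Inference on period summaries (beyond descriptive mean ± SD/SE) is out
  of scope.
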