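# Methods

This note documents the models and numerical choices behind `triage_sim`:
what the synthetic cohort emulates, how the triage mechanics are defined
where the underlying study protocol leaves freedom, and what the passing
test suite does and does not establish about real ICU data.

## Synthetic cohort

### Marginal distributions

The generator emulates a fourth-pandemic-wave ICU cohort that is known
only through its summary table: n = 1083, age 64.6 ± 15.7 y, first
SAPS II 35.0 ± 12.7, first TISS 9.4 ± 5.4, 12.2 ± 6.4 secondary
diagnoses, 22.8 % SARS-CoV-2, ICU-LOS 4.0 ± 5.4 d, hospital LOS
17.8 ± 13.6 d, 23.8 % in-hospital mortality. Continuous attributes are
truncated normals on their natural supports (age [18, 100], SAPS II
[0, 163], TISS [0, 78], counts and stays [0, ∞)).

A truncated normal naively parameterized by the printed mean/SD does not
*have* that mean — truncation at 0 with parent 4.0/5.4 yields a mean of
≈6.1 days. The generator therefore solves for the parent location (scale
fixed at the printed SD) such that the **truncated** mean equals the
printed mean, by monotone root finding. Consequences worth knowing:

* all sample means recover the printed values (the tests check 2 standard
  errors at n = 1083);
* the realized SDs of the strongly truncated variables are smaller than
  the printed SDs. For ICU-LOS no zero-truncated normal can reach
  CV = 5.4/4.0 = 1.35 (the family's supremum is 1), so only the mean is
  matched. A log-normal switch (`los_distribution="lognormal"`) matches
  both moments and the right skew of real LOS distributions, at the price
  of leaving the stated truncated-normal family; the default stays with
  the truncated normal.

Values are rounded to integers where the raw export would hold integers
(years, score points, calendar days); the rounding bias on means is
negligible against the Monte-Carlo tolerances used.

### Dependence structure

Real severity criteria are prognostic: older, multi-morbid, long-staying
patients are sicker. A cohort with fully independent attributes would make
every criterion-based policy a coin flip driven by spurious sample
correlations of the one generated cohort. The generator therefore ties
age, TISS, secondary-diagnosis count and ICU-LOS to the SAPS II latent
through a Gaussian copula (correlations 0.40 / 0.65 / 0.50 / 0.25). The
TISS and secondary-diagnosis values are calibrated so the non-survivor
subgroup means land near the published anchors (TISS ≈ 11.9, ≈14.5
secondary diagnoses, non-survivor SAPS ≈ 44 — the last emerging from the
death model alone). The copula leaves every marginal untouched. COVID
status, admission dates and the hospital-minus-ICU stay remainder are
independent. The hospital stay is built as ICU-LOS plus a nonnegative
remainder (mean 13.8 d), which guarantees the ICU interval nests inside
the hospital interval.

### Death model and calibration

Conditional on the first SAPS II score S, death is Bernoulli with

    p_death(S) = expit( legall_logit(S) + c ),
    legall_logit(S) = −7.7631 + 0.0737·S + 0.9971·ln(S + 1)

where the offset c is found by monotone root finding (Brent, |mean − 
target| ≤ 1e−6, offset bracketed in ±20 logit units) so the cohort mean of
p_death equals the 23.8 % target. The calibrated offset is positive
(≈ +0.45 at the defaults): the unshifted Le Gall prediction averages
≈0.21 < 0.238, reproducing by construction the well-documented
underestimation of modern ICU mortality by the original SAPS II formula,
while preserving its ranking ability — exactly the property that makes
SAPS II usable for triage but biased as an outcome predictor.

Death flags are drawn by **systematic sampling on the cumulative
probability scale in risk order**: a unit-spaced uniform-offset grid over
the cumulated p_death of the SAPS-sorted cohort. Each flag remains exactly
Bernoulli(p_i) marginally, but the death count of any contiguous severity
stratum equals its summed probability ±1. The generated cohort thus
behaves like a fixed real cohort whose stratum mortalities sit on the risk
curve, with no binomial noise on the 23.8 % marginal — at the price of
(irrelevant for the bed-swap mechanics) negative dependence between death
flags of similar-severity patients, and of realization noise that is
*not* suppressed for non-contiguous subsets selected through correlated
covariates (see Limitations).

### Contamination

`n_implausible` extra records (default 4) are appended, cycling
deterministically through the three plausibility violations — two main
diagnoses, missing SAPS series, negative ICU stay — so the
data-preparation filter is exercised on every rule and the packaged
fixture reproduces a four-record exclusion.

## Data preparation

* First scores: earliest event date wins; equal dates keep file order.
* First ICU stay: earliest start; equal starts keep the longer stay.
* LOS: calendar-day difference, same-day stay = 0.
* COVID-19: ICD-10 U07.1/U07.2 anywhere, or a case-insensitive
  {covid, sars-cov-2, coronavirus} match in main-diagnosis free text.
* Exclusion rules are checked in a fixed order (main-diagnosis count,
  missing mandatory value, negative/inconsistent LOS) and each record is
  reported once under the first rule violated. All downstream-used fields
  are mandatory. A hospital stay shorter than the ICU stay is treated as
  the negative-LOS case.

## Severity scores

SAPS II maps linearly onto the SOFA scale via the score maxima
(S·24/163, not rounded before tier lookup). The adjusted DIVI score sums
tier points from three configurable scales (defaults: SOFA-equivalent
<6→1, 6–8→2, 9–11→3, ≥12→4; secondary diagnoses ≤6→0, 7–12→1, 13–18→2,
>18→3; age <50→0, 50–64→1, 65–79→2, ≥80→3); lower totals mean better
prognosis, and age enters policy 9 additively (treating age as a third
summed criterion; a pure tie-breaker reading is the documented
alternative). The table is a YAML-serializable config object so a
hospital-specific point table can be dropped in.

## Triage mechanics

The study protocol specifies the cap m but not *which* occupants are
exposed. Here the eligible set of a ranked policy holds the m occupants
with the worst keys (ties: shorter elapsed stay first, then stable input
order) — the only reading consistent with a swap cap plus "compare the
queue against the ICU by criterion". Reverse FCFS exposes the most
recently admitted; the random policy draws uniformly. Ranked swaps require
strict improvement and stop at the first non-improving pair (queue sorted
best-first against incumbents worst-first), which provably attains the
enumeration optimum (minimum total key reachable with ≤ m swaps) — the
test suite checks this exhaustively on small instances. Ties keep the
incumbent, minimizing interventions. Prognosis-blind policies swap
unconditionally min(q, m) patients: a blind rule has no notion of
improvement, and their observed equivalence with the no-triage baseline
confirms the neutrality of that choice. Policy 7 ranks by each patient's
retrospective total ICU-LOS attribute (assumed predictable at decision
time), not by elapsed days.

## Simulation design

Occupancies draw 60 patients with replacement; initial elapsed stays are
discrete-uniform on {1, …, 7} — support chosen so the mean elapsed time
(4 d) equals the cohort's mean ICU-LOS; configurable. Fresh, independent
queues arrive at each timepoint; unadmitted queue patients do not carry
over; nobody leaves inside the 3-day horizon except by displacement; and
elapsed times advance one day per timepoint (new admissions start at 0).
Both mortality metrics are recorded post-triage; outcomes of displaced
patients are outside the metric, which is deliberately "mortality *in the
ICU*". Occupancy and queue draws use a substream keyed by (seed, scenario,
run) shared by all policies — common random numbers sharpen policy
contrasts — while policy-internal randomness keys in the policy id.
Everything is reproducible bit-for-bit from the seed.

Default problem sizes follow the study design (6 scenarios × 10 policies
× 1000 runs × 3 timepoints; ≈10 s on one CPU). The test suite exercises
the identical code paths at 150 runs per cell, which keeps every
Monte-Carlo tolerance interpretable while the whole suite stays fast.

## Evaluation

Per (scenario, t): one-way fixed-effects ANOVA over the 10 policy groups
of per-run mortalities (runs as independent replicates; no
repeated-measures correction, since each run is an independent cohort
draw), then Tukey HSD on all 45 pairs at α = 0.05 via the studentized
range distribution. Zero within-group variance everywhere is reported as
an exact-tie result rather than an error. Summary tables carry means,
SDs, quartiles and 1.5·IQR whiskers (plot-ready CSV; no figure rendering).
p-values are written to machine precision with a "<1e-16" floor label.

## Limitations

* The synthetic cohort reproduces printed margins, three subgroup anchors
  and a plausible dependence skeleton — not the true joint distribution of
  any real ICU population. Effect *sizes* (e.g. how far policy 4 drops
  mortality in scenario 6) depend on the assumed copula strengths; the
  qualitative ordering of policy classes is insensitive to them as long as
  the criteria remain positively prognostic.
* Predicted-vs-realized mortality comparisons are table-level statements.
  For a single fixed cohort, the realized death rate of a narrow covariate
  tail carries ±2-point realization noise, which can locally exceed the
  calibration gap; the systematic-underestimation property is therefore
  asserted on cell averages across policies (and cellwise only for the
  prognosis-blind policies), never per extreme-selection cell.
* No admission process, no within-horizon natural discharge or death, no
  inter-patient infection dynamics, no time-varying severity, and no
  patient-level treatment preferences are modelled.
* The DIVI point values are a documented guideline-shaped default, not a
  hospital's actual triage-team table; swap in the real table via the
  config object before drawing practical conclusions.
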