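# Methods

This note records the conventions, model assumptions, defaults, and open
design choices behind `cdburden`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Four delimited-text tables (members, enrollment spans, medical claims,
pharmacy claims) mirror a commercial health-plan research database. All
interval arithmetic is in whole days; enrollment spans and analysis windows
are inclusive on both ends. Codes are matched by exact string after one-time
normalization (trim, uppercase, dots kept); code *sets* are config inputs
and the shipped defaults are symbolic placeholder tokens — the package
asserts no real ICD-9/CPT/HCPCS values beyond CS 255.0.

Key temporal defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| study window | 2006-07-01 … 2012-06-30 | claims observed |
| identification window | 2007-01-01 … 2011-12-31 | index events allowed |
| `pre_days` | 183 | pre-index enrollment/washout window |
| `post_min_days` | 183 | minimum post-index follow-up |
| `match_ratio` | 3 | controls per case |
| `enrollment_gap_days` | 0 | tolerated gap between spans |

"Six months" is operationalized as a fixed 183 days so that all window
arithmetic is exact and testable. One consequence: with
`follow_up_days = (follow_up_end − index).days`, a member indexed on the
last identification day would need coverage one day past the study cutoff,
so the very edge of the identification window yields no eligible cases. A
calendar-month convention would admit them; the fixed-day convention was
chosen for determinism.

## Case finding

CS screen and pituitary classification examine only *selectable* claims:
inside the identification window and not at a lab/diagnostic place of
service. The lab exclusion is applied to both diagnosis and procedure codes
(uniformity; conservative). The index date is the earliest selectable claim
bearing a CS or pituitary code. On a same-day tie between CS and pituitary
codes the pituitary condition/procedure labels the event (the date is
unaffected); among pituitary sets the first in the configured order wins.
Eligibility requires a gap-free chain of spans with both medical and
pharmacy benefits covering `[index − pre_days, index + post_min_days]`;
follow-up ends at the earliest of death, end of coverage, or study cutoff,
and the censoring reason records the binding constraint (death checked
first).

## Controls and matching

The CD-free exclusion scan is deliberately *unqualified*: any CS or
pituitary code anywhere in the study period disqualifies a candidate,
including lab claims that the case-finding step ignores (control purity
over symmetry). A control's index date is the first medical claim in the
identification window; controls must satisfy the same enrollment rules as
cases. Matching is greedy and seeded: cases in random order, exact strata on
(completed years of age at index, sex, region, index year), `ratio` controls
sampled uniformly without replacement. Cases with too few stratum candidates
are reported unmatched and dropped, their tentative controls returned. Exact
matching makes the groups' marginal distributions on the four covariates
identical by construction, which the tests assert.

## Incidence, washout, person-time

Pre-index window `[index − 183, index − 1]`; post-index window
`[index, follow_up_end]` — the index day is post-index because the index
event itself occurs on it. A member with any pre-index claim for a condition
is removed from that condition's risk set entirely (washout). Time at risk
is `(first event − index)` days for events, full follow-up for non-events
(censored time must count or rates are ill-defined); person-years use
365.25 days. The rate contract is `rate = 100·events/person_years`, NaN on
zero person-time (warned). Female-only and child-only (<18 at index)
conditions restrict the risk set before washout.

## Statistics

* **IRR.** The covariate-free Poisson model with log link and log
  person-time offset has the closed-form MLE
  `IRR = (Σe₁/Σt₁)/(Σe₀/Σt₀)`; the implementation computes it in closed
  form and the test suite checks the algebraic identity to 1e-12 and
  cross-checks against an independent GLM fit. Clustering (match sets)
  enters only the variance, via a one-way CR0 cluster sandwich on the
  Poisson score — a GEE with independence working correlation. Wald 95%
  intervals on the log scale; no small-count exact intervals (counts in
  this design are moderate). Zero events in either group → undefined (NaN),
  with an optional continuity correction adding 0.5 to all four group sums,
  off by default.
* **Rao–Scott.** Pearson chi-square of the 2×2 group-by-outcome table
  divided by a first-order design-effect estimate built from cluster-level
  outcome totals within each group (no small-sample factor, so singleton
  clusters give design effect exactly 1 and the statistic reduces to the
  classical Pearson chi-square; fully correlated clusters of size k give
  design effect k). Degenerate tables return statistic 0, p = 1.
* **Mean comparison.** OLS of the member-level value on a group indicator,
  CR0 cluster sandwich scaled by G/(G−1), t reference with G−1 df.
* **Significance** in reports uses the dual rule: p < 0.05 *and* the 95%
  CI excluding 1.

## PPPM economics

Month = 30.4375 days (the average-month constant consistent with 365.25-day
years). "Ambulatory" = outpatient hospital + physician office. Visit counts
deduplicate to one visit per member-date-setting (config-exposed);
inpatient utilization counts admissions: claims sharing a `stay_id` form one
stay, claims lacking one are merged when their dates overlap or abut
(gap ≤ 1 day). Costs are plan-paid + patient-paid, restated in target-year
dollars with the annual medical-care CPI (a config table) per service year
before summing; member total = medical + pharmacy exactly. Only claims in
`[index, follow_up_end]` contribute.

## Synthetic data: what it emulates, and what it does not

The generator draws, per master seed, one independent RNG stream per stage
(population, CD signal, outcomes, costs) keyed by fixed labels, so adding a
stage never perturbs earlier ones. Defaults encode the study conditions the
package targets:

* demographics: 75.26% female, age ~N(42, 14²) clipped to 1–90 (≈5%
  children), region mix 16/37/36/10;
* enrollment: 60% enrolled at study start, the rest entering uniformly;
  exponential disenrollment (0.18/year) and death (0.004/year); 10% of
  members get their coverage emitted as two abutting spans to exercise the
  chain logic;
* CD signal: a configurable share of members is CS-coded (`p_cs_coded`),
  of whom 15% (`p_cd_given_cs`) also receive a pituitary-qualifier claim,
  both placed inside coverage ∩ identification window; a fraction also
  receives qualifying codes on lab-place-of-service claims that the
  algorithm must ignore;
* outcomes: per condition, first-event times are exponential with
  group-specific hazards (control hazards near the observed control rates of
  a hypercortisolism cohort, case:control ratios ≈ 2–5; configured per
  condition), rounded up to whole days and emitted only while enrolled.
  Pre-index claims exercise washout with group-specific probabilities
  (cases 0.16, controls 0.08 — cases carry more pre-index comorbidity);
* costs: Poisson visit counts per setting per month and log-normal per-visit
  costs (σ = 1) with group-specific means; the implied true PPPM means are
  exposed (`SimulationParams.implied_pppm_means`), with a total-cost
  case:control ratio ≈ 6.6. When a CPI table is supplied, emitted amounts
  are deflated to nominal service-year dollars so the pipeline's inflation
  adjustment restates them at the intended level.

Two generator conventions worth knowing. First, members whose coverage
misses the identification window are downgraded to background so the truth
table always agrees with the emitted claims. Second, control members'
washout-exercising pre-index claims are dated before the identification
window; otherwise they would become the member's first in-window claim and
silently redefine the control's index date (and count as instant events).
Case members' pre-index claims are unrestricted, since a case's index is
pinned by CS/pituitary codes.

The generator does *not* emulate: realistic code distributions or billing
semantics (adjustments, reversals, coordination of benefits), seasonality,
correlated comorbidities within members, cost inflation trends beyond the
CPI mechanism, or care-pathway structure. Passing tests therefore establish
that the pipeline's logic and estimators are correct under a clean
generating process — not that the algorithm's sensitivity/specificity would
hold on real claims, where qualifier codes appear without CD and coding
practice varies.

## Numerical and degenerate-input choices

Dates are pandas Timestamps (ns resolution); far-future simulated event and
death times are capped at 30,000 days before date arithmetic. The Poisson
solver is closed-form for the two-group model (no IRLS needed); sandwich
variances clamp tiny negative diagonal round-off at 0. Empty inputs
propagate as empty outputs (empty dataset from `n_members = 0`; zero-CD
datasets produce empty cohorts and tables with headers; empty claim tables
validate cleanly). Validation reports are sorted, hence idempotent and
row-order insensitive.

## Problem sizes in the checks

The test suite and acceptance script size their simulations for tight
sampling error at interactive runtimes: 20,000-member populations for
attrition/matching structure, 2,000-case/6,000-control cohorts for IRR
recovery (pooled over 10 replicates in the acceptance script), 200
replicates of 500 match sets for null CI coverage, and 500 match sets for
cost recovery. These are the package's chosen study sizes; all scale
linearly if larger runs are wanted.

## Known limitations

* The algorithm cannot separate CD from ectopic CS beyond the eight rules
  (e.g., an ectopic-CS patient with petrosal sinus sampling is classified
  CD); chart validation is out of scope.
* The clustered IRR variance is a design choice (independence point
  estimate + cluster sandwich); other defensible estimators (conditional
  Poisson, mixed models) would give different intervals, and published
  clustered ratios from proprietary data are generally not recomputable
  from marginal counts alone.
* Pediatric incidence denominators in this design can be reported in units
  that are not person-years; the package guarantees only the arithmetic
  contract `rate = 100·events/person_time` in whatever unit person-time is
  supplied.
* The log-normal control-group cost process is an assumption; real cost
  distributions are heavier-tailed and zero-inflated.
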