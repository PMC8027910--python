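# Methods

`trialmatch` implements an EHR-based comparison of clinical-trial
participants with exactly matched nonparticipants, together with the
synthetic study generator used to validate it. This note records the model,
the numerical conventions, and the design choices made where the procedure
was genuinely open.

## Cohort construction

**Participant selection.** Each person in the enrollment report is limited
to their earliest trial (minimal status date; date ties break by the
lexicographically smallest trial id, so selection is deterministic). The
index event is the condition occurrence whose concept is one of the trial's
focus concepts *or a descendant in the concept hierarchy*, dated within the
365 days before and including the status date, and closest to it. "Within
the 365 days before and including" is implemented as the closed interval
`[status − 365 d, status]` — 366 calendar days; all intervals in the package
are closed and each caller states both endpoints, because the selection
rules deliberately mix "before and including" with "before, but not
including" windows. Ties on the index date break by smallest concept id.
A *reassurance requirement* then demands the index concept or one of its
descendants recorded in `[index − 365 d, index − 1 d]`. Persons whose
earliest trial has no mappable focus concepts are excluded with the trial;
persons without a qualifying code or failing reassurance are excluded
individually, and every exclusion is counted in the selection audit.

The concept hierarchy is stored as an explicit transitive closure (the form
of the OMOP `concept_ancestor` table) with self-pairs excluded;
`descendants_of` re-adds the concept itself, so hierarchy queries are set
lookups with no traversal at query time.

**Nonparticipant matching.** A candidate entry is a never-enrolled person
with a condition event of the *exact* index condition code (the matching is
deliberately non-hierarchical) dated in a participant's index month; the
candidate index date is the earliest such event in that month (the
procedure is silent on this point; earliest is deterministic and
order-independent), and the reassurance requirement must hold at that date.
The match key is (index concept, index calendar year-month, number of
visits in the 365 days *before, not including* the index date) — note the
visit window excludes the index day while the covariate window includes it.
Visit counts are computed at the candidate's own index date; the source
wording supports this reading but does not state it.

Each iteration processes participants in a shuffled order; every
participant draws uniformly at random one still-unused compatible
candidate, without replacement, and a nonparticipant person can serve at
most one participant per iteration (a person appearing as several candidate
entries is still consumed once). Because compatibility is exact on the key,
the implementation resolves each key independently with a pre-shuffled
candidate stack; this is distributionally identical to the sequential
description. The procedure repeats `n_iterations` times (default 1000);
iteration *i* uses an independent stream seeded `seed + i`, so single
iterations are reproducible. A participant matched in *no* iteration is
excluded from the downstream cohort ("could not be matched in all
iterations" is read as *never* matchable — the alternative reading, drop if
ever unmatched, would shrink the cohort whenever contention exists);
iterations in which a retained participant finds no free candidate simply
contribute no pair.

Two invariants are asserted on every run: no nonparticipant person repeats
within an iteration, and every emitted pair has bitwise-equal match keys.
On small instances the set of participants ever matched provably equals the
set coverable by some maximum bipartite matching; the test suite checks
this against a brute-force enumeration oracle.

## Covariates and the balance screen

A person qualifies for a clinical covariate if at least one event of the
covariate's kind (condition or drug) whose concept lies in the
descendant-expanded concept set falls in `[index − 365 d, index]`.
Demographics are age group (<18 / 18–64 / ≥65, *floored* whole years at the
index date — the convention for the boundary is ours), sex, race and
ethnicity with explicit Unknown levels.

Nonparticipant descriptive statistics are the across-iteration mean of the
per-iteration matched-set counts; prevalence is mean count over mean
matched-set size. Imbalance is screened with the standardized difference
for binary proportions,

    d = (p1 − p2) / sqrt((p1(1 − p1) + p2(1 − p2)) / 2),

flagged at |d| ≥ 0.1. The statistic is computed on the participant
proportion versus the *mean* nonparticipant proportion (not the mean of
per-iteration standardized differences); this choice reproduces published
balance-table values from their printed percentages. Report rounding is
three decimals, half away from zero. The degenerate pair p1 = p2 ∈ {0, 1}
is defined as 0 with a warning; opposite extremes (0 vs 1) return the
formula's signed infinity. A continuous-covariate variant
`(m1 − m2)/sqrt((s1² + s2²)/2)` is provided for configured continuous
covariates such as age in years.

## Association scan

Within each disease domain, every covariate is cross-tabulated against
every trial design characteristic over that domain's participants and
tested for independence. Domains are derived from ancestor concepts of each
trial's focus conditions (a trial can carry several domains); the default
keeps the top four domains by trial count, with labels and anchor concepts
supplied as configuration. Trial metadata are recoded first: combination
phases collapse to the later phase (phase 1/phase 2 → 2), arms group as
1 / 2 / ≥3, overall enrollment bins at <50 / 50–499 / ≥500, site enrollment
at <5 / 5–19 / ≥20 (anticipated enrollment stands in when the actual figure
is missing), and status strings normalize case-insensitively to five rows.

The default test is the chi-square without continuity correction; under
the classical Cochran criterion (any expected count < 5) a 2×2 table uses
the conditional Fisher exact test — computed by exact integer
hypergeometric enumeration, with ties in the "no more probable" rule
classified without rounding — and a larger sparse table uses a seeded
Monte-Carlo exact p with 10⁴ fixed-margin resamples of the chi-square
statistic, reported as (1 + exceedances)/(1 + resamples). The source
procedure names only "chi-square (or Fisher exact)"; the expected-count
rule and the omitted Yates correction are the conventional reading.
Degenerate pairings (constant covariate or characteristic within a domain)
are skipped and excluded from the family size. Bonferroni correction is
applied within each domain at a base two-tailed level of 0.01: a cell is
significant iff p < 0.01/m, strict, with m the number of pairings that
produced a p-value in that domain. Odds ratios for 2×2 tables are sample
cross-products with Wald log-scale CIs and the Haldane 0.5 correction for
zero cells; note that a published pediatric-enrollment odds ratio of 0.14
is not exactly the cross-product of its printed counts (≈0.148) — the
estimator behind the printed value is unstated, so the package reports the
sample cross-product and leaves the discrepancy documented rather than
guessed. Manhattan-like panels plot −log10 p per covariate with a dashed
line at the domain threshold; all plot data are also written as plain
tables.

## Synthetic data generator

The generator emulates the three linked sources — OMOP-style EHR tables, an
enrollment report, and registry-style trial metadata — with known ground
truth written alongside (`ground_truth.json`).

* **Vocabulary.** One focus-condition tree per disease domain (default 4
  roots × branching 4 × depth 2, transitively closed) plus a private
  concept block (parent + three children) per covariate.
* **Covariates.** Independent Bernoulli indicators per person at configured
  baseline prevalences. A positive person receives one event per 180-day
  block over the generation span, so consecutive events are < 360 days
  apart and any 365-day lookback inside the span contains at least one:
  windowed prevalence equals the latent indicator, which makes calibration
  and effect-recovery tests sharp.
* **Enrollment.** Logistic selection on the covariate indicators: exactly
  `n_enrolled` persons are drawn without replacement with weights
  `exp(Σ bias_c x_c)`. Zero bias is a uniform draw, so enrolled and
  background prevalences differ only by sampling noise; a +0.5 log-odds
  shift on a 0.30-prevalence covariate moves the enrolled prevalence to
  ≈ 0.41. Every enrolled person is forced to satisfy selection: an index
  event 0–60 days before the status date and a same-concept reassurance
  event 1–365 days before that. One preset trial is always unmappable, to
  exercise the trial-exclusion rule; its enrollees are recorded as forced
  exclusions so selection counts are predictable.
* **Candidates.** A configurable fraction (default 0.6) of background
  persons carry one focus concept with recurring events, giving candidate
  pools with realistic contention; visit counts are Poisson at the
  configured rate (default 2/person-year) with uniform dates, producing the
  integer ties exact matching needs.

The generator does **not** emulate disease trajectories, coded-vocabulary
realism, correlated comorbidity structure, or informative visit patterns.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and calibrated under a known mechanism — not that any specific
clinical population behaves this way.

Fixing the seed fixes the output byte for byte; all randomness flows from
one `numpy` generator.

## Problem sizes used in validation

Two presets pin the study conditions. `make_paper_like_preset` keeps the
reference scale: 202 trials, 1645 enrolled persons, a background population
twenty-one times the enrolled cohort, 31 condition and 17 medication-class
covariates, and a 1996–2019 accrual window. `make_calibration_preset`
keeps the cohort sizes (1645 enrolled, 202 trials, all 48 covariates) but
uses a seven-fold background population and a 2012–2015 accrual window so
that the twenty-seed calibration experiments complete on a single
workstation: null calibration and family-wise-error checks run 20 seeded
studies at 100 matching iterations with zero bias, and effect recovery runs
20 more with ±0.5 log-odds shifts on four covariates with baselines between
0.2 and 0.4. End-to-end determinism is demonstrated on a smaller smoke
configuration (1500 persons, 50 iterations) run twice to identical
checksums.

## Known limitations

* Matching treats each trial as having one effective index condition per
  participant; trials defined by multiple simultaneous conditions are not
  modeled.
* Propensity-score or caliper matching is deliberately out of scope: the
  clinical covariates being compared must stay out of the matching model.
* Nonparticipant counts in reports are means over iterations and need not
  be integers; full precision is kept alongside the rounded display values.
* The figures are rendered with pinned SVG hash salt and date metadata so
  reruns are byte-stable; if a matplotlib upgrade changes its SVG writer,
  checksums will legitimately differ across versions.
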