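# Methods

This note records the algorithms, their parameters and defaults, the
numerical choices, and the known limitations of each stage. Everything
here is implemented in `src/divertiphen/` and exercised by the test
suite; problem sizes quoted are the ones the tests and acceptance
script actually run.

## 1. Data model (`ehr_core`)

Persons carry birth date, sex at birth, BMI, Charlson comorbidity
index (consumed as a precomputed covariate, never derived), a
neighborhood deprivation index validated to [0, 1], and named survey
dates. Clinical events are immutable (person, date, code, vocabulary,
event class, optional encounter link); encounters have a care setting
(inpatient / outpatient / emergency) and a date interval. A person's
`EventTimeline` sorts events by `(date, event_class, code)` so ordering
is total and permutation-invariant.

The CSV reader is schema-validating: malformed rows are collected in a
rejects table `(table, row, reason)` instead of aborting; an event
referencing an unknown encounter is kept with its link nulled and a
warning recorded (the dangling-link count is reported). Column names
and care-setting vocabularies are remappable through `SchemaConfig`;
an unmapped setting falls back to outpatient with a warning, which is
conservative for the inpatient-admission rule below.

## 2. Code sets (`codesets`)

Matching is dot- and case-insensitive (`K57.32` ≡ `k5732`) and
vocabulary-gated; a trailing `*` makes an entry a prefix pattern.
A registry must provide eight required sets (diverticular diagnoses
split into diverticulosis vs diverticulitis plus their union,
abdominal CT, lower-GI endoscopy, colectomy, abscess drainage, fistula
repair). Registry validation enforces two invariants: the union covers
both diagnosis subsets, and the diverticulosis / diverticulitis subsets
are disjoint (a code matched by both is a configuration error). Custom
registries load from YAML with `VOCAB:pattern` entries and get the same
validation.

## 3. Severity rules (`phenotyper`)

Decision order, first match wins:

1. no diverticular code at all → **control**;
2. no index pair → **excluded** (codes exist but are unconfirmed);
3. no diverticulitis code anywhere → **diverticulosis**;
4. qualifying procedure, or more than one distinct inpatient
   diverticulitis admission → **operative_or_recurrent**;
5. otherwise → **mild_diverticulitis**.

Parameters and conventions:

- **Index pair**: earliest diverticular diagnosis that has a confirming
  CT/endoscopy 0–7 days (inclusive) *before* it; the confirmation
  window (7 days) is a module constant.
- **Qualifying procedure**: colectomy / drainage / fistula-repair code
  linked to a diverticulitis diagnosis either by shared encounter or by
  a ±`link_window_days` day window (default 30, configurable).
- **Admission counting**: inpatient encounters containing a
  diverticulitis code are merged when their date intervals overlap or
  are same-day adjacent, then counted; emergency-department visits
  never count. Codes in no inpatient encounter are tallied as unlinked
  rather than silently dropped.
- **Inclusion window**: cases are kept when the assignment date lies
  within `window_years` (default 5.0; 365.25 days/year) either side of
  the chosen survey date (`earliest`, `healthcare_access`, or `sdoh`);
  controls need any survey on record. Drop counts are reported
  separately for "outside window" and "no survey".

## 4. Validation metrics (`validation_metrics`)

Per-class PPV/NPV are one-vs-rest confusion-matrix ratios against
either a fixed reviewer or the majority consensus (ties broken by the
first reviewer and flagged). A zero denominator yields `None` with a
reason, never a silent 0. Cohen's kappa is `(p_o − p_e)/(1 − p_e)`
with two explicit degenerate conventions: perfect agreement on a
single category is 1.0; `p_e = 1` with imperfect agreement raises.
Differential classification is the percent of multi-reviewer records
whose reviewers disagree, per algorithm class; single-reviewer records
are excluded and counted. Review sampling is per-class without
replacement with a seeded RNG (classes smaller than the target are
taken whole).

## 5. Survey scoring (`sdoh_scoring`)

Instruments are declarative (`InstrumentSpec`: items, ordered response
levels, scoring rule ∈ {sum, mean, screen, categorical}). Screens are
positive on any at-risk item, negative only when all items are
answered. Top-box binarization flags a barrier unless *every* answered
item is at the most favorable level; a fully unanswered instrument is
missing, a partially answered one cannot be top-box. The composite
unmet-need flag is 1 if any of food insecurity, housing instability,
delayed/unaffordable care is flagged; 0 only when all three are
decidably 0; missing otherwise — making it monotone and symmetric in
its inputs.

Deprivation quintiles cut at the 20/40/60/80th percentiles, ties
assigned to the lower quintile; external boundaries can be supplied to
freeze cuts across cohorts; an all-identical column degenerates to
quintile 1 with a warning. Fold enrichment is the count ratio of the
most- to least-deprived quintile (undefined sentinel when the reference
count is zero); it is scale-invariant in the counts.

## 6. Analysis (`analysis`)

- **Tables**: numeric variables get median (IQR) with a Wilcoxon
  rank-sum (2 groups) or Kruskal-Wallis (>2) test; categorical get
  counts and within-group percentages with a Pearson chi-squared test.
  Suppression marks cells with 1 ≤ count ≤ 20 (zeros are shown); it is
  display-only, idempotent, and true counts stay internal.
- **Imputation**: covariates with < 20% missingness are singly imputed
  by bagged decision trees (25 estimators; regressor for numeric,
  classifier for categorical, ordinal-encoded predictors); at or above
  the threshold they are left untouched and flagged. Only covariates —
  never outcome or exposure — are imputable.
- **Predictor filtering** (caret-style near-zero variance): constant
  columns; 0/1 indicators below 1% prevalence; columns whose
  top-to-second frequency ratio exceeds 19 *and* whose unique-value
  fraction is under 10% (the conjunction means a continuous covariate
  with a clipped tail is never discarded). Then pairwise |r| > 0.90
  drops the later column.
- **Model**: logistic regression of operative/recurrent (1) versus
  diverticulosis (0), restricted to persons with a decidable unmet-need
  flag. Reference levels: female, insured, income > 100k, at least
  some college. VIFs are computed on the pre-interaction design.
  Interactions: unmet-need × each income and education indicator,
  added after filtering. Newton MLE with a BFGS fallback when the
  Hessian is singular (quasi-separation); standard errors above 50
  raise a separation flag, and non-estimable fits return a flagged
  result instead of raising. Intervals are 95% Wald by default
  (profile likelihood optional).
- **Sensitivity**: the inclusion window is re-applied to the raw
  assignments per variant (default: 2.5-year window; anchoring on the
  healthcare-access or SDOH survey) and the model refit; cohort-size
  deltas are reported next to each fit.

## 7. Synthetic generator (`synthetic_ehr`)

Two paths share one covariate model:

- **Event-level** (`generate_cohort`): for each person an independent
  counter-based substream (`default_rng([seed, 2, i])`) draws
  covariates and constructs a timeline *guaranteed* to realize the
  target class — e.g. the recurrent arm plants two disjoint inpatient
  admissions 30–500 days apart; the operative arm links a procedure to
  a diverticulitis code; excluded timelines carry diverticular codes
  with no confirmation in window; decoy non-diverticular events and
  ED visits are sprinkled everywhere. Class mix defaults to 66%
  control / 23.75% diverticulosis / 5% mild / 1.25% operative / 4%
  excluded; within the diverticulosis+operative contrast pool the
  class is drawn from a logistic outcome model whose unmet-need
  coefficient defaults to ln(1.61) and whose intercept is tuned by
  bisection (80 iterations on a probe design) to a 5% target
  prevalence. Survey responses realize the drawn barrier flags;
  barrier probabilities are graded over deprivation quintiles;
  missingness is planted last (whole instruments removed per person;
  MAR variants shift the masking log-odds by +0.7 for low-income or
  low-education persons).
- **Covariate-level** (`generate_analysis_frame`): the same covariate
  and outcome draw without event construction, for studies needing
  hundreds of replicates. The event-level path is validated separately
  (100% phenotyper agreement at 1000 timelines per class), so the fast
  path does not skip any scientifically load-bearing step when the
  quantity of interest is the regression coefficient.

Determinism: a fixed config reproduces every table exactly; per-person
substreams make person `i` independent of cohort size.

## 8. Problem sizes and runtimes

- Round-trip fidelity: 5 × 1000 timelines (~40 s including demotion
  checks).
- Parameter recovery: 200 replicates × n = 20 000 (~40 s); null
  coverage: 500 replicates × n = 4 000 (~50 s).
- Enrichment consistency: n = 50 000 single draws (<5 s).
- The full pytest suite runs in a few minutes on one CPU.

## 9. Limitations

- The generator plants idealized timelines: codes are consistent with
  the planted class by construction, so round-trip agreement measures
  rule invertibility, not real-world phenotyping accuracy (which the
  validation-metrics module is for, given chart reviews).
- Single imputation understates downstream variance relative to
  multiple imputation; it mirrors the bagged-tree single-imputation
  design the analysis stage specifies.
- The covariate-level recovery path bypasses survey-response realization
  and missingness; recovery under MAR missingness is exercised at
  smaller replicate counts through the event-level pipeline (CLI demo,
  sensitivity tests).
- Interaction cells can be sparse at moderate cohort sizes; the model
  reports quasi-separation rather than regularizing, by design.
- PROMIS global health scores appear in published tables of this kind
  but are not part of the survey battery here; the instrument registry
  is extensible via YAML/`InstrumentSpec` if needed.
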