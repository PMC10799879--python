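# Methods

This note documents the models and procedures implemented in `riskpipe`,
the assumptions behind the synthetic data, the parameters that matter, the
numerical choices, and what the tests do and do not establish.

## Outcome model

Three component outcomes are recognized from coded records. Suicide-related
codes are matched case-insensitively by one anchored regex family — ICD-9
`^e95`; ICD-10 `^T14.91`, `^T3[6789]..X2`, `^T[456]..X2`, `^X[678]..XX`,
`^Y87.0` — with the record context deciding the meaning: a cause-of-death
match is a *suicide*, a clinical match is an *attempt*. Overdoses are
clinical-only: ICD-9 `^e850`, `^e8[67]`, `^e935`; ICD-10 `^T40`. The ICD-9
overdose family plausibly overmatches some non-drug accident codes; it is
used verbatim rather than second-guessed. The combined outcome per patient
and study window takes any suicide death, else the earliest attempt, else
the earliest overdose; same-date ties resolve by that priority order and
then by input record id, so the label is independent of row order and each
patient contributes at most one case event per window.

## Study designs

All designs share one observation convention: predictors may use only
information strictly before the row's *time of prediction*, which ends a
7.5-year window of eight half-open bins (3, 3, 6, 6, 12, 12, 24, 24 months,
most recent first). Months are fixed at 365.25/12 days, giving integer
cumulative boundaries (91, 183, 365, 548, 913, 1278, 2009, 2739 days); a
boundary-dated event belongs to the more recent bin. Fixing month length
makes the schedule identical for every row and every design — the property
cross-prediction depends on — at the cost of drifting up to ~1 day from
calendar months over the window.

- **Rcc (matched nested case-control).** Cases are patients with a
  combined outcome at least 7.5 years + 45 days after calendar start (so a
  full window fits); time of prediction is exactly 45 days before the
  outcome. Four controls per case are drawn from the case's date-of-birth
  partition among patients with no outcome event, by sampling *visits*
  uniformly within the span of case outcome dates in that partition; the
  visit date becomes the control's pseudo-outcome date. Visit-weighted
  sampling over-represents heavy utilizers on purpose. Within one case's
  draw the four controls are distinct patients; across cases a patient may
  serve again (a flag forbids reuse). An unfillable draw raises a shortfall
  report rather than silently reusing; at desk scale this means the
  partition count should be chosen so each partition holds multiple cases
  (the reference configurations use 20 partitions at a few thousand
  patients, 100 at 30,000).
- **Calendar prospective cohorts.** Everyone with a visit in the three
  months before a fixed prediction date (a four-month lookback is a config
  switch, since both conventions are defensible); cases have their outcome
  after a one-week exclusion and within a two-year follow-up. A target
  flag selects the combined outcome or suicide only.
- **Event-triggered time-to-event cohorts.** Time of prediction is the
  first qualifying psychiatric or office visit in a three-year initiation
  window beginning 7.5 years after calendar start; follow-up (default 10
  years) is right-censored on death only — never on last visit — so
  patients who drop out of care still contribute events.
- **Date-of-birth partitioning.** Patients are ranked by DOB (ties by id)
  and split into k contiguous partitions of near-equal size; partition
  parity defines the even/odd train/test halves.

## Base learners

Five kinds share one fit/score contract (scores on the log-odds or
log-hazard scale):

- **L1-penalized logistic regression.** Columns are standardized
  internally; coefficients are reported on the original scale. The penalty
  path (default 20 points, log-spaced over inverse-penalty 1e-3..1) is
  selected by K-fold cross-validation (default 5) on out-of-fold
  per-observation log loss. Selection uses the **1-SE rule**: the strongest
  penalty whose mean CV loss is within one standard error of the minimum,
  with the SE computed from the per-observation loss spread (stable at
  small fold counts). Minimum-deviance selection is available
  (`glm_select="min"`), but on sparse synthetic ground truth it admits
  dozens of spurious near-zero coefficients — the canonical R
  implementation behaves the same way at its `lambda.min` — whereas the
  1-SE rule recovers the generating support, so 1-SE is the default for a
  package whose selected support is itself a reported quantity.
- **Cox proportional hazards** (lifelines), small ridge stabilizer 0.01,
  constant columns dropped before fitting and zero-filled in the reported
  coefficient vector.
- **Random forest**: 500 trees, sqrt-features per split, minimum 100
  samples per leaf.
- **Feed-forward network**: three hidden layers (1024, 512, 256), ReLU,
  early stopping on a validation slice of the training half, fixed seed
  (scikit-learn's MLP; optimizer and epoch budget are package choices —
  Adam, 60 epochs cap — since only the architecture is prescribed).
- **Bernoulli naive Bayes** with additive smoothing 1, included for
  methodology comparison.

A sixth registry slot for an attention-based tabular network (TabNet) is
reserved and deliberately unimplemented. Desk-scale pipeline runs default
to a lighter configuration (128/64 network, 200 trees, 3-fold/12-point
penalty path) so a full run fits in minutes on one CPU; the class defaults
above remain the reference settings and are asserted by tests.

The even/odd protocol trains each kind on both halves; linear kinds
average even- and odd-trained coefficients into the final model, non-linear
kinds designate the odd-trained model as the final evaluator, and every
row's evaluation score comes from the model not trained on it. Base models
whose cohort half has too few cases to cross-validate raise a clean fit
error and are dropped from the registry with a log note — at desk scale the
suicide-only calendar models are the usual casualties, which mirrors how
non-converging prospective models are handled in practice.

## Ensemble fine-tuning

The stacking layer is an unpenalized logistic regression of the target
outcome on the base scores plus exactly ten covariates: female sex,
non-white race, Hispanic ethnicity, age < 55, age > 65, any-window chronic
pain, suicide ideation, suicide attempt and overdose indicators, and the
utilization index (count of active diagnosis-variable × bin cells,
0..75×8 = 600). "Young or old" is implemented as the two age flags, making
the ten. Base scores enter unstandardized; their range is roughly five
times that of the binary covariates, and coefficient magnitudes are read
accordingly. No cross-validation and no model selection: fine-tuning is
meant to touch only the degrees of freedom that shift with study design.
Complete separation (easy in small cohorts) falls back to a tiny ridge
(1e-6, via a large-C logistic fit) with a recorded note; exact duplicate
columns are dropped with one retained and logged. Bases trained on the
target cohort itself (the target-calendar logistic model) contribute their
*out-of-half* scores to the stacking matrix and to the reported base
AUROCs, so neither the fitted ensemble weights nor any comparison uses a
score from a model that saw the row; transfer bases score the cohort with
their final models, which are out-of-sample by construction. Two ensembles are built
on the target calendar cohort: the combined-outcome ensemble excludes the
earlier-calendar suicide-trained base and the suicide ensemble excludes
the earlier-calendar combined-trained base, keeping seven bases in each
under the full registry (the published description of the registry is
ambiguous between a 7-model list and an 8-minus-1 census; the
8-minus-1 reading is the default and the registry is configurable).

## Evaluation

AUROC is computed from midranks (exact tie handling); AUPRC is the
step-sum average precision over distinct thresholds; Harrell's c counts a
pair admissible when the event-bearing patient's time is strictly shorter,
or equal with the comparator censored, with score ties counting one half.
All three have exhaustive pairwise/threshold oracles in the package and
the fast paths are required to agree with them to 1e-12. Calibration
tables bin log-odds scores at width 0.5 (configurable; the choice is a
display convention), report observed event fractions with exact
Clopper-Pearson intervals, the sigmoid of the bin center as the nominal
expectation, and the mean predicted probability in the bin as the exact
well-specified reference used by the coverage check. Subgroups below 11
rows are skipped (a cosmetic reporting floor, configurable).
Concentration of risk ranks rows by score with deterministic tie-breaks
(strata are therefore nested), takes the top round(qN) rows, and reports
the stratum event rate over the overall rate; it equals 1 in expectation
under label-independent scores and exactly 1/prevalence under perfect
ranking with q ≤ prevalence. The drift scenario freezes an ensemble
fine-tuned at the target date, applies it to a later-calendar cohort
(optionally with a recording changepoint injected between the two dates),
and compares against a fine-tuning refreshed on the later cohort.

## Synthetic data: what it emulates and what it does not

Each patient gets a DOB (1930–1985), sex/race/ethnicity, one area-level
covariate, and a yearly visit intensity drawn log-normal (median 2.5
visits/year, σ = 0.8) — the heavy-tailed utilization heterogeneity the
matched design must absorb. Visits per calendar year (2000–2021) are
Poisson; each of 75 diagnosis variables and 15 medication/procedure
variables is emitted per visit with a fixed probability (named clinical
variables at realistic per-visit rates, filler variables on a geometric
tail). Labs/vitals (blood pressure for pulse pressure, hemoglobin, A1c,
eGFR) are measured at a configurable per-visit rate with patient-level
baselines; PHQ surveys occur at psychiatric visits and correlate with
recent suicide-ideation coding.

Outcomes follow a discrete-time annual Bernoulli hazard per component,
evaluated on the trailing 8-year presence state (a yearly-resolution
analogue of the 8-bin encoding): intercept + per-variable log-odds +
age effect (−0.15/decade, centered at 55) + utilization effect (+0.01 per
active variable-year cell — the built-in confounding) + effects of past
attempts/overdoses, which are written back into the event stream so risk
is self-exciting. Suicide is terminal and unique; attempts and overdoses
recur. Attempt, overdose and suicide-death records carry real ICD codes
(ICD-9 before October 2015, ICD-10 after) so the regex classifier is
genuinely exercised; other variables carry representative non-matching
codes. Nothing postdates death. A config multiplier can drop a fraction of
*recorded* attempts after the ICD changeover while leaving the underlying
events untouched, emulating the recording discontinuity that the drift
scenario probes.

Default intercepts give roughly 2% of patients a suicide and ~20% a
combined outcome over 22 years. These rates are deliberately one to two
orders of magnitude above the real system's so that desk-scale populations
(1,500–30,000 patients) contain enough cases to fit and evaluate models;
the suicide-to-combined ratio (~1:10) preserves the regime the method
targets. Consequences of the simplifications: no true ICD ontology or
free-text, one undifferentiated clinical event stream (no
inpatient/fee-basis distinction), annual rather than continuous hazard
resolution, independent per-visit variable emissions (no comorbidity
correlation structure beyond shared utilization), and no census/geographic
realism beyond a single synthetic area covariate. Passing tests therefore
establish that the *pipeline machinery* is correct and well calibrated
against a known generative process — not that real-data coefficient values
or headline c-statistics would be reproduced, which requires the
access-restricted source data.

## Numerical choices and degenerate inputs

Dates are integer days since the Unix epoch; intervals are half-open
[start, end). Stage seeds derive from the global seed by hashing stage
names (all below 2^31). Tree/NB/network scores are converted to log-odds
with probability clipping at 1e-9. Events dated at or after a row's time
of prediction are outside every bin by construction; a brute-force
leakage audit re-derives feature cells from raw event dates and counts
violations. All-constant designs, single-class targets, no-event Cox
inputs, empty even/odd halves, unknown code systems and out-of-range
survey scores raise typed errors naming the offending input. Pipeline
stage outputs are cached on disk keyed by a config fingerprint; deleting
an intermediate regenerates only downstream stages, and reruns with an
unchanged config are byte-identical.

## Known limitations

The Rcc "same period" eligibility reading (span of case outcome dates per
partition) degenerates when a partition holds a single case; choose the
partition count to the population size. The Cox models fit the full
~950-column design with a small ridge rather than an L1 path (desk-scale
cost); their role in the ensemble is secondary, matching their small
fitted weights. The drift scenario manipulates recording rates only —
true coefficient drift (changing hazards) can be configured through the
generating model but has no dedicated scenario. Suicide-only targets at
small n routinely separate or lose their calendar base models; that
behavior is surfaced, not hidden, and disappears at larger n.
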