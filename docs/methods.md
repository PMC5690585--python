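# Methods

## The index

The package operationalizes frailty with the cumulative-deficit model: a
person's multimorbidity frailty index (mFI) is the unweighted proportion of
catalog deficits present, `mFI = d / D` with `d` the number of deficits
present and `D` the catalog size, so `mFI ∈ [0, 1]` and larger is frailer.
Deficits are 3-digit ICD-9-CM roots; the decimal point is stripped before
truncation, so `428.0`, `4280` and `428` are one root. Codes shorter than
three characters after normalization are rejected as unparseable.

Presence requires ≥ 3 outpatient claims or ≥ 1 inpatient claim carrying the
root within the one-year baseline window — a specificity filter against
rule-out and transcription diagnoses. Each claim line counts once per root
no matter how many of its listed codes share that root.

### Deficit selection

Candidates are all roots observed in the cohort's baseline claims. The
three criteria are evaluated independently and a root is selected only on
their conjunction, with *strict* inequalities throughout:

- **(i) prevalence** — rule-qualified presence prevalence > 0.02. We
  compute prevalence of *qualified* presence (after the claim-count rule),
  not raw code occurrence, because the catalog is meant to describe
  deficits as defined, and we expose the threshold as a parameter.
- **(ii) age trend** — ordinary least squares of band prevalence on the
  band index 0–4 (bands 65–69, 70–74, 75–79, 80–84, ≥ 85) with slope > 0
  and R² > 0.30. The band index is used as the abscissa because the
  open-ended ≥ 85 band has no midpoint; slope sign and R² are invariant to
  any affine recoding of an equally spaced abscissa, so the choice only
  affects the slope's reported scale. When all bands are equal the total
  sum of squares is zero and R² is undefined; such codes fail (ii) (their
  slope is 0 anyway). If fewer than 3 age bands are populated, the
  regression is not attempted and the code fails (ii) with an
  `insufficient_bands` note.
- **(iii) non-saturation** — prevalence in the youngest populated band
  strictly below 1.0.

V- and E-codes are admitted as candidates by default (a `numeric_only`
switch restricts to 001–999 roots). Full diagnostics (overall and band
prevalences, slope, R², the three pass flags) are emitted for every
candidate, selected or not.

### Categorization

Fixed cut points 0.0625 / 0.125 / 0.1875 define fit, mild, moderate and
severe frailty. Printed ranges of the form "0–0.0625 fit, 0.0625–0.125
mild" overlap at the cut points; only "severe > 0.1875" is unambiguous,
which implies a cut point belongs to the *lower* category. We apply that
right-closed convention uniformly: fit = [0, 0.0625], mild =
(0.0625, 0.125], moderate = (0.125, 0.1875], severe = (0.1875, 1]. With a
32-item catalog the scores are exact binary fractions (k/32), so the
boundary comparisons are exact in floating point and category is a
function of the deficit count alone: fit ≤ 2, mild 3–4, moderate 5–6,
severe ≥ 7. Quantile categorization (tertile/quartile/quintile) is the
sensitivity scheme; ties at an empirical cut point go to the lower group,
and with heavy ties (many zero scores) duplicate cut points are collapsed
with a logged warning.

## Cohort and outcomes

Eligibility: completed age 65–100 at the baseline window start (2005-01-01
by default — the reference date is a package convention, chosen because it
is deterministic and matches "aged 65–100 with full coverage in the
baseline year" at window entry) and coverage spanning the whole baseline
window. Death is recorded as disenrollment, so a baseline-year death
necessarily fails the coverage criterion. Every excluded person is counted
under exactly one first-failing criterion (age → death during baseline →
coverage).

Outcomes over follow-up (2006-01-01 to 2013-12-31 by default):

- **death** — the disenrollment-due-to-death date;
- **unplanned hospitalization** — first inpatient admission flagged as
  following an emergency-department visit; ED visits billed as outpatient
  claims are accepted on input but never count as hospitalizations;
- **ICU admission** — first inpatient admission with ICU services.

Follow-up time is measured in days with the start date counted as day 1,
so 1/5/8-year horizons are 365/1826/2922 days (calendar-exact, leap days
included). Non-fatal outcomes are censored at death; a same-day admission
and death counts as the event (the event precedes censoring within a day).
Disenrollment for reasons other than death is right-censoring at coverage
end. Baseline-year (2005) admissions never count as outcomes because
follow-up starts 2006-01-01.

## Statistics

- **Kaplan–Meier / log-rank** per frailty category (lifelines); censored
  times do not step the curve; the k-group log-rank statistic has k−1
  degrees of freedom.
- **Cox proportional hazards** via partial-likelihood maximization
  (statsmodels `PHReg`), Breslow tie handling by default with Efron
  available by switch. The unadjusted model uses category indicators (fit
  as reference); the adjusted model adds age (continuous, in years) and
  sex (male = 1). Hazard ratios are `exp(β)` with Wald 95% CIs
  `exp(β ± 1.959964·SE)`. Degenerate fits (no events: error; monotone
  likelihood or singular information: flagged `converged=False` with
  NaN/diagnostic notes rather than a silent estimate). A closed-form score
  test at β = 0 (Breslow score and information) is provided; with no tied
  event times and a binary covariate it reproduces the classical log-rank
  statistic.
- **Discrimination** at each horizon treats "event by the horizon" as a
  binary outcome. Persons censored before the horizon for reasons other
  than death are dropped (their status is unknown; the count is logged);
  death-censored persons are event-free controls, and for the death
  outcome survivors are controls. The logistic model on a k-level
  categorical predictor is saturated, so its MLE fitted probabilities are
  the per-level event rates; we use this closed form, which stays defined
  under perfect separation where an iterative fit diverges. The
  C-statistic is the concordance of fitted probabilities (a Mann–Whitney
  rank statistic over case/control pairs); Cox–Snell and Nagelkerke
  pseudo-R² come from the binomial log-likelihoods. We use the indicator
  (4-level class) parameterization; an ordinal single-score variant would
  give the same C because the level event rates are monotone in practice.

## The synthetic panel

The generator exists so that every downstream stage has a recoverable
answer; it emulates the *structure* of a national claims panel, not any
real epidemiology.

- **Demographics.** Age bands 65–69 … ≥ 85 drawn with weights
  0.3306/0.2752/0.2179/0.1153/0.0610 (the band composition of a large
  East-Asian insured cohort of older adults; resulting mean age ≈ 73.9),
  uniform ages within closed bands and a geometric tail within ≥ 85;
  49.82% male. A small fraction (2%) of extra registry rows is ineligible
  (wrong age or partial coverage) so the cohort screen is exercised.
- **Diagnosis codes.** Each code root has five band prevalences. The
  default study-scale configuration plants 32 strictly age-rising chronic
  roots whose rule-qualified overall prevalences are spread over 3.0–7.5%
  (mean ≈ 5.2%, so the expected mean index over 32 items is ≈ 0.052),
  plus decoys: a "diabetes" code (250) at exactly 18.15% overall whose
  band profile peaks at 70–74 and declines beyond 85 (net OLS slope ≈
  −0.015/band) — common but not age-rising, hence excluded by criterion
  (ii); two constant-prevalence codes at 1.2–1.5% (excluded by (i)); two
  rare rising codes (excluded by (i)); and an every-person health-exam
  code V70 at 100% in all bands (excluded by (iii)). The diabetes profile
  is deliberately *systematically* non-increasing rather than exactly
  flat: for an exactly flat profile the empirical 5-point R² is
  scale-free noise (Beta(1/2, 3/2) whatever the sample size), so no
  sample size could keep criterion (ii) from selecting it occasionally,
  whereas survivorship-shaped decline is both the realistic pattern for
  diabetes in the very old and deterministically rejected.
- **Claims.** Present codes emit `min + Poisson` outpatient claim counts
  and an inpatient admission with a per-code probability, so some present
  codes fail the ≥3/≥1 rule by design — presence-with-insufficient-claims
  is a distinct truth state the generator records. Codes are rendered with
  random 4th digits / decimal points to exercise truncation. Claim dates
  are uniform within the baseline year (timing within the year does not
  enter the index). Irrelevant outpatient noise claims use a disjoint pool
  of acute-code roots.
- **Correlation.** Deficits are conditionally independent given one
  shared latent frailty factor per person: a Gaussian (SD 0.8 by default)
  added to every code's presence log-odds. Band intercepts are calibrated
  by quadrature + bisection so *marginal* band prevalences equal the
  specification exactly; the factor induces the positive deficit
  correlation and right-skewed index tail seen in real cohorts (with the
  default configuration: ≈ 75% fit, ≈ 3% severe, 99th percentile 0.250).
  Setting the SD to 0 gives independent deficits.
- **Outcomes.** Exponential (constant-hazard) survival per outcome with
  log-linear effects: hazard = baseline × exp(β_cat + β_age(age−75) +
  β_male). Defaults: baselines 0.035/0.10/0.045 events/person-year for
  death/hospitalization/ICU in the fit 75-year-old female reference;
  category log-hazards ln 2 / ln 3 / ln 5 (mild/moderate/severe — a
  gradient of the magnitude reported for claims-based frailty indices);
  β_age 0.07 (death) or 0.05 per year; β_male 0.35/0.15/0.25. The "true"
  category driving the hazard is computed from the rule-qualified presence
  of the planted roots, so a correct downstream pipeline can recover the
  coefficients without misclassification bias. Constant hazards are the
  simplest generator consistent with proportional hazards, making Cox
  recovery exact in expectation. Event times are drawn uncensored (ceil of
  the exponential draw in days, 365.2425 days/year); hospital events
  falling before min(death, window end) are emitted as ED-/ICU-flagged
  inpatient claims, alongside planned (non-ED) admissions and outpatient
  ED visits that the outcome filters must ignore. Everyone survives the
  baseline year by construction.

What the generator does **not** emulate: real disease ontology or
code-specific epidemiology, sex-specific prevalences (e.g. prostate codes
in men only), seasonality or visit clustering, competing-risk structure
beyond death censoring, disenrollment other than death, and time-varying
frailty. Passing tests therefore demonstrate the pipeline's arithmetic and
statistical correctness under a proportional-hazards world, not clinical
validity of the index on any real population.

## Numerical choices and problem sizes

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical config + seed reproduce byte-identical
CSV outputs (floats are written with `%.10g`). The test suite runs the
study-scale recovery checks at n = 20,000 subjects (20 seeds for deficit
recovery), the selection-oracle equivalence on 100 random 500-person
cohorts, and Cox CI coverage over 200 replicates at n = 5,000 — sizes at
which every recovery margin is several standard errors wide. Quantile
categories use `numpy.quantile` with ties to the lower group. Cox fits
declare non-convergence for non-finite or absurd (|β| > 30) estimates and
singular information matrices.

## Known limitations

- ICD-9-CM only; no ICD-10 mapping.
- First-event analyses only; no recurrent events, competing-risks
  (Fine–Gray) models, time-varying covariates or random-effect survival
  terms.
- The ED-visit linkage of a real claims database is collapsed into a
  per-admission `ed_flag` on input.
- The supremum-type proportional-hazards diagnostic offered by some
  commercial survival procedures is not implemented.
- Exact boundary ownership at the category cut points is a declared
  convention (right-closed), not an empirically recoverable fact.
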