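# mfi — a claims-based multimorbidity frailty index

`mfi` builds a cumulative-deficit frailty index from administrative health
insurance claims and quantifies how well it predicts death and
hospitalization in older adults. It is aimed at epidemiologists and health
services researchers who have (or want to prototype against) a beneficiary
registry plus outpatient/inpatient claim lines with ICD-9-CM diagnosis
codes, and who want a population-scale frailty measure without clinical
assessment instruments.

## The method

In the cumulative-deficit model, frailty is the fraction of a fixed catalog
of health deficits an individual exhibits:

```
mFI_i = (number of deficits present in person i) / (number of catalog items)
```

Deficit items are 3-digit ICD-9-CM code roots ("428" for heart failure,
"332" for Parkinson's disease, …) observed in one baseline year. A root is
*present* for a person when the year holds at least 3 outpatient claims or
at least 1 inpatient claim carrying it. A candidate root enters the catalog
only if, in the study cohort (ages 65–100 with full baseline-year
coverage):

1. its presence prevalence exceeds 2%;
2. prevalence *rises with age*: regressing band prevalence on the five age
   bands 65–69, 70–74, 75–79, 80–84, ≥85 gives a positive slope with
   R² > 0.30;
3. it is not already universal by age 65 (100% prevalence carries no
   signal).

Individuals are categorized as fit (mFI ≤ 0.0625), mild (≤ 0.125), moderate
(≤ 0.1875) or severe (> 0.1875) frailty — the 2/32, 4/32 and 6/32 multiples
of a 32-item catalog. Outcomes over an 8-year follow-up — all-cause death,
unplanned hospitalization (admission after an emergency-department visit)
and ICU admission — are analysed at 1/5/8-year horizons with Kaplan–Meier
curves and log-rank tests, bivariate and age/sex-adjusted Cox
proportional-hazards models (`HR = exp(β)`, Wald 95% CIs), and horizon-wise
discrimination (C-statistic, Cox–Snell and Nagelkerke pseudo-R²).

Real claim panels of this kind are not redistributable, so the package
ships a synthetic-panel generator with known ground truth: which code roots
genuinely accumulate with age, each person's latent deficit state, and
exponential proportional-hazards outcome models whose category log-hazards
(ln 2, ln 3, ln 5), age and sex effects the downstream fits must recover.

## Worked example

Either run the numbered drivers (they write under `results/`):

```sh
python analysis/01_simulate_cohort.py     # synthetic panel + ground truth
python analysis/02_select_deficits.py     # cohort screen + deficit catalog
python analysis/03_score_frailty.py       # mFI scores + summary table
python analysis/04_derive_outcomes.py     # time-to-event datasets
python analysis/05_survival_analysis.py   # KM / Cox / discrimination
```

or the equivalent single command `mfi run-all --out results/run --seed 1`.
On the default 20,000-subject panel the drivers print:

```
cohort: 20000 members; excluded {'age': 187, 'coverage': 213}
candidates: 58 code roots; selected: 32
recovery vs ground truth: exact match = True
diabetes decoy (250): prevalence 0.1829, slope -0.0144 -> selected = False
mFI mean 0.052 (SD 0.059), median 0.031, 99th pct 0.250
category shares: fit 76.11%, mild 16.00%, moderate 5.26%, severe 2.62%
adjusted 1-year mortality hazard ratios (vs fit):
  category[mild]         HR 1.85 (95% CI 1.60-2.15)
  category[moderate]     HR 3.25 (95% CI 2.72-3.89)
  category[severe]       HR 6.02 (95% CI 5.00-7.23)
```

Reading this: the selection stage recovered exactly the 32 planted
age-rising codes while rejecting the common-but-flat diabetes code (18%
prevalence, no age trend — criterion 2), the index distribution is
right-skewed with the familiar mean ≈ 0.05, and the age/sex-adjusted Cox
fits recover the planted roughly 2-/3-/5-fold mortality gradient across
frailty categories within sampling error.

The library can equally ingest real files in the documented dialect:

```python
import mfi
bene = mfi.read_beneficiaries("beneficiaries.csv")
claims = mfi.read_claims("claims.csv")
cohort = mfi.select_study_cohort(bene)
presence = mfi.build_presence_matrix(cohort, claims)
catalog = mfi.select_deficits(presence, cohort)
scores = mfi.score_frailty(presence, catalog)
```

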