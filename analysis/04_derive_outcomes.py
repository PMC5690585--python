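"""Derive the three outcomes and assemble time-to-event datasets.

Death comes from the disenrollment date, unplanned hospitalization from the
first ED-preceded inpatient admission, ICU admission from the first
ICU-flagged admission; non-fatal outcomes are censored at death, and every
outcome is assembled at the 1-, 5- and 8-year horizons. Writes
survival_{outcome}_{horizon}y.csv under results/.
"""

from pathlib import Path

import mfi

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    data = RESULTS / "data"
    beneficiaries = mfi.read_beneficiaries(data / "beneficiaries.csv")
    claims = mfi.read_claims(data / "claims.csv")
    cohort = mfi.select_study_cohort(beneficiaries)
    presence = mfi.build_presence_matrix(cohort, claims)
    catalog = mfi.select_deficits(presence, cohort)
    scores = mfi.score_frailty(presence, catalog)

    datasets = mfi.build_all_survival_datasets(cohort, scores, beneficiaries, claims)
    for (outcome, horizon), df in sorted(datasets.items()):
        path = RESULTS / f"survival_{outcome}_{horizon}y.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        rate = 100 * df["event"].mean()
        print(f"{outcome:28s} {horizon}y: {df['event'].sum():6d} events ({rate:5.2f}%)")


if __name__ == "__main__":
    main()
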