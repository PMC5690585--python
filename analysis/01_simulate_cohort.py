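"""Simulate the study panel: one baseline claims year plus 8 years of follow-up.

Writes beneficiaries.csv, claims.csv and ground_truth.json (the planted
deficit codes, per-person latent states and true hazard coefficients) under
results/data/. Later numbered scripts start from these files.
"""

import argparse
from pathlib import Path

import mfi

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-subjects", type=int, default=20_000)
    parser.add_argument("--seed", type=int, default=20050101)
    args = parser.parse_args()

    outdir = RESULTS / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    config = mfi.default_study_config(n_subjects=args.n_subjects, seed=args.seed)
    beneficiaries, claims, truth = mfi.generate_cohort(config)
    mfi.write_beneficiaries(beneficiaries, outdir / "beneficiaries.csv")
    mfi.write_claims(claims, outdir / "claims.csv")
    truth.to_json(outdir / "ground_truth.json")

    n_deaths = beneficiaries["death_date"].notna().sum()
    print(f"wrote {len(beneficiaries)} beneficiaries ({len(claims)} claim lines) -> {outdir}")
    print(f"  planted age-rising deficit codes: {len(truth.true_deficit_roots)}")
    print(f"  deaths during follow-up: {n_deaths}")
    print(
        "  presence-without-enough-claims states: "
        f"{int(truth.insufficient_claims.to_numpy().sum())}"
    )


if __name__ == "__main__":
    main()
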