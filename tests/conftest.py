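import numpy as np
import pandas as pd
import pytest

import mfi
from mfi.simulate import ClaimCountDist, CodeSpec, OutcomeModel, SimulationConfig


def make_beneficiaries(rows):
    """Build a beneficiaries frame from (person_id, sex, birth, cov_start, cov_end, death)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "sex",
            "birth_date",
            "coverage_start",
            "coverage_end",
            "death_date",
        ],
    )
    for col in ("birth_date", "coverage_start", "coverage_end", "death_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_claims(rows):
    """Build a claims frame from (person_id, setting, service, admit, discharge, codes, ed, icu)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "setting",
            "service_date",
            "admission_date",
            "discharge_date",
            "diagnosis_codes",
            "ed_flag",
            "icu_flag",
        ],
    )
    for col in ("service_date", "admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def outpatient(pid, date, codes):
    return (pid, "outpatient", date, None, None, codes, False, False)


def inpatient(pid, admit, discharge, codes, ed=False, icu=False):
    return (pid, "inpatient", None, admit, discharge, codes, ed, icu)


@pytest.fixture
def tiny_cohort():
    """Three eligible members spanning three age bands."""
    bene = make_beneficiaries(
        [
            ("A", "female", "1938-06-01", "2000-01-01", "2013-12-31", None),
            ("B", "male", "1930-03-15", "2000-01-01", "2013-12-31", None),
            ("C", "female", "1919-11-02", "2000-01-01", "2009-05-20", "2009-05-20"),
        ]
    )
    return bene, mfi.select_study_cohort(bene)


def small_sim_config(n=500, seed=0, rng=None, n_codes=20):
    """Randomized small simulation config with a mix of code kinds."""
    rng = rng or np.random.default_rng(seed)
    specs = []
    kinds = ["age_rising", "flat", "rare", "near_universal"]
    for i in range(n_codes):
        kind = kinds[i % len(kinds)]
        root = f"{100 + i:03d}"
        if kind == "age_rising":
            base = rng.uniform(0.02, 0.15)
            step = rng.uniform(0.2, 0.6) * base
            bands = tuple(base + step * b for b in range(5))
        elif kind == "flat":
            bands = (float(rng.uniform(0.005, 0.3)),) * 5
        elif kind == "rare":
            base = rng.uniform(0.001, 0.008)
            bands = tuple(base + 0.001 * b for b in range(5))
        else:
            bands = (1.0,) * 5
        specs.append(
            CodeSpec(
                code_root=root,
                kind=kind,
                prevalence_by_age_band=bands,
                outpatient_claims=ClaimCountDist(
                    int(rng.integers(0, 4)), float(rng.uniform(1.0, 4.0))
                ),
                inpatient_probability=float(rng.uniform(0.0, 0.4)),
            )
        )
    return SimulationConfig(
        n_subjects=n,
        code_specs=specs,
        outcome_models={
            "death": OutcomeModel(
                baseline_hazard=0.04, log_hr_category=(0.5, 1.0, 1.5)
            ),
            "unplanned_hospitalization": OutcomeModel(
                baseline_hazard=0.09, log_hr_category=(0.5, 1.0, 1.5)
            ),
            "icu_admission": OutcomeModel(
                baseline_hazard=0.05, log_hr_category=(0.5, 1.0, 1.5)
            ),
        },
        noise_code_roots=("780", "786"),
        noise_claim_rate=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_panel():
    """One study-scale synthetic panel shared across expensive tests."""
    config = mfi.default_study_config(n_subjects=20_000)
    beneficiaries, claims, truth = mfi.generate_cohort(config, seed=20050101)
    return config, beneficiaries, claims, truth


@pytest.fixture(scope="session")
def default_analysis(default_panel):
    """Cohort, presence matrix, catalog and scores for the shared panel."""
    _, beneficiaries, claims, truth = default_panel
    cohort = mfi.select_study_cohort(beneficiaries)
    presence = mfi.build_presence_matrix(cohort, claims)
    catalog = mfi.select_deficits(presence, cohort)
    scores = mfi.score_frailty(presence, catalog)
    return cohort, presence, catalog, scores
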