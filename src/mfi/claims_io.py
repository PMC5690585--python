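"""Claims-table I/O and study-cohort screening.

The package reads and writes a small, self-documented delimited-text dialect
for administrative claims panels:

``beneficiaries.csv``
    ``person_id,sex,birth_date,coverage_start,coverage_end,death_date``

``claims.csv``
    ``person_id,setting,service_date,admission_date,discharge_date,
    diagnosis_codes,ed_flag,icu_flag``

All files are UTF-8 with one header row; dates are ISO-8601 (``YYYY-MM-DD``),
missing optional fields are empty strings, ``diagnosis_codes`` is a
``;``-separated list of ICD-9-CM codes (with or without the decimal point),
and boolean flags are ``true``/``false``. Writers emit the same dialect
bit-exactly, so a write/read round trip reproduces identical records.

Cohort screening selects beneficiaries aged 65-100 (completed years at the
start of the baseline year) with insurance coverage spanning the full
baseline window; anyone dying during the baseline year necessarily fails the
coverage criterion because death is recorded as disenrollment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BENEFICIARY_COLUMNS = [
    "person_id",
    "sex",
    "birth_date",
    "coverage_start",
    "coverage_end",
    "death_date",
]

CLAIM_COLUMNS = [
    "person_id",
    "setting",
    "service_date",
    "admission_date",
    "discharge_date",
    "diagnosis_codes",
    "ed_flag",
    "icu_flag",
]

SEXES = ("male", "female")
SETTINGS = ("outpatient", "inpatient")

#: Closed lower edges of the five analysis age bands (the last is open-ended).
AGE_BAND_EDGES = (65, 70, 75, 80, 85)
AGE_BAND_LABELS = ("65-69", "70-74", "75-79", "80-84", ">=85")

DEFAULT_BASELINE_WINDOW = (pd.Timestamp("2005-01-01"), pd.Timestamp("2005-12-31"))
DEFAULT_FOLLOWUP_WINDOW = (pd.Timestamp("2006-01-01"), pd.Timestamp("2013-12-31"))
DEFAULT_AGE_RANGE = (65, 100)


class SchemaError(ValueError):
    """A table row violates the documented dialect.

    Carries the offending 1-based data row (header = row 1, first data row
    = row 2) and column name where they are known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            if column is not None:
                loc += f", column '{column}'"
            loc += "]"
        super().__init__(message + loc)
        self.row = row
        self.column = column


def _parse_dates(raw: pd.Series, column: str, required: bool) -> pd.Series:
    stripped = raw.str.strip()
    parsed = pd.to_datetime(stripped, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (stripped != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"malformed date {stripped.iloc[i]!r}", row=i + 2, column=column
        )
    if required and (stripped == "").any():
        i = int(np.flatnonzero((stripped == "").to_numpy())[0])
        raise SchemaError("missing required date", row=i + 2, column=column)
    return parsed


def _parse_flag(raw: pd.Series, column: str) -> pd.Series:
    stripped = raw.str.strip().str.lower()
    mapping = {"true": True, "1": True, "false": False, "0": False, "": False}
    bad = ~stripped.isin(mapping)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unparseable boolean {raw.iloc[i]!r}", row=i + 2, column=column
        )
    return stripped.map(mapping).astype(bool)


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    return df


def read_beneficiaries(path) -> pd.DataFrame:
    """Read a beneficiary registry, validating the schema row by row.

    Returns a frame with one row per ``person_id`` and parsed calendar
    dates (``death_date`` is ``NaT`` when absent).
    """
    raw = _read_table(path, BENEFICIARY_COLUMNS)
    person_id = raw["person_id"].str.strip()
    if (person_id == "").any():
        i = int(np.flatnonzero((person_id == "").to_numpy())[0])
        raise SchemaError("empty person_id", row=i + 2, column="person_id")
    dup = person_id.duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"duplicate person_id {person_id.iloc[i]!r}", row=i + 2, column="person_id"
        )
    sex = raw["sex"].str.strip()
    bad_sex = ~sex.isin(SEXES)
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise SchemaError(f"unknown sex code {sex.iloc[i]!r}", row=i + 2, column="sex")

    out = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_date": _parse_dates(raw["birth_date"], "birth_date", required=True),
            "coverage_start": _parse_dates(
                raw["coverage_start"], "coverage_start", required=True
            ),
            "coverage_end": _parse_dates(
                raw["coverage_end"], "coverage_end", required=True
            ),
            "death_date": _parse_dates(raw["death_date"], "death_date", required=False),
        }
    )
    bad = out["coverage_start"] > out["coverage_end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            "coverage_start after coverage_end", row=i + 2, column="coverage_start"
        )
    has_death = out["death_date"].notna()
    bad = has_death & (out["death_date"] < out["birth_date"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError("death_date before birth_date", row=i + 2, column="death_date")
    return out


def write_beneficiaries(beneficiaries: pd.DataFrame, path) -> None:
    out = beneficiaries.copy()
    for col in ("birth_date", "coverage_start", "coverage_end", "death_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out[BENEFICIARY_COLUMNS].to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    """Read claim lines; ``diagnosis_codes`` becomes a list of code strings.

    Outpatient rows need a ``service_date``; inpatient rows need
    ``admission_date <= discharge_date``. An outpatient row carrying an
    ``icu_flag`` (or ``ed_flag``) is accepted — ED visits may be billed as
    outpatient claims — but inpatient-only flags are ignored downstream and
    an ``icu_flag`` on an outpatient row is logged as a warning.
    """
    raw = _read_table(path, CLAIM_COLUMNS)
    setting = raw["setting"].str.strip()
    bad = ~setting.isin(SETTINGS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown setting {setting.iloc[i]!r}", row=i + 2, column="setting"
        )
    out = pd.DataFrame(
        {
            "person_id": raw["person_id"].str.strip(),
            "setting": setting,
            "service_date": _parse_dates(raw["service_date"], "service_date", False),
            "admission_date": _parse_dates(
                raw["admission_date"], "admission_date", False
            ),
            "discharge_date": _parse_dates(
                raw["discharge_date"], "discharge_date", False
            ),
            "ed_flag": _parse_flag(raw["ed_flag"], "ed_flag"),
            "icu_flag": _parse_flag(raw["icu_flag"], "icu_flag"),
        }
    )
    outp = out["setting"] == "outpatient"
    bad = outp & out["service_date"].isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            "outpatient claim missing service_date", row=i + 2, column="service_date"
        )
    inp = ~outp
    for col in ("admission_date", "discharge_date"):
        bad = inp & out[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"inpatient claim missing {col}", row=i + 2, column=col)
    bad = inp & (out["admission_date"] > out["discharge_date"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            "discharge_date before admission_date", row=i + 2, column="admission_date"
        )
    codes = (
        raw["diagnosis_codes"]
        .str.split(";")
        .map(lambda cs: [c.strip() for c in cs if c.strip()])
    )
    empty = codes.map(len) == 0
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise SchemaError("empty diagnosis_codes", row=i + 2, column="diagnosis_codes")
    out["diagnosis_codes"] = codes

    n_odd = int((outp & out["icu_flag"]).sum())
    if n_odd:
        logger.warning(
            "%d outpatient claim(s) carry icu_flag=true; the flag is ignored "
            "downstream (ICU admission requires an inpatient claim)",
            n_odd,
        )
    return out[CLAIM_COLUMNS]


def write_claims(claims: pd.DataFrame, path) -> None:
    out = claims.copy()
    for col in ("service_date", "admission_date", "discharge_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out["diagnosis_codes"] = out["diagnosis_codes"].map(";".join)
    for col in ("ed_flag", "icu_flag"):
        out[col] = out[col].map({True: "true", False: "false"})
    out[CLAIM_COLUMNS].to_csv(path, index=False)


def claim_dates(claims: pd.DataFrame) -> pd.Series:
    """Anchor date of each claim: service date (outpatient) or admission date."""
    return claims["service_date"].where(
        claims["setting"] == "outpatient", claims["admission_date"]
    )


def completed_age(birth_dates: pd.Series, ref_date: pd.Timestamp) -> pd.Series:
    """Completed years of age at ``ref_date`` (birthday not yet reached counts down)."""
    ref = pd.Timestamp(ref_date)
    before_birthday = (birth_dates.dt.month > ref.month) | (
        (birth_dates.dt.month == ref.month) & (birth_dates.dt.day > ref.day)
    )
    return (ref.year - birth_dates.dt.year - before_birthday.astype(int)).astype(int)


def age_band_index(ages) -> np.ndarray:
    """Map ages to analysis band indices 0..4 (65-69, 70-74, 75-79, 80-84, >=85)."""
    ages = np.asarray(ages)
    return np.clip((ages - AGE_BAND_EDGES[0]) // 5, 0, 4).astype(int)


@dataclass
class StudyCohort:
    """Eligible study population with per-person age (at baseline start) and sex.

    ``members`` has columns ``person_id, sex, age, age_band``; ``exclusions``
    counts excluded persons by their first failing criterion, in the order
    age -> death during baseline -> coverage.
    """

    baseline_window: tuple[pd.Timestamp, pd.Timestamp]
    followup_window: tuple[pd.Timestamp, pd.Timestamp]
    members: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    @property
    def person_ids(self) -> pd.Index:
        return pd.Index(self.members["person_id"])

    def __len__(self) -> int:
        return len(self.members)


def select_study_cohort(
    beneficiaries: pd.DataFrame,
    baseline_window=DEFAULT_BASELINE_WINDOW,
    age_range=DEFAULT_AGE_RANGE,
    followup_window=DEFAULT_FOLLOWUP_WINDOW,
) -> StudyCohort:
    """Screen the registry for the study cohort.

    Eligibility: completed age at the baseline start within ``age_range``
    (inclusive) and coverage spanning the full baseline window. Each
    excluded person is attributed to exactly one first-failing criterion.
    """
    start, end = (pd.Timestamp(baseline_window[0]), pd.Timestamp(baseline_window[1]))
    if start > end:
        raise ValueError("baseline_window start after end")
    age = completed_age(beneficiaries["birth_date"], start)
    ok_age = (age >= age_range[0]) & (age <= age_range[1])
    died_in_baseline = beneficiaries["death_date"].notna() & (
        (beneficiaries["death_date"] >= start) & (beneficiaries["death_date"] <= end)
    )
    ok_coverage = (beneficiaries["coverage_start"] <= start) & (
        beneficiaries["coverage_end"] >= end
    )

    reason = np.where(
        ~ok_age,
        "age",
        np.where(
            died_in_baseline,
            "death_during_baseline",
            np.where(~ok_coverage, "coverage", ""),
        ),
    )
    included = reason == ""
    excl_reasons, excl_counts = np.unique(reason[~included], return_counts=True)
    exclusions = dict(zip(excl_reasons.tolist(), excl_counts.tolist()))
    if not included.any():
        logger.warning("study cohort is empty after eligibility screening")
    logger.info(
        "cohort screening: %d included, exclusions %s", int(included.sum()), exclusions
    )

    members = pd.DataFrame(
        {
            "person_id": beneficiaries.loc[included, "person_id"].to_numpy(),
            "sex": beneficiaries.loc[included, "sex"].to_numpy(),
            "age": age[included].to_numpy(),
        }
    )
    members["age_band"] = age_band_index(members["age"])
    members = members.sort_values("person_id", kind="mergesort").reset_index(drop=True)
    return StudyCohort(
        baseline_window=(start, end),
        followup_window=(pd.Timestamp(followup_window[0]), pd.Timestamp(followup_window[1])),
        members=members,
        exclusions=exclusions,
    )
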