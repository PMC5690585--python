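"""Outcome derivation and time-to-event dataset assembly.

Three outcomes are derived from the follow-up window (default 2006-01-01 to
2013-12-31):

* ``death`` — the disenrollment date due to death;
* ``unplanned_hospitalization`` — first inpatient admission that followed an
  emergency-department visit (``ed_flag``); planned admissions are ignored;
* ``icu_admission`` — first inpatient admission with ICU services
  (``icu_flag``).

Follow-up time is measured in days from the follow-up start, counting the
start date itself as day 1, so an event on the first follow-up day
contributes time 1 and administrative censoring at the end of a 1/5/8-year
horizon contributes 365/1826/2922 days (calendar-exact, leap days included).
For the non-fatal outcomes, death censors follow-up ("censored at death if
it occurred first"); a same-day admission and death counts as an event.
Disenrollment for reasons other than death is right-censoring at
``coverage_end``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .claims_io import StudyCohort

logger = logging.getLogger(__name__)

OUTCOMES = ("death", "unplanned_hospitalization", "icu_admission")
DEFAULT_HORIZONS = (1, 5, 8)


def horizon_days(followup_start, horizon_years: int) -> int:
    """Calendar-exact number of days in a horizon starting at ``followup_start``."""
    start = pd.Timestamp(followup_start)
    return int((start + pd.DateOffset(years=horizon_years) - start).days)


def derive_death(beneficiaries: pd.DataFrame, followup_window) -> pd.DataFrame:
    """First (only) death event per person: ``person_id, event_date`` (NaT if none)."""
    start, end = pd.Timestamp(followup_window[0]), pd.Timestamp(followup_window[1])
    d = beneficiaries["death_date"]
    in_window = d.notna() & (d >= start) & (d <= end)
    return pd.DataFrame(
        {
            "person_id": beneficiaries["person_id"].to_numpy(),
            "event_date": d.where(in_window, pd.NaT).to_numpy(),
        }
    )


def _first_flagged_admission(
    claims: pd.DataFrame, flag: str, followup_window
) -> pd.DataFrame:
    start, end = pd.Timestamp(followup_window[0]), pd.Timestamp(followup_window[1])
    inp = claims[
        (claims["setting"] == "inpatient")
        & claims[flag]
        & (claims["admission_date"] >= start)
        & (claims["admission_date"] <= end)
    ]
    first = inp.groupby("person_id")["admission_date"].min()
    return first.rename("event_date").reset_index()


def derive_unplanned_hospitalization(claims: pd.DataFrame, followup_window) -> pd.DataFrame:
    """First ED-preceded inpatient admission in the follow-up window."""
    return _first_flagged_admission(claims, "ed_flag", followup_window)


def derive_icu(claims: pd.DataFrame, followup_window) -> pd.DataFrame:
    """First inpatient admission with ICU services in the follow-up window."""
    return _first_flagged_admission(claims, "icu_flag", followup_window)


def derive_outcome_events(
    beneficiaries: pd.DataFrame, claims: pd.DataFrame, followup_window
) -> dict[str, pd.DataFrame]:
    """All three outcome event tables keyed by outcome name."""
    return {
        "death": derive_death(beneficiaries, followup_window),
        "unplanned_hospitalization": derive_unplanned_hospitalization(
            claims, followup_window
        ),
        "icu_admission": derive_icu(claims, followup_window),
    }


def build_survival_dataset(
    cohort: StudyCohort,
    scores: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    events: pd.DataFrame,
    outcome: str,
    horizon_years: int,
) -> pd.DataFrame:
    """Per-person ``(time, event)`` records for one outcome at one horizon.

    ``time`` is days of follow-up (see module docstring); ``event`` is 1 when
    the outcome attains the minimum of event time, death time (non-fatal
    outcomes), coverage end and the horizon. A ``censor_reason`` column
    (``event`` / ``death`` / ``coverage_end`` / ``horizon``) records which
    bound was attained, with ties resolved in that order.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    members = cohort.members
    scores = scores.set_index("person_id")
    missing = ~members["person_id"].isin(scores.index)
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} cohort member(s) lack frailty scores; "
            "score the cohort before building survival datasets"
        )
    start = cohort.followup_window[0]
    h_days = horizon_days(start, horizon_years)

    bene = beneficiaries.set_index("person_id").reindex(members["person_id"])
    death_days = (bene["death_date"] - start).dt.days + 1
    coverage_days = (bene["coverage_end"] - start).dt.days + 1

    ev = events.set_index("person_id")["event_date"].reindex(members["person_id"])
    event_days = (ev - start).dt.days + 1

    big = 10**9  # sentinel beyond any horizon; safe under float round-trip
    cand = np.full((len(members), 4), big, dtype=np.int64)
    cand[:, 0] = event_days.fillna(big).to_numpy()
    if outcome != "death":
        cand[:, 1] = death_days.fillna(big).to_numpy()
    cand[:, 2] = np.minimum(coverage_days.fillna(big).to_numpy(), big)
    cand[:, 3] = h_days
    time = cand.min(axis=1)
    reason_idx = cand.argmin(axis=1)  # ties -> lowest index: event wins over death
    reasons = np.array(["event", "death", "coverage_end", "horizon"])
    out = pd.DataFrame(
        {
            "person_id": members["person_id"].to_numpy(),
            "time": time,
            "event": (reason_idx == 0).astype(int),
            "censor_reason": reasons[reason_idx],
            "age_at_baseline": members["age"].to_numpy(),
            "sex": members["sex"].to_numpy(),
            "frailty_category": scores.loc[members["person_id"], "category"].to_numpy(),
            "mfi": scores.loc[members["person_id"], "mfi"].to_numpy(),
        }
    )
    if (out["time"] <= 0).any():
        raise ValueError("non-positive follow-up time; check dates against the window")
    return out


def build_all_survival_datasets(
    cohort: StudyCohort,
    scores: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    claims: pd.DataFrame,
    horizons=DEFAULT_HORIZONS,
    outcomes=OUTCOMES,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Survival datasets for every requested outcome x horizon pair."""
    events = derive_outcome_events(beneficiaries, claims, cohort.followup_window)
    return {
        (outcome, h): build_survival_dataset(
            cohort, scores, beneficiaries, events[outcome], outcome, h
        )
        for outcome in outcomes
        for h in horizons
    }
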