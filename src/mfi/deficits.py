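"""Deficit identification from baseline claims.

A *deficit candidate* is a 3-character ICD-9-CM root (codes sharing the same
first three characters after the decimal point is stripped). A candidate is
*present* for a person when the baseline year contains at least 3 outpatient
claims or at least 1 inpatient claim carrying that root. Candidates enter the
deficit catalog when they jointly satisfy:

(i)   overall presence prevalence strictly above 2%;
(ii)  a positive ordinary-least-squares slope of prevalence on the five age
      bands (65-69, 70-74, 75-79, 80-84, >=85) with R^2 strictly above 0.30;
(iii) presence prevalence in the youngest band strictly below 100%
      (codes saturated by age 65 carry no frailty signal).

The regression abscissa is the band index 0..4; the open-ended >=85 band has
no midpoint, and slope sign and R^2 are invariant to any affine recoding of
an equally spaced abscissa, so the choice only affects the slope's scale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_io import StudyCohort, SchemaError, claim_dates

logger = logging.getLogger(__name__)

DEFAULT_MIN_PREVALENCE = 0.02
DEFAULT_MIN_R2 = 0.30
MIN_OUTPATIENT_CLAIMS = 3
MIN_INPATIENT_CLAIMS = 1

_NUMERIC_ROOT = re.compile(r"^\d{3}$")

DIAGNOSTIC_COLUMNS = [
    "code_root",
    "overall_prevalence",
    "prev_band_0",
    "prev_band_1",
    "prev_band_2",
    "prev_band_3",
    "prev_band_4",
    "slope",
    "r_squared",
    "passed_prevalence",
    "passed_trend",
    "passed_not_saturated",
    "selected",
    "note",
]


def truncate_code(icd9_code: str) -> str:
    """Normalize an ICD-9-CM code and return its 3-character root.

    The decimal point is stripped first, so ``"428.0"`` and ``"4280"`` share
    the root ``"428"``; V/E codes keep their letter (``"V70.0"`` -> ``"V70"``).
    """
    code = str(icd9_code).strip().upper().replace(".", "")
    if len(code) < 3:
        raise SchemaError(f"ICD-9 code too short to truncate: {icd9_code!r}")
    return code[:3]


def flag_presence(person_claims: pd.DataFrame, code_root: str) -> int:
    """Presence indicator for one person and one code root.

    ``person_claims`` must already be restricted to the baseline window.
    Each claim line counts once per root even if it lists the root twice.
    """
    n_out = n_in = 0
    for _, row in person_claims.iterrows():
        roots = {truncate_code(c) for c in row["diagnosis_codes"]}
        if code_root in roots:
            if row["setting"] == "outpatient":
                n_out += 1
            else:
                n_in += 1
    return int(n_out >= MIN_OUTPATIENT_CLAIMS or n_in >= MIN_INPATIENT_CLAIMS)


def build_presence_matrix(
    cohort: StudyCohort, claims: pd.DataFrame, baseline_window=None
) -> pd.DataFrame:
    """Person x code-root binary presence matrix over the baseline window.

    One row per cohort member (members with no qualifying claims get an
    all-zero row), one column per distinct truncated root observed among the
    cohort's baseline claims, columns in lexicographic order. Claims from
    non-members are skipped with a logged count.
    """
    window = baseline_window or cohort.baseline_window
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    member_ids = cohort.person_ids

    in_cohort = claims["person_id"].isin(member_ids)
    n_skipped = int((~in_cohort).sum())
    if n_skipped:
        logger.info("build_presence_matrix: skipped %d claims from non-members", n_skipped)
    dates = claim_dates(claims)
    cl = claims[in_cohort & (dates >= start) & (dates <= end)]

    if len(cl):
        long = pd.DataFrame(
            {
                "claim_id": cl.index.repeat(cl["diagnosis_codes"].map(len)),
                "person_id": cl["person_id"].repeat(cl["diagnosis_codes"].map(len)),
                "setting": cl["setting"].repeat(cl["diagnosis_codes"].map(len)),
                "code": np.concatenate(cl["diagnosis_codes"].to_numpy()),
            }
        )
        long["root"] = [truncate_code(c) for c in long["code"]]
        # each claim line counts once per root
        long = long.drop_duplicates(["claim_id", "root"])
        counts = (
            long.groupby(["person_id", "root", "setting"], sort=False)
            .size()
            .unstack("setting", fill_value=0)
        )
        for col in ("outpatient", "inpatient"):
            if col not in counts.columns:
                counts[col] = 0
        present = (counts["outpatient"] >= MIN_OUTPATIENT_CLAIMS) | (
            counts["inpatient"] >= MIN_INPATIENT_CLAIMS
        )
        matrix = present.astype(np.int8).unstack("root", fill_value=0)
        # keep all observed roots as candidate columns, even if nobody qualifies
        all_roots = sorted(long["root"].unique())
    else:
        matrix = pd.DataFrame(index=pd.Index([], name="person_id"))
        all_roots = []

    matrix = matrix.reindex(index=member_ids, columns=sorted(all_roots), fill_value=0)
    matrix = matrix.astype(np.int8)
    matrix.index.name = "person_id"
    return matrix


def age_trend(band_prevalences, band_indices=None) -> tuple[float, float]:
    """OLS slope and R^2 of prevalence on age-band index.

    Returns ``(slope, r_squared)``; ``r_squared`` is ``nan`` (undefined)
    when the prevalences are constant (total sum of squares is zero).
    """
    y = np.asarray(band_prevalences, dtype=float)
    x = (
        np.arange(len(y), dtype=float)
        if band_indices is None
        else np.asarray(band_indices, dtype=float)
    )
    if band_indices is None and len(y) != 5:
        raise ValueError(f"expected 5 band prevalences, got {len(y)}")
    if len(x) != len(y) or len(y) < 2:
        raise ValueError("band_prevalences and band_indices must align (length >= 2)")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    tss = float(yc @ yc)
    slope = float(xc @ yc) / sxx
    if tss == 0.0:
        return slope, float("nan")
    rss = tss - slope * float(xc @ yc)
    return slope, 1.0 - rss / tss


@dataclass
class DeficitCatalog:
    """Selected deficit roots plus full selection diagnostics for every candidate."""

    selected_roots: list[str]
    diagnostics: pd.DataFrame
    min_prevalence: float = DEFAULT_MIN_PREVALENCE
    min_r2: float = DEFAULT_MIN_R2

    @property
    def total_items(self) -> int:
        return len(self.selected_roots)

    def to_csv(self, path) -> None:
        self.diagnostics.to_csv(path, index=False, float_format="%.10g")


def select_deficits(
    matrix: pd.DataFrame,
    cohort: StudyCohort,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_r2: float = DEFAULT_MIN_R2,
    numeric_only: bool = False,
    min_bands: int = 3,
) -> DeficitCatalog:
    """Apply the three selection criteria to every candidate root.

    All thresholds are strict inequalities ("more than 2%", "more than
    0.30"). The age trend is fitted on the bands actually populated in the
    cohort; with fewer than ``min_bands`` populated bands a candidate fails
    the trend criterion with an ``insufficient_bands`` note. The saturation
    criterion (iii) tests the youngest populated band against 100%.
    """
    members = cohort.members.set_index("person_id")
    if not matrix.index.equals(pd.Index(members.index)):
        members = members.reindex(matrix.index)
        if members["age_band"].isna().any():
            raise ValueError("presence matrix rows must match cohort members")
    bands = members["age_band"].to_numpy()
    n = len(matrix)
    band_sizes = np.bincount(bands, minlength=5)
    populated = np.flatnonzero(band_sizes > 0)

    rows = []
    roots = list(matrix.columns)
    if numeric_only:
        roots = [r for r in roots if _NUMERIC_ROOT.match(r)]
    for root in roots:
        col = matrix[root].to_numpy()
        overall = float(col.mean()) if n else float("nan")
        band_prev = np.full(5, np.nan)
        for b in populated:
            band_prev[b] = float(col[bands == b].mean())
        note = ""
        if len(populated) >= min_bands:
            slope, r2 = age_trend(band_prev[populated], band_indices=populated)
            passed_trend = bool(slope > 0 and not np.isnan(r2) and r2 > min_r2)
            if np.isnan(r2):
                note = "constant_prevalence"
        else:
            slope, r2 = float("nan"), float("nan")
            passed_trend = False
            note = "insufficient_bands"
        passed_prevalence = bool(overall > min_prevalence)
        youngest = populated[0] if len(populated) else None
        passed_not_saturated = bool(
            youngest is None or band_prev[youngest] < 1.0
        )
        rows.append(
            {
                "code_root": root,
                "overall_prevalence": overall,
                **{f"prev_band_{b}": band_prev[b] for b in range(5)},
                "slope": slope,
                "r_squared": r2,
                "passed_prevalence": passed_prevalence,
                "passed_trend": passed_trend,
                "passed_not_saturated": passed_not_saturated,
                "selected": passed_prevalence and passed_trend and passed_not_saturated,
                "note": note,
            }
        )
    diagnostics = pd.DataFrame(rows, columns=DIAGNOSTIC_COLUMNS)
    selected = sorted(diagnostics.loc[diagnostics["selected"], "code_root"])
    logger.info(
        "deficit selection: %d candidates, %d selected", len(diagnostics), len(selected)
    )
    return DeficitCatalog(
        selected_roots=selected,
        diagnostics=diagnostics,
        min_prevalence=min_prevalence,
        min_r2=min_r2,
    )
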