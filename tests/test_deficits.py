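"""Deficit identification: truncation, presence rule, age trend, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mfi
from mfi.claims_io import SchemaError

from conftest import make_beneficiaries, make_claims, outpatient, inpatient, small_sim_config
from _oracles import naive_select


class TestTruncateCode:
    @pytest.mark.parametrize(
        "code,root",
        [
            ("332.0", "332"),
            ("4280", "428"),
            ("428.0", "428"),
            ("428", "428"),
            ("V70.0", "V70"),
            ("v700", "V70"),
            ("E912", "E91"),
            (" 250.01 ", "250"),
        ],
    )
    def test_truncation(self, code, root):
        assert mfi.truncate_code(code) == root

    def test_dotted_and_dotless_share_a_root(self):
        assert mfi.truncate_code("428.0") == mfi.truncate_code("4280")

    @pytest.mark.parametrize("bad", ["", "42", "4.2", " 1 "])
    def test_short_codes_rejected(self, bad):
        with pytest.raises(SchemaError):
            mfi.truncate_code(bad)

    @given(st.from_regex(r"[0-9]{3}[0-9]{0,2}", fullmatch=True))
    @settings(max_examples=50, deadline=None)
    def test_dot_insertion_never_changes_root(self, code):
        dotted = code[:3] + "." + code[3:] if len(code) > 3 else code
        assert mfi.truncate_code(code) == mfi.truncate_code(dotted)


class TestFlagPresence:
    def claims_for(self, rows):
        return make_claims(rows)

    def test_three_outpatient_claims_qualify(self):
        claims = self.claims_for(
            [outpatient("A", f"2005-0{m}-10", ["332.0"]) for m in (2, 5, 8)]
        )
        assert mfi.flag_presence(claims, "332") == 1

    def test_two_outpatient_claims_do_not_qualify(self):
        claims = self.claims_for(
            [outpatient("A", f"2005-0{m}-10", ["332"]) for m in (2, 5)]
        )
        assert mfi.flag_presence(claims, "332") == 0

    def test_single_inpatient_claim_qualifies(self):
        claims = self.claims_for(
            [inpatient("A", "2005-04-01", "2005-04-07", ["3320"])]
        )
        assert mfi.flag_presence(claims, "332") == 1

    def test_duplicate_root_on_one_line_counts_once(self):
        claims = self.claims_for(
            [outpatient("A", "2005-04-01", ["428.0", "4281", "428.9"])] * 2
        )
        assert mfi.flag_presence(claims, "428") == 0  # 2 claim lines, not 6


class TestPresenceMatrix:
    def cohort_of(self, ids_and_births):
        bene = make_beneficiaries(
            [
                (pid, "female", birth, "2000-01-01", "2013-12-31", None)
                for pid, birth in ids_and_births
            ]
        )
        return mfi.select_study_cohort(bene)

    def test_direct_rule_application(self):
        cohort = self.cohort_of([("A", "1935-06-01"), ("B", "1930-01-01")])
        claims = make_claims(
            [outpatient("A", f"2005-0{m}-10", ["428.0"]) for m in (1, 2, 3)]
        )
        matrix = mfi.build_presence_matrix(cohort, claims)
        assert matrix.shape == (2, 1)
        assert matrix.loc["A", "428"] == 1
        assert matrix.loc["B", "428"] == 0

    def test_no_claims_gives_zero_columns(self):
        cohort = self.cohort_of([("A", "1935-06-01")])
        matrix = mfi.build_presence_matrix(cohort, make_claims([]))
        assert matrix.shape == (1, 0)

    def test_multi_code_inpatient_line_sets_both_roots(self):
        cohort = self.cohort_of([("A", "1935-06-01")])
        claims = make_claims([inpatient("A", "2005-03-01", "2005-03-05", ["428", "332"])])
        matrix = mfi.build_presence_matrix(cohort, claims)
        assert matrix.loc["A", "428"] == 1
        assert matrix.loc["A", "332"] == 1

    def test_claims_outside_baseline_window_ignored(self):
        cohort = self.cohort_of([("A", "1935-06-01")])
        claims = make_claims(
            [outpatient("A", d, ["428"]) for d in
             ("2004-12-31", "2006-01-01", "2005-06-01", "2005-06-02", "2005-06-03")]
        )
        matrix = mfi.build_presence_matrix(cohort, claims)
        assert matrix.loc["A", "428"] == 1  # exactly the 3 baseline claims

    def test_non_member_claims_skipped(self):
        cohort = self.cohort_of([("A", "1935-06-01")])
        claims = make_claims(
            [outpatient("Z", f"2005-0{m}-10", ["428"]) for m in (1, 2, 3)]
        )
        matrix = mfi.build_presence_matrix(cohort, claims)
        assert matrix.shape == (1, 0) or matrix.loc["A"].sum() == 0


class TestAgeTrend:
    def test_exact_linearity(self):
        slope, r2 = mfi.age_trend([0.02, 0.04, 0.06, 0.08, 0.10])
        assert slope == pytest.approx(0.02)
        assert r2 == pytest.approx(1.0)

    def test_constant_prevalence_undefined_r2(self):
        slope, r2 = mfi.age_trend([0.1815] * 5)
        assert slope == 0
        assert np.isnan(r2)

    def test_negative_slope(self):
        slope, _ = mfi.age_trend([0.10, 0.08, 0.06, 0.04, 0.02])
        assert slope == pytest.approx(-0.02)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            mfi.age_trend([0.1, 0.2, 0.3])


def planted_cohort(n_per_band=60):
    """Deterministic cohort where code 428 rises, 250 is flat, 401 saturates."""
    rows, claims = [], []
    births = {0: "1938-06-01", 1: "1933-06-01", 2: "1928-06-01", 3: "1923-06-01", 4: "1918-06-01"}
    rising = [0.1, 0.2, 0.4, 0.6, 0.8]
    pid = 0
    for band in range(5):
        for i in range(n_per_band):
            person = f"P{pid:04d}"
            pid += 1
            rows.append((person, "female", births[band], "2000-01-01", "2013-12-31", None))
            if i < rising[band] * n_per_band:
                claims.append(inpatient(person, "2005-03-01", "2005-03-04", ["428.0"]))
            if i < 0.3 * n_per_band:  # flat decoy, well above 2%
                claims.append(inpatient(person, "2005-04-01", "2005-04-04", ["250"]))
            claims.append(inpatient(person, "2005-05-01", "2005-05-02", ["401"]))  # saturated
    cohort = mfi.select_study_cohort(make_beneficiaries(rows))
    return cohort, make_claims(claims)


class TestSelectDeficits:
    def test_planted_rising_code_selected_and_decoys_rejected(self):
        cohort, claims = planted_cohort()
        matrix = mfi.build_presence_matrix(cohort, claims)
        catalog = mfi.select_deficits(matrix, cohort)
        diag = catalog.diagnostics.set_index("code_root")
        assert catalog.selected_roots == ["428"]
        assert diag.loc["428", "selected"]
        # flat decoy fails the trend criterion despite 30% prevalence
        assert diag.loc["250", "passed_prevalence"]
        assert not diag.loc["250", "passed_trend"]
        # saturated decoy fails criterion (iii)
        assert not diag.loc["401", "passed_not_saturated"]

    def test_threshold_strictness_prevalence(self):
        # exactly 2% prevalence is NOT "more than 2%"
        cohort, claims = planted_cohort()
        matrix = mfi.build_presence_matrix(cohort, claims)
        catalog = mfi.select_deficits(matrix, cohort, min_prevalence=0.42)
        diag = catalog.diagnostics.set_index("code_root")
        assert diag.loc["428", "overall_prevalence"] == pytest.approx(0.42)
        assert not diag.loc["428", "passed_prevalence"]

    def test_monotone_in_prevalence_threshold(self):
        config = small_sim_config(n=400, seed=3)
        b, c, _ = mfi.generate_cohort(config, seed=3)
        cohort = mfi.select_study_cohort(b)
        matrix = mfi.build_presence_matrix(cohort, c)
        prev = None
        for thr in (0.0, 0.02, 0.05, 0.10, 0.5):
            selected = set(mfi.select_deficits(matrix, cohort, min_prevalence=thr).selected_roots)
            if prev is not None:
                assert selected <= prev
            prev = selected

    def test_numeric_only_switch_drops_v_codes(self):
        cohort, claims = planted_cohort()
        claims = pd.concat(
            [claims, make_claims([inpatient("P0000", "2005-06-01", "2005-06-02", ["V70"])])],
            ignore_index=True,
        )
        matrix = mfi.build_presence_matrix(cohort, claims)
        with_v = mfi.select_deficits(matrix, cohort)
        without_v = mfi.select_deficits(matrix, cohort, numeric_only=True)
        assert "V70" in set(with_v.diagnostics["code_root"])
        assert "V70" not in set(without_v.diagnostics["code_root"])

    def test_insufficient_bands_fails_trend(self):
        # cohort entirely within two age bands cannot support the regression
        rows = [(f"P{i}", "male", "1938-06-01" if i % 2 else "1933-06-01",
                 "2000-01-01", "2013-12-31", None) for i in range(40)]
        cohort = mfi.select_study_cohort(make_beneficiaries(rows))
        claims = make_claims(
            [inpatient(f"P{i}", "2005-03-01", "2005-03-04", ["428"]) for i in range(30)]
        )
        matrix = mfi.build_presence_matrix(cohort, claims)
        catalog = mfi.select_deficits(matrix, cohort)
        diag = catalog.diagnostics.set_index("code_root")
        assert not diag.loc["428", "passed_trend"]
        assert diag.loc["428", "note"] == "insufficient_bands"


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_cohorts(self):
        rng = np.random.default_rng(202)
        for rep in range(5):
            config = small_sim_config(n=300, rng=rng, n_codes=12)
            b, c, _ = mfi.generate_cohort(config, seed=int(rng.integers(2**31)))
            cohort = mfi.select_study_cohort(b)
            matrix = mfi.build_presence_matrix(cohort, c)
            catalog = mfi.select_deficits(matrix, cohort)
            oracle = naive_select(c, cohort.members, cohort.baseline_window)
            diag = catalog.diagnostics.set_index("code_root")
            assert set(diag.index) == set(oracle)
            for root, (sel, overall, slope, r2) in oracle.items():
                assert diag.loc[root, "selected"] == sel, root
                assert diag.loc[root, "overall_prevalence"] == pytest.approx(overall)
                if not np.isnan(slope):
                    assert diag.loc[root, "slope"] == pytest.approx(slope)
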