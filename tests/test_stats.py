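"""KM, log-rank, Cox and discrimination against hand-computed / brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import mfi
from mfi.stats import cox_score_test

from _oracles import (
    breslow_log_partial_likelihood,
    brute_force_cox_beta,
    mann_whitney_c,
    product_limit,
    two_group_logrank,
)


def records(times, events, group=None, **extra):
    df = pd.DataFrame({"time": times, "event": events})
    df["frailty_category"] = group if group is not None else "all"
    for k, v in extra.items():
        df[k] = v
    return df


def simulate_exponential(rng, n, beta, censor_rate=0.3, binary=True):
    """Single-covariate exponential survival with uniform censoring."""
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(1.0 / (0.1 * censor_rate), size=n)
    df = pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
    )
    return df


class TestKaplanMeier:
    def test_hand_product_limit_with_censoring(self):
        # times (5,event), (8,censored), (12,event): S(5) = 2/3; at t=12 the
        # censored subject has left the risk set, so S(12) = 2/3 * (1-1/1) = 0
        rec = records([5, 8, 12], [1, 0, 1])
        km = mfi.km_estimate(rec)
        surv = km.set_index("time")["survival"]
        assert surv.loc[5] == pytest.approx(2 / 3)
        assert surv.loc[12] == pytest.approx(0.0)
        oracle = dict(product_limit([5, 8, 12], [1, 0, 1]))
        assert surv.loc[12] == pytest.approx(oracle[12.0])

    def test_all_censored_curve_stays_flat(self):
        rec = records([3, 6, 9], [0, 0, 0])
        km = mfi.km_estimate(rec)
        assert (km["survival"] == 1.0).all()

    def test_distinct_event_times_step_by_quarters(self):
        rec = records([1, 2, 3, 4], [1, 1, 1, 1])
        km = mfi.km_estimate(rec)
        steps = km[km["n_events"] > 0].sort_values("time")["survival"].tolist()
        assert steps == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(4)
        df = simulate_exponential(rng, 200, 0.0)
        km = mfi.km_estimate(records(df["time"], df["event"]))
        oracle = dict(product_limit(df["time"].to_numpy(), df["event"].to_numpy()))
        stepped = km[km["n_events"] > 0]
        for t, s in zip(stepped["time"], stepped["survival"]):
            assert s == pytest.approx(oracle[float(t)])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1.0, size=100)
        km = mfi.km_estimate(records(t, np.ones(100, dtype=int)))
        for _, row in km[km["n_events"] > 0].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        rec = records([5, 8, 12] * 2, [1, 0, 1] * 2, group=["a"] * 3 + ["b"] * 3)
        chi2, df, p = mfi.logrank_test(rec)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_four_groups_have_three_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        rec = records(
            rng.exponential(1, 80), rng.integers(0, 2, 80),
            group=np.repeat(["a", "b", "c", "d"], 20),
        )
        _, df, _ = mfi.logrank_test(rec)
        assert df == 3

    def test_two_group_fixture_matches_hand_table(self):
        times = [3, 5, 7, 9, 11, 4, 6, 8, 10, 12]
        events = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        group = [0] * 5 + [1] * 5
        rec = records(times, events, group=[str(g) for g in group])
        chi2, _, _ = mfi.logrank_test(rec)
        assert chi2 == pytest.approx(two_group_logrank(times, events, group))

    def test_invariant_under_group_relabeling(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        g = np.repeat(["a", "b", "c"], 20)
        chi1, _, _ = mfi.logrank_test(records(t, e, group=g))
        relabel = {"a": "z", "b": "y", "c": "x"}
        chi2_, _, _ = mfi.logrank_test(records(t, e, group=[relabel[x] for x in g]))
        assert chi1 == pytest.approx(chi2_)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            mfi.logrank_test(records([1, 2], [1, 1]))


class TestCoxFit:
    def test_coefficient_matches_brute_force_partial_likelihood(self):
        rng = np.random.default_rng(10)
        df = simulate_exponential(rng, 60, beta=0.8)
        df["time"] = np.round(df["time"], 6)  # keep times distinct
        assert df["time"].nunique() == len(df)
        fit = mfi.cox_fit(df, covariates=("x",))
        oracle = brute_force_cox_beta(
            df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy()
        )
        assert fit.summary.loc[0, "coef"] == pytest.approx(oracle, abs=1e-6)

    def test_matches_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        df = simulate_exponential(rng, 300, beta=0.5, binary=False)
        fit = mfi.cox_fit(df, covariates=("x",))
        cph = CoxPHFitter().fit(df[["time", "event", "x"]], "time", "event")
        assert fit.summary.loc[0, "coef"] == pytest.approx(
            cph.params_["x"], abs=1e-4
        )
        assert fit.summary.loc[0, "se"] == pytest.approx(
            cph.standard_errors_["x"], rel=1e-3
        )

    def test_hazard_ratio_and_ci_consistency(self):
        rng = np.random.default_rng(12)
        df = simulate_exponential(rng, 200, beta=0.7)
        fit = mfi.cox_fit(df, covariates=("x",))
        row = fit.summary.iloc[0]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - 1.959964 * row["se"]))
        assert row["ci_low"] < row["hr"] < row["ci_high"]

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(13)
        df = simulate_exponential(rng, 2000, beta=0.6)
        df["x"] = rng.permutation(df["x"].to_numpy())  # break the association
        fit = mfi.cox_fit(df, covariates=("x",))
        row = fit.summary.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(14)
        df = simulate_exponential(rng, 120, beta=0.6)
        assert df["time"].nunique() == len(df)
        chi2_score, _, _ = cox_score_test(df, "x")
        chi2_lr, _, _ = mfi.logrank_test(
            df.assign(frailty_category=df["x"].astype(int).astype(str))
        )
        assert chi2_score == pytest.approx(chi2_lr, rel=1e-10)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            mfi.cox_fit(df, covariates=("x",))

    def test_complete_separation_flagged(self):
        # every event in one arm, sorted so the likelihood is monotone in beta
        df = pd.DataFrame(
            {
                "time": np.concatenate([np.arange(1, 21), np.arange(21, 41)]).astype(float),
                "event": np.concatenate([np.ones(20, int), np.zeros(20, int)]),
                "x": np.concatenate([np.ones(20), np.zeros(20)]),
            }
        )
        fit = mfi.cox_fit(df, covariates=("x",))
        assert not fit.converged

    def test_partial_likelihood_value_matches_written_out_formula(self):
        rng = np.random.default_rng(15)
        df = simulate_exponential(rng, 50, beta=0.4)
        fit = mfi.cox_fit(df, covariates=("x",))
        beta = fit.summary.loc[0, "coef"]
        assert fit.log_likelihood == pytest.approx(
            breslow_log_partial_likelihood(
                beta, df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy()
            )
        )


class TestCoverage:
    def test_ci_covers_true_hr3_in_about_95pct(self):
        # 60 replicates at n=1,200 as a fast coverage check (the acceptance
        # suite runs the full 200 x 5,000 version)
        rng = np.random.default_rng(16)
        beta = np.log(3.0)
        hits = 0
        reps = 60
        for _ in range(reps):
            df = simulate_exponential(rng, 1200, beta=beta)
            row = mfi.cox_fit(df, covariates=("x",)).summary.iloc[0]
            hits += row["ci_low"] <= 3.0 <= row["ci_high"]
        assert hits / reps > 0.85


class TestDiscrimination:
    def build(self, y, levels):
        n = len(y)
        return pd.DataFrame(
            {
                "time": np.where(np.asarray(y) == 1, 100, 365),
                "event": y,
                "censor_reason": np.where(np.asarray(y) == 1, "event", "horizon"),
                "frailty_category": levels,
            }
        )

    def test_permuted_predictor_near_half(self):
        rng = np.random.default_rng(20)
        y = rng.integers(0, 2, 4000)
        levels = rng.choice(["fit", "mild", "moderate", "severe"], size=4000)
        res = mfi.discrimination(self.build(y, levels), horizon_years=1)
        assert abs(res.c_statistic - 0.5) < 0.03

    def test_perfect_separation_gives_c_one(self):
        y = np.array([0] * 50 + [1] * 50)
        levels = np.array(["fit"] * 50 + ["severe"] * 50)
        res = mfi.discrimination(self.build(y, levels), horizon_years=1)
        assert res.c_statistic == 1.0
        assert res.pseudo_r2_nagelkerke == pytest.approx(1.0)

    def test_c_equals_mann_whitney_concordance(self):
        rng = np.random.default_rng(21)
        levels = rng.choice(["fit", "mild", "moderate", "severe"], size=200)
        risk = {"fit": 0.1, "mild": 0.2, "moderate": 0.4, "severe": 0.6}
        y = (rng.random(200) < np.vectorize(risk.get)(levels)).astype(int)
        res = mfi.discrimination(self.build(y, levels), horizon_years=1)
        rates = pd.Series(y).groupby(pd.Series(levels)).mean()
        scores = rates.loc[levels].to_numpy()
        oracle = mann_whitney_c(scores[y == 1], scores[y == 0])
        assert res.c_statistic == pytest.approx(oracle)

    def test_matches_statsmodels_logit_pseudo_r2(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        levels = rng.choice(["fit", "mild", "severe"], size=500)
        risk = {"fit": 0.1, "mild": 0.3, "severe": 0.6}
        y = (rng.random(500) < np.vectorize(risk.get)(levels)).astype(int)
        res = mfi.discrimination(self.build(y, levels), horizon_years=1)
        X = pd.get_dummies(pd.Series(levels), drop_first=True, dtype=float)
        logit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        n = len(y)
        cs = 1 - np.exp(2 * (logit.llnull - logit.llf) / n)
        assert res.pseudo_r2_cox_snell == pytest.approx(cs, rel=1e-6)
        assert res.pseudo_r2_nagelkerke >= res.pseudo_r2_cox_snell

    def test_non_death_pre_horizon_censoring_excluded(self):
        df = pd.DataFrame(
            {
                "time": [100, 200, 365, 365],
                "event": [1, 0, 0, 0],
                "censor_reason": ["event", "coverage_end", "horizon", "horizon"],
                "frailty_category": ["severe", "fit", "fit", "mild"],
            }
        )
        res = mfi.discrimination(df, horizon_years=1)
        assert res.n_excluded == 1
        assert res.n_used == 3

    def test_all_identical_outcomes_rejected(self):
        df = self.build(np.ones(10, dtype=int), ["fit"] * 10)
        with pytest.raises(ValueError):
            mfi.discrimination(df, horizon_years=1)
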