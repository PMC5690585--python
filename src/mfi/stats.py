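"""Survival and discrimination statistics for the frailty categories.

Kaplan-Meier product-limit curves with the k-group log-rank test, bivariate
(category only) and adjusted (category + age + sex) Cox proportional-hazards
fits with Wald confidence intervals, the Cox score test at beta = 0, and
horizon-wise discrimination (C-statistic plus Cox-Snell and Nagelkerke
pseudo-R^2) of a categorical risk score.

Cox models use the Breslow tie approximation by default (Efron available via
``tie_method``); hazard ratios are ``exp(coef)`` with 95% CIs
``exp(coef +/- 1.959964 * SE)`` on the log-hazard scale. Age enters adjusted
models as a continuous covariate in years; sex as an indicator (male = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

Z_95 = 1.959964


class ConvergenceError(RuntimeError):
    """A model fit failed to converge (e.g. monotone partial likelihood)."""


def km_estimate(records: pd.DataFrame, group_col: str = "frailty_category") -> pd.DataFrame:
    """Product-limit survival curve per group.

    Returns a tidy step-function table with columns ``group, time,
    n_at_risk, n_events, n_censored, survival``; censored times do not step
    the curve. Empty groups are skipped with a warning.
    """
    frames = []
    groups = records[group_col].unique()
    for g in sorted(pd.Series(groups).dropna().astype(str)):
        sub = records[records[group_col].astype(str) == g]
        if len(sub) == 0:
            logger.warning("km_estimate: group %r is empty", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        tab = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": tab.index.to_numpy(),
                    "n_at_risk": tab["at_risk"].to_numpy().astype(int),
                    "n_events": tab["observed"].to_numpy().astype(int),
                    "n_censored": tab["censored"].to_numpy().astype(int),
                    "survival": surv.reindex(tab.index).to_numpy(),
                }
            )
        )
    if not frames:
        logger.warning("km_estimate: no non-empty groups")
        return pd.DataFrame(
            columns=["group", "time", "n_at_risk", "n_events", "n_censored", "survival"]
        )
    return pd.concat(frames, ignore_index=True)


def logrank_test(records: pd.DataFrame, group_col: str = "frailty_category"):
    """k-group log-rank test; returns ``(chi_square, df, p_value)``."""
    groups = records[group_col].astype(str)
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    chi2 = float(res.test_statistic)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def cox_score_test(records: pd.DataFrame, covariate: str) -> tuple[float, float, float]:
    """Cox partial-likelihood score test at beta = 0 for one covariate.

    Uses the Breslow form: at each event time with ``d`` events, the score
    accrues the observed covariate sum minus ``d`` times the risk-set mean,
    and the information accrues ``d`` times the risk-set variance. With no
    tied event times this equals the classical log-rank statistic for a
    binary covariate. Returns ``(chi_square, score, information)``.
    """
    x = records[covariate].to_numpy(dtype=float)
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    x, t, e = x[order], t[order], e[order]
    u = v = 0.0
    csum = csum2 = 0.0
    nrisk = 0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        csum += x[i:j].sum()
        csum2 += (x[i:j] ** 2).sum()
        nrisk += j - i
        ev = e[i:j] == 1
        d = int(ev.sum())
        if d:
            mean = csum / nrisk
            var = csum2 / nrisk - mean**2
            u += x[i:j][ev].sum() - d * mean
            v += d * var
        i = j
    if v <= 0:
        raise ValueError("score test undefined: zero information")
    return u * u / v, u, v


@dataclass
class CoxFit:
    """Summary of one Cox proportional-hazards fit.

    ``summary`` has one row per covariate: ``term, coef, se, hr, ci_low,
    ci_high``; the CI is Wald at 95% on the log-hazard scale.
    """

    summary: pd.DataFrame
    log_likelihood: float
    tie_method: str
    n: int
    n_events: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def _design_matrix(records: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in covariates:
        if cov == "frailty_category":
            cats = records["frailty_category"]
            if not isinstance(cats.dtype, pd.CategoricalDtype):
                cats = pd.Categorical(cats)
            else:
                cats = cats.array
            levels = list(cats.categories)
            for lev in levels[1:]:  # first level is the reference
                ind = (np.asarray(cats) == lev).astype(float)
                if ind.sum() == 0:
                    logger.warning("cox_fit: category level %r absent, dropped", lev)
                    continue
                cols.append(ind)
                names.append(f"category[{lev}]")
        elif cov == "sex":
            cols.append((records["sex"].to_numpy() == "male").astype(float))
            names.append("sex[male]")
        else:
            cols.append(records[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def cox_fit(
    records: pd.DataFrame,
    covariates=("frailty_category",),
    tie_method: str = "breslow",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by partial-likelihood maximization.

    ``covariates`` may mix ``"frailty_category"`` (expanded to indicator
    columns with the lowest category as reference), ``"sex"`` (male = 1) and
    numeric column names such as ``"age_at_baseline"``. Monotone-likelihood
    (complete separation) fits are flagged ``converged=False``; a dataset
    with no events raises ``ValueError``.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model with no events")
    X, names = _design_matrix(records, covariates)
    model = PHReg(
        records["time"].to_numpy(dtype=float),
        X,
        status=records["event"].to_numpy(dtype=int),
        ties=tie_method,
    )
    notes = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit()
        for w in caught:
            notes.append(str(w.message))
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
    except np.linalg.LinAlgError as exc:
        # singular information: degenerate design (e.g. an event-free level)
        notes.append(f"singular information matrix: {exc}")
        params = np.full(len(names), np.nan)
        bse = np.full(len(names), np.nan)
    converged = bool(
        np.all(np.isfinite(params))
        and np.all(np.isfinite(bse))
        and np.all(np.abs(params) < 30)
    )
    if not converged:
        notes.append("non-convergence or monotone likelihood suspected")
        logger.warning("cox_fit did not converge cleanly: %s", notes)
    summary = pd.DataFrame(
        {
            "term": names,
            "coef": params,
            "se": bse,
            "hr": np.exp(params),
            "ci_low": np.exp(params - Z_95 * bse),
            "ci_high": np.exp(params + Z_95 * bse),
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(model.loglike(params)),
        tie_method=tie_method,
        n=len(records),
        n_events=n_events,
        converged=converged,
        notes=notes,
    )


@dataclass
class DiscriminationResult:
    """C-statistic and pseudo-R^2 of a categorical predictor at one horizon."""

    c_statistic: float
    pseudo_r2_cox_snell: float
    pseudo_r2_nagelkerke: float
    outcome: str = ""
    horizon_years: int = 0
    n_used: int = 0
    n_events: int = 0
    n_excluded: int = 0


def _binary_loglik(y: np.ndarray, p: np.ndarray) -> float:
    # 0*log(0) := 0 keeps saturated fits finite under separation
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y == 1, np.log(p), np.log1p(-p))
    return float(np.where(((y == 1) & (p == 1)) | ((y == 0) & (p == 0)), 0.0, terms).sum())


def discrimination(
    records: pd.DataFrame,
    horizon_years: int,
    predictor: str = "frailty_category",
    outcome: str = "",
    followup_start=pd.Timestamp("2006-01-01"),
) -> DiscriminationResult:
    """Horizon-wise discrimination of a categorical predictor.

    The binary outcome is "event by the horizon". Persons censored before
    the horizon for reasons other than death are excluded (their status at
    the horizon is unknown); death-censored persons are event-free controls,
    and for the death outcome survivors to the horizon are controls. The
    logistic model on a k-level categorical predictor is saturated, so the
    fitted probabilities are the per-level event rates; the C-statistic is
    the concordance of those fitted probabilities (equivalently a
    Mann-Whitney rank statistic over case/control pairs) and the pseudo-R^2
    values come from the binomial log-likelihoods.
    """
    h_days = int(
        (pd.Timestamp(followup_start) + pd.DateOffset(years=horizon_years)
         - pd.Timestamp(followup_start)).days
    )
    unknown = (
        (records["event"] == 0)
        & (records["time"] < h_days)
        & (records["censor_reason"] == "coverage_end")
    )
    n_excluded = int(unknown.sum())
    if n_excluded:
        logger.info(
            "discrimination: excluded %d record(s) censored before the horizon "
            "for non-death reasons",
            n_excluded,
        )
    use = records[~unknown]
    y = use["event"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("discrimination undefined: all outcomes identical")
    levels, codes = np.unique(use[predictor].astype(str).to_numpy(), return_inverse=True)
    rates = np.bincount(codes, weights=y) / np.bincount(codes)
    p_hat = rates[codes]

    # concordance of fitted probabilities = Mann-Whitney U / (n1 * n0)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    u_stat = sps.mannwhitneyu(p_hat[y == 1], p_hat[y == 0], alternative="two-sided").statistic
    c = float(u_stat) / (n1 * n0)

    n = len(y)
    ll1 = _binary_loglik(y, p_hat)
    p0 = y.mean()
    ll0 = _binary_loglik(y, np.full(n, p0))
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
    return DiscriminationResult(
        c_statistic=c,
        pseudo_r2_cox_snell=float(cox_snell),
        pseudo_r2_nagelkerke=float(nagelkerke),
        outcome=outcome,
        horizon_years=horizon_years,
        n_used=n,
        n_events=n1,
        n_excluded=n_excluded,
    )
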