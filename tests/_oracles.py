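"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's own vectorized code paths:
presence is recounted with Python loops and dictionaries, the age-trend
regression is refit with the closed-form two-variable OLS formulas, the Cox
partial likelihood is written out and maximized one-dimensionally, and
concordance is computed as a Mann-Whitney rank statistic.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy.optimize import minimize_scalar


def naive_root(code: str) -> str:
    return code.strip().upper().replace(".", "")[:3]


def naive_presence(claims_df, member_ids, window) -> dict:
    """{(person, root): 1} recounted claim by claim with loops."""
    start, end = window
    out_counts: dict = defaultdict(set)
    in_counts: dict = defaultdict(set)
    members = set(member_ids)
    for idx, row in claims_df.iterrows():
        pid = row["person_id"]
        if pid not in members:
            continue
        date = row["service_date"] if row["setting"] == "outpatient" else row["admission_date"]
        if not (start <= date <= end):
            continue
        for root in {naive_root(c) for c in row["diagnosis_codes"]}:
            if row["setting"] == "outpatient":
                out_counts[(pid, root)].add(idx)
            else:
                in_counts[(pid, root)].add(idx)
    presence = {}
    for key in set(out_counts) | set(in_counts):
        presence[key] = int(len(out_counts.get(key, ())) >= 3 or len(in_counts.get(key, ())) >= 1)
    return presence


def naive_ols(xs, ys):
    """Closed-form simple OLS slope and R^2."""
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    sxx = sum((x - xbar) ** 2 for x in xs)
    syy = sum((y - ybar) ** 2 for y in ys)
    slope = sxy / sxx
    if syy == 0:
        return slope, float("nan")
    return slope, (sxy * sxy) / (sxx * syy)


def naive_select(claims_df, members_df, window, min_prevalence=0.02, min_r2=0.30):
    """Independent reimplementation of the three selection criteria.

    ``members_df`` must carry person_id and age_band. Returns
    {root: (selected, overall, slope, r2)} for every root observed.
    """
    presence = naive_presence(claims_df, members_df["person_id"], window)
    roots = sorted({root for (_, root) in presence})
    bands = dict(zip(members_df["person_id"], members_df["age_band"]))
    n = len(members_df)
    band_members = defaultdict(list)
    for pid, b in bands.items():
        band_members[b].append(pid)
    out = {}
    for root in roots:
        overall = sum(presence.get((pid, root), 0) for pid in bands) / n
        populated = sorted(b for b in band_members if band_members[b])
        prevs = [
            sum(presence.get((pid, root), 0) for pid in band_members[b]) / len(band_members[b])
            for b in populated
        ]
        if len(populated) >= 3:
            slope, r2 = naive_ols(populated, prevs)
            trend = slope > 0 and not math.isnan(r2) and r2 > min_r2
        else:
            slope, r2, trend = float("nan"), float("nan"), False
        saturated = prevs[0] >= 1.0 if prevs else False
        selected = (overall > min_prevalence) and trend and not saturated
        out[root] = (selected, overall, slope, r2)
    return out


def breslow_log_partial_likelihood(beta, times, events, x):
    """Written-out Breslow log partial likelihood for one covariate."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        d = dead.sum()
        ll += beta * x[dead].sum() - d * math.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def brute_force_cox_beta(times, events, x, bound=6.0):
    """1-D maximization of the written-out partial likelihood."""
    res = minimize_scalar(
        lambda b: -breslow_log_partial_likelihood(b, times, events, x),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def mann_whitney_c(scores_cases, scores_controls) -> float:
    """Concordance as the tie-corrected Mann-Whitney statistic."""
    n_pairs = wins = 0
    for a in scores_cases:
        for b in scores_controls:
            n_pairs += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / n_pairs


def product_limit(times, events):
    """Hand product-limit estimator: [(t, S(t))] at event times."""
    n = len(times)
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    curve = []
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        curve.append((float(t), s))
    return curve


def two_group_logrank(times, events, group):
    """Hand-computed two-group log-rank chi-square (hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & (group == 1)).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v
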