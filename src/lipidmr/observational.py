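"""Observational comparator analyses.

Multivariable linear regression of each outcome on the measured exposure
plus covariates, percentile grouping of the exposure for descriptive
tables, Cuzick's rank test for trend across ordered groups, and the
Cochran-Armitage chi-square test for trend in proportions.  These are the
non-genetic estimates the MR results are contrasted against: under
confounding they can differ from — even flip sign relative to — the
causal effect, by the omitted-variable-bias formula
``beta_OLS = beta + a_x a_y var(U) / var(X)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, DataError, DomainError

Z975 = stats.norm.ppf(0.975)

DEFAULT_PERCENTILE_CUTS = (50, 75, 90, 95)


@dataclass
class ObsEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    covariates: list


@dataclass
class TrendResult:
    statistic: float
    p: float
    test_name: str


def multivariable_ols(outcome, exposure, covariates=None,
                      covariate_names=None) -> ObsEstimate:
    """OLS coefficient on the exposure with normal-theory CI and p."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    n = len(y)
    if covariates is None:
        X = np.column_stack([x, np.ones(n)])
        names = []
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([x, np.ones(n), C])
        names = list(covariate_names) if covariate_names else [f"cov_{i}" for i in range(C.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(columns=names)
    fit = sm.OLS(y, X).fit()
    beta, se = fit.params[0], fit.bse[0]
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return ObsEstimate(beta=float(beta), se=float(se),
                       ci_low=float(beta - Z975 * se),
                       ci_high=float(beta + Z975 * se),
                       p=float(p), n_used=n, covariates=names)


def percentile_grouping(values, cuts=DEFAULT_PERCENTILE_CUTS):
    """Assign each value to a percentile group with right-closed bins.

    With the default edges (50, 75, 90, 95) the labels are
    ``0-50%, 51-75%, 76-90%, 91-95%, 96-100%`` and the group sizes always
    sum to n.  Group membership uses the empirical percentile rank
    (average rank under ties), so identical values share a group.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise DataError("empty input")
    cuts = tuple(cuts)
    if any(not (0 < c < 100) for c in cuts) or list(cuts) != sorted(set(cuts)):
        raise DataError("cuts must be strictly increasing within (0, 100)")
    if np.all(values == values[0]):
        warnings.warn("all values identical: single percentile group",
                      UserWarning, stacklevel=2)
    pr = stats.rankdata(values, method="average") / len(values) * 100.0
    edges = list(cuts) + [100.0]
    labels = []
    prev = 0
    for c in edges:
        labels.append(f"{prev}-{int(c)}%")
        prev = int(c) + 1
    idx = np.searchsorted(np.asarray(edges, dtype=float), pr, side="left")
    idx = np.minimum(idx, len(edges) - 1)
    return np.asarray(labels, dtype=object)[idx]


def cuzick_trend(values, group_labels, group_order=None) -> TrendResult:
    """Cuzick's nonparametric test for trend across ordered groups.

    Ranks all observations jointly (midranks under ties), scores groups
    1..G in the given order, and standardizes
    ``T = sum_g score_g * ranksum_g`` by its permutation-null mean and
    variance (with the tie correction).  Two-sided normal p.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if group_order is None:
        group_order = list(pd.unique(labels))
    if len(group_order) < 2:
        raise DomainError("need at least 2 groups for a trend test")
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    scores = np.empty(n)
    group_sizes = []
    for g, name in enumerate(group_order, start=1):
        mask = labels == name
        if mask.sum() == 0:
            raise DataError(f"group {name!r} is empty")
        scores[mask] = g
        group_sizes.append(int(mask.sum()))
    t_obs = float(np.sum(scores * ranks))
    sum_nl = float(np.sum(scores))                       # sum_g n_g l_g
    l2 = float(np.sum([g**2 * m for g, m in enumerate(group_sizes, 1)]))
    e_t = sum_nl * (n + 1) / 2.0
    # tie correction on the rank variance (midranks)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    var_t = (n + 1) / 12.0 * (n * l2 - sum_nl**2) * tie
    if var_t <= 0:
        raise DataError("degenerate trend variance (all observations tied)")
    z = (t_obs - e_t) / math.sqrt(var_t)
    return TrendResult(statistic=float(z),
                       p=float(2 * stats.norm.sf(abs(z))),
                       test_name="cuzick")


def chi2_trend(success_counts, group_sizes, scores=None) -> TrendResult:
    """Cochran-Armitage chi-square test for a linear trend in proportions
    across ordered groups (df 1, two-sided)."""
    x = np.asarray(success_counts, dtype=float)
    m = np.asarray(group_sizes, dtype=float)
    if np.any(m <= 0):
        raise DataError("zero-size group")
    if np.any(x > m) or np.any(x < 0):
        raise DataError("success counts must lie in [0, group size]")
    g = len(x)
    s = np.asarray(scores, dtype=float) if scores is not None else np.arange(1, g + 1, dtype=float)
    n = m.sum()
    p_bar = x.sum() / n
    s_bar = np.sum(m * s) / n
    num = np.sum(s * (x - m * p_bar))
    den = p_bar * (1 - p_bar) * np.sum(m * (s - s_bar) ** 2)
    if den == 0:
        return TrendResult(statistic=0.0, p=1.0, test_name="chi2_trend")
    stat = float(num**2 / den)
    return TrendResult(statistic=stat, p=float(stats.chi2.sf(stat, 1)),
                       test_name="chi2_trend")


def group_summary(df: pd.DataFrame, group_col: str, value_cols,
                  group_order=None) -> pd.DataFrame:
    """Descriptive per-group means/SDs for a grouped table, with Cuzick
    trend p per value column."""
    order = group_order or list(pd.unique(df[group_col]))
    rows = []
    for col in value_cols:
        rec = {"variable": col}
        for g in order:
            sub = df.loc[df[group_col] == g, col]
            rec[str(g)] = f"{sub.mean():.1f} ± {sub.std():.1f}"
        trend = cuzick_trend(df[col].to_numpy(), df[group_col].to_numpy(), order)
        rec["p_trend"] = trend.p
        rows.append(rec)
    return pd.DataFrame(rows)
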