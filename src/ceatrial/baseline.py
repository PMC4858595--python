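"""Descriptive and diagnostic statistics for the trial sample.

Covers the baseline group comparisons (uncorrected Pearson chi-square for
discrete variables, pooled-variance Student t for continuous ones), the
change scores that define the effect measures, the skewness z-score used to
diagnose right-tailed cost distributions, and the one-way ANOVA
variance-components estimator of the intraclass correlation
rho = s_b^2 / (s_b^2 + s_w^2) for school-level clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ChangeScores", "IccResult", "compute_change_scores",
    "chi_square_independence", "two_sample_t", "skewness_zscore",
    "icc_anova", "IccAnova", "baseline_table",
]


@dataclass(frozen=True)
class ChangeScores:
    """T0 minus T1 for both outcomes; positive means a reduction."""

    weekly_reduction: float
    binge_reduction: float


@dataclass(frozen=True)
class IccResult:
    rho: float
    s2_between: float
    s2_within: float


def compute_change_scores(record) -> ChangeScores:
    """Change scores for one participant; raises if T1 is missing."""
    w1, b1 = record.get("weekly_glasses_t1"), record.get("binge_t1")
    if w1 is None or b1 is None or pd.isna(w1) or pd.isna(b1):
        pid = record.get("participant_id", "<unknown>")
        raise ValueError(f"participant {pid} has no T1 measurement")
    return ChangeScores(
        weekly_reduction=float(record["weekly_glasses_t0"]) - float(w1),
        binge_reduction=float(record["binge_t0"]) - float(b1),
    )


def add_change_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized change scores for a table of T1 completers."""
    missing = df["weekly_glasses_t1"].isna() | df["binge_t1"].isna()
    if missing.any():
        ids = df.loc[missing, "participant_id"].tolist()[:5]
        raise ValueError(f"participants without T1 measurement: {ids} ...")
    out = df.copy()
    out["weekly_reduction"] = df["weekly_glasses_t0"] - df["weekly_glasses_t1"]
    out["binge_reduction"] = df["binge_t0"] - df["binge_t1"]
    return out


def chi_square_independence(table) -> float:
    """Uncorrected Pearson X^2 for an r x c contingency table of counts."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need an at least 2x2 table")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be nonnegative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, _, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(stat)


def two_sample_t(group_a, group_b) -> float:
    """Pooled-variance Student t; positive when group_b has the larger mean."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(b, a, equal_var=True)
    return float(res.statistic)


def skewness_zscore(values) -> float:
    """Adjusted sample skewness G1 over its standard error.

    SE(G1) = sqrt(6 n (n-1) / ((n-2)(n+1)(n+3))).  A z above 1.96 marks a
    distribution skewed and tailed to the right.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined skewness")
    g1_adj = stats.skew(x, bias=False)
    se = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    return float(g1_adj / se)


def icc_anova(values, clusters) -> IccResult:
    """Method-of-moments one-way ANOVA intraclass correlation.

    s_w^2 = MSW; s_b^2 = max(0, (MSB - MSW) / n0) with n0 the
    imbalance-adjusted average cluster size (N - sum n_i^2 / N) / (k - 1);
    rho = s_b^2 / (s_b^2 + s_w^2).
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(clusters)
    if len(x) != len(g):
        raise ValueError("values and clusters differ in length")
    labels, inv = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    n_i = np.bincount(inv)
    N = len(x)
    grand = x.mean()
    means = np.bincount(inv, weights=x) / n_i
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(np.sum((x - means[inv]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - np.sum(n_i ** 2) / N) / (k - 1)
    s2_b = max(0.0, (msb - msw) / n0)
    s2_w = msw
    denom = s2_b + s2_w
    rho = s2_b / denom if denom > 0 else 0.0
    return IccResult(rho=rho, s2_between=s2_b, s2_within=s2_w)


class IccAnova(BaseEstimator):
    """Estimator form of :func:`icc_anova`.

    ``fit(X, y)`` takes outcome values ``X`` (1-d) and cluster labels ``y``;
    fitted attributes are ``rho_``, ``s2_between_``, ``s2_within_``.
    """

    def fit(self, X, y):
        res = icc_anova(np.ravel(X), y)
        self.rho_ = res.rho
        self.s2_between_ = res.s2_between
        self.s2_within_ = res.s2_within
        return self


def baseline_table(df: pd.DataFrame, arm_col: str = "arm") -> pd.DataFrame:
    """Arm-comparison table: counts/means per arm with test statistics.

    Discrete variables get an uncorrected Pearson chi-square (binary
    splits as in the published comparisons: gender, education, religious
    vs not, Dutch vs not); continuous ones a pooled-variance t.
    """
    arms = sorted(df[arm_col].unique())
    if len(arms) != 2:
        raise ValueError("baseline table expects exactly two arms")
    a, b = "control", "intervention"
    rows = []

    def _binary(name, series_bool):
        tab = pd.crosstab(df[arm_col], series_bool)
        if tab.shape != (2, 2) or (tab.values.sum(axis=0) == 0).any():
            return
        stat = chi_square_independence(tab.values)
        p = float(stats.chi2.sf(stat, 1))
        rows.append({"variable": name, "type": "chi2",
                     f"n_{a}": int((df[arm_col] == a).sum()),
                     f"n_{b}": int((df[arm_col] == b).sum()),
                     "statistic": stat, "p": p})

    def _continuous(name, series):
        ga = series[df[arm_col] == a].dropna()
        gb = series[df[arm_col] == b].dropna()
        try:
            stat = two_sample_t(ga, gb)
        except ValueError:
            return
        dof = len(ga) + len(gb) - 2
        p = float(2 * stats.t.sf(abs(stat), dof))
        rows.append({"variable": name, "type": "t",
                     f"mean_{a}": float(ga.mean()), f"mean_{b}": float(gb.mean()),
                     "statistic": stat, "p": p})

    _continuous("age", df["age"])
    _binary("gender_female", df["gender"] == "female")
    _binary("education_low", df["education"] == "low")
    _binary("religious", df["religion"] != "none")
    _binary("ethnicity_dutch", df["ethnicity"] == "Dutch")
    _binary("never_drinker", df["weekly_glasses_t0"] == 0)
    _binary("binge_drinker", df["binge_t0"] > 0)
    _continuous("binge_t0", df["binge_t0"])
    _continuous("weekly_glasses_t0", df["weekly_glasses_t0"])
    return pd.DataFrame(rows)
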