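"""Exclusion rules and an auditable participant-flow report.

Two screening passes mirror the data-preparation protocol of a trial with
open-ended service-use questions: first, participants whose answers breach
plausibility limits (strictly above the limit; the boundary value is
retained) are excluded whole-case; second, participants who answered none of
the cost questions are removed.  At follow-up the pass is preceded by
removal of participants who did not take part in the follow-up measurement
at all.  Every pass is recorded as a chained stage in a
:class:`FlowReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP, ROUND_DOWN

import pandas as pd
import yaml
from sklearn.base import BaseEstimator

__all__ = [
    "PlausibilityLimits", "FlowStage", "FlowReport", "percentage",
    "flag_unrealistic", "screen_baseline", "screen_followup",
    "exclude_cost_outliers", "build_flow_report", "PlausibilityScreen",
]


@dataclass(frozen=True)
class PlausibilityLimits:
    """Maximum credible volume per category over the recall window.

    A value strictly above its limit is an "unrealistic answer".  Day-count
    categories can never exceed the recall window itself (default 120 days).
    """

    limits: dict
    recall_days: int = 120

    def __post_init__(self):
        for cat, lim in self.limits.items():
            if lim <= 0:
                raise ValueError(f"limit for {cat!r} must be positive")
            if cat.endswith("_days") and lim > self.recall_days:
                raise ValueError(
                    f"limit for {cat!r} ({lim}) exceeds the "
                    f"{self.recall_days}-day recall window")

    @classmethod
    def from_yaml(cls, path) -> "PlausibilityLimits":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(limits={k: float(v) for k, v in d["limits"].items()},
                   recall_days=int(d.get("recall_days", 120)))


def percentage(numerator: int, denominator: int, decimals: int = 1,
               rounding: str = "half_up") -> float:
    """n/d as a percentage, rounded to ``decimals``.

    ``rounding`` is ``'half_up'`` (default) or ``'truncate'``.  Published
    flow figures mix both conventions, so the rule is explicit here.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    mode = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}[rounding]
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=mode)
    return float(pct)


@dataclass(frozen=True)
class FlowStage:
    label: str
    n_before: int
    n_excluded: int

    @property
    def n_after(self) -> int:
        return self.n_before - self.n_excluded


@dataclass
class FlowReport:
    """Chained exclusion stages with configurable percentage rendering."""

    stages: list
    decimals: int = 1
    rounding: str = "half_up"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            rows.append({
                "label": s.label, "n_before": s.n_before,
                "n_excluded": s.n_excluded, "n_after": s.n_after,
                "pct_excluded": percentage(s.n_excluded, s.n_before,
                                           self.decimals, self.rounding),
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = []
        for s in self.stages:
            pct = percentage(s.n_excluded, s.n_before, self.decimals, self.rounding)
            lines.append(f"{s.n_before:>6}  {s.label}")
            lines.append(f"        -{s.n_excluded} excluded ({pct}%)")
        if self.stages:
            lines.append(f"{self.stages[-1].n_after:>6}  analyzed")
        return "\n".join(lines)


def build_flow_report(stages, decimals: int = 1,
                      rounding: str = "half_up") -> FlowReport:
    """Assemble chained stages into a report; stages must chain exactly."""
    stages = list(stages)
    for prev, nxt in zip(stages, stages[1:]):
        if prev.n_after != nxt.n_before:
            raise ValueError(
                f"broken stage chain: {prev.label!r} leaves {prev.n_after} "
                f"but {nxt.label!r} starts from {nxt.n_before}")
    return FlowReport(stages=stages, decimals=decimals, rounding=rounding)


def _volume_columns(df: pd.DataFrame, limits: PlausibilityLimits) -> list:
    cols = [c for c in limits.limits if c in df.columns]
    missing = [c for c in df.columns if c in limits.limits and c not in cols]
    if missing:  # pragma: no cover - defensive
        raise ValueError(f"limits missing for {missing}")
    return cols


def flag_unrealistic(record, limits: PlausibilityLimits) -> list:
    """Categories whose volume strictly exceeds its plausibility limit."""
    out = []
    for cat, lim in limits.limits.items():
        val = record.get(cat)
        if val is not None and not pd.isna(val) and val > lim:
            out.append(cat)
    return out


def _violation_mask(df: pd.DataFrame, limits: PlausibilityLimits) -> pd.Series:
    mask = pd.Series(False, index=df.index)
    for cat in _volume_columns(df, limits):
        mask |= df[cat].fillna(0) > limits.limits[cat]
    return mask


def screen_baseline(df: pd.DataFrame, limits: PlausibilityLimits):
    """Baseline screen: unrealistic answers first, then missing cost answers.

    Returns a new frame (input untouched) and the ordered stage list.
    """
    if len(df) == 0:
        raise ValueError("empty participant table")
    stages = []
    bad = _violation_mask(df, limits)
    stages.append(FlowStage("unrealistic answers (T0)", len(df), int(bad.sum())))
    df1 = df.loc[~bad]
    no_costs = ~df1["cost_answers_present_t0"].astype(bool)
    stages.append(FlowStage("no cost answers at T0", len(df1), int(no_costs.sum())))
    df2 = df1.loc[~no_costs].copy()
    return df2, stages


def screen_followup(df: pd.DataFrame, limits: PlausibilityLimits):
    """Follow-up screen: non-participation, unrealistic answers, missing costs."""
    if len(df) == 0:
        raise ValueError("empty participant table")
    stages = []
    absent = df["weekly_glasses_t1"].isna()
    stages.append(FlowStage("did not participate at T1", len(df), int(absent.sum())))
    df1 = df.loc[~absent]
    bad = _violation_mask(df1, limits)
    stages.append(FlowStage("unrealistic answers (T1)", len(df1), int(bad.sum())))
    df2 = df1.loc[~bad]
    no_costs = ~df2["cost_answers_present_t1"].astype(bool)
    stages.append(FlowStage("no cost answers at T1", len(df2), int(no_costs.sum())))
    df3 = df2.loc[~no_costs].copy()
    return df3, stages


def exclude_cost_outliers(costs: pd.DataFrame, threshold: float,
                          perspective: str = "societal"):
    """Drop participants whose perspective total is strictly above ``threshold``.

    Returns (retained frame, list of excluded participant ids).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    col = {"healthcare": "cost_healthcare_perspective",
           "societal": "cost_societal_perspective"}.get(perspective, perspective)
    if col not in costs.columns:
        raise ValueError(f"no column {col!r} in cost table")
    out = costs[col] > threshold
    excluded = (costs.loc[out, "participant_id"].tolist()
                if "participant_id" in costs.columns
                else list(costs.index[out]))
    return costs.loc[~out].copy(), excluded


class PlausibilityScreen(BaseEstimator):
    """Estimator wrapper over the screening passes.

    Parameters
    ----------
    limits : PlausibilityLimits
    stage : {'baseline', 'followup'}

    After :meth:`transform`, ``flow_stages_`` holds the stage list and
    ``excluded_ids_`` the participant ids removed.
    """

    def __init__(self, limits=None, stage="baseline"):
        self.limits = limits
        self.stage = stage

    def fit(self, X: pd.DataFrame, y=None):
        if self.limits is None:
            raise ValueError("limits is required")
        if self.stage not in ("baseline", "followup"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        fn = screen_baseline if self.stage == "baseline" else screen_followup
        kept, stages = fn(X, self.limits)
        self.flow_stages_ = stages
        if "participant_id" in X.columns:
            self.excluded_ids_ = sorted(
                set(X["participant_id"]) - set(kept["participant_id"]))
        else:
            self.excluded_ids_ = sorted(set(X.index) - set(kept.index))
        return kept

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
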