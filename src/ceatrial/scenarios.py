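"""Base-case, sensitivity and subgroup cost-effectiveness scenarios.

A single :class:`ScenarioConfig` drives the whole evaluation: the screened
analysis set is costed once, then the bootstrap engine runs per
perspective x outcome for the base case, for the outlier-excluded and
substance-cost-excluded sensitivity scenarios, and for every dichotomized
subgroup.  Replicate seeds depend on the outcome (and, for subgroups, a
stable hash of the subgroup label) but not on the perspective, so a change
of perspective changes only costs — never effects — and adding a subgroup
never changes any other cell.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import pandas as pd

from .baseline import add_change_scores, baseline_table
from .cea import BootstrapCEA
from .costing import (InterventionCostSpec, SUBSTANCE, UnitCostTable,
                      summarize_costs, value_costs_table)
from .screening import (PlausibilityLimits, build_flow_report,
                        exclude_cost_outliers, screen_baseline,
                        screen_followup)

__all__ = [
    "SubgroupSpec", "ScenarioConfig", "AnalysisSet", "CEAResult",
    "default_subgroups", "dichotomize", "prepare_analysis_set",
    "run_base_case", "run_sensitivity", "run_subgroups", "run_all",
    "ReportBundle",
]

PERSPECTIVE_COLS = {
    "healthcare": "cost_healthcare_perspective",
    "societal": "cost_societal_perspective",
    "societal_ex_substance": "cost_societal_ex_substance",
}
EFFECT_COLS = {"weekly": "weekly_reduction", "binge": "binge_reduction"}


@dataclass(frozen=True)
class SubgroupSpec:
    """Total, two-valued mapping of a background variable's raw values."""

    variable: str
    rule: dict

    def __post_init__(self):
        labels = set(self.rule.values())
        if len(labels) != 2:
            raise ValueError(
                f"subgroup rule for {self.variable!r} must yield exactly two "
                f"labels, got {sorted(map(str, labels))}")

    @property
    def labels(self) -> tuple:
        seen = []
        for lab in self.rule.values():
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def apply(self, df: pd.DataFrame) -> pd.Series:
        vals = df[self.variable]
        uncovered = sorted(set(map(str, vals.unique())) - set(map(str, self.rule)))
        if uncovered:
            raise KeyError(
                f"values of {self.variable!r} not covered by rule: {uncovered}")
        return vals.astype(str).map({str(k): v for k, v in self.rule.items()})


def default_subgroups() -> list:
    """The standard dichotomizations: gender, age 15-16 vs >=17, education,
    religious vs not, Dutch vs non-Dutch ethnicity."""
    from .synthdata import ETHNICITIES, RELIGIONS
    return [
        SubgroupSpec("gender", {"male": "male", "female": "female"}),
        SubgroupSpec("age", {"15": "15-16", "16": "15-16",
                             "17": ">=17", "18": ">=17", "19": ">=17"}),
        SubgroupSpec("education", {"low": "low", "high": "high"}),
        SubgroupSpec("religion", {r: ("not religious" if r == "none"
                                      else "religious") for r in RELIGIONS}),
        SubgroupSpec("ethnicity", {e: ("Dutch" if e == "Dutch" else "non-Dutch")
                                   for e in ETHNICITIES}),
    ]


def dichotomize(record, spec: SubgroupSpec) -> str:
    """Label one participant record under a subgroup rule."""
    val = str(record[spec.variable])
    rule = {str(k): v for k, v in spec.rule.items()}
    if val not in rule:
        raise KeyError(f"value {val!r} of {spec.variable!r} not covered by rule")
    return rule[val]


@dataclass
class ScenarioConfig:
    perspectives: tuple = ("healthcare", "societal")
    outcomes: tuple = ("weekly", "binge")
    n_reps: int = 5000
    seed: int = 0
    outlier_threshold: float = 5000.0
    include_substance_costs: bool = True
    subgroups: list = field(default_factory=default_subgroups)
    wtp_max: float = 1000.0
    wtp_step: float = 10.0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be positive")


def _cell_seed(base_seed: int, outcome: str, label: str = "") -> int:
    h = zlib.crc32(f"{outcome}|{label}".encode())
    return (int(base_seed) + h) % (2 ** 31)


@dataclass
class AnalysisSet:
    """Screened completers with change scores and perspective cost columns."""

    data: pd.DataFrame
    flow: object
    costs: pd.DataFrame
    participants: pd.DataFrame


def prepare_analysis_set(participants: pd.DataFrame,
                         limits: PlausibilityLimits,
                         unit_costs: UnitCostTable,
                         intervention_spec: InterventionCostSpec | None = None,
                         flow_decimals: int = 1) -> AnalysisSet:
    """Screen, compute change scores, and value costs for analysis."""
    base, st0 = screen_baseline(participants, limits)
    complete, st1 = screen_followup(base, limits)
    flow = build_flow_report(st0 + st1, decimals=flow_decimals)
    scored = add_change_scores(complete)
    costs = value_costs_table(complete, unit_costs, intervention_spec)
    costs["cost_societal_ex_substance"] = (
        costs["cost_societal_perspective"] - costs[f"cost_sector_{SUBSTANCE}"])
    keep = ["participant_id", "cluster_id", "arm", "gender", "age",
            "education", "religion", "ethnicity",
            "weekly_reduction", "binge_reduction"]
    keep = [c for c in keep if c in scored.columns]
    cost_cols = ["participant_id"] + [c for c in costs.columns
                                      if c.startswith("cost_")]
    data = scored[keep].merge(costs[cost_cols], on="participant_id")
    return AnalysisSet(data=data, flow=flow, costs=costs, participants=complete)


@dataclass
class CEAResult:
    scenario: str
    perspective: str
    outcome: str
    estimator: BootstrapCEA

    @property
    def distribution(self):
        return self.estimator.distribution_

    @property
    def ceac(self):
        return self.estimator.ceac_


def _run_cell(df: pd.DataFrame, perspective: str, outcome: str,
              config: ScenarioConfig, scenario: str,
              seed_label: str = "") -> CEAResult:
    est = BootstrapCEA(
        n_reps=config.n_reps,
        seed=_cell_seed(config.seed, outcome, seed_label),
        wtp_max=config.wtp_max, wtp_step=config.wtp_step,
        cost_col=PERSPECTIVE_COLS[perspective],
        effect_col=EFFECT_COLS[outcome],
    ).fit(df)
    return CEAResult(scenario=scenario, perspective=perspective,
                     outcome=outcome, estimator=est)


def run_base_case(aset: AnalysisSet, config: ScenarioConfig) -> dict:
    """Full engine per perspective x outcome on the whole analysis set."""
    out = {}
    for p in config.perspectives:
        for o in config.outcomes:
            out[(p, o)] = _run_cell(aset.data, p, o, config, "base_case")
    return out


def run_sensitivity(aset: AnalysisSet, config: ScenarioConfig) -> dict:
    """Outlier-excluded (per perspective) and substance-cost-excluded scenarios."""
    out = {}
    for p in config.perspectives:
        kept, _ = exclude_cost_outliers(aset.data, config.outlier_threshold,
                                        PERSPECTIVE_COLS[p])
        for o in config.outcomes:
            out[("outlier_excluded", p, o)] = _run_cell(
                kept, p, o, config, "outlier_excluded")
    for o in config.outcomes:
        out[("ex_substance", "societal_ex_substance", o)] = _run_cell(
            aset.data, "societal_ex_substance", o, config, "ex_substance")
    return out


def run_subgroups(aset: AnalysisSet, config: ScenarioConfig) -> dict:
    """Full engine per subgroup level; empty arm cells are skipped with a warning."""
    out = {}
    for spec in config.subgroups:
        labels = spec.apply(aset.data)
        for label in spec.labels:
            sub = aset.data[labels == label]
            if any((sub["arm"] == a).sum() == 0
                   for a in ("intervention", "control")):
                warnings.warn(
                    f"subgroup {spec.variable}={label}: empty arm cell, skipped")
                continue
            for p in config.perspectives:
                for o in config.outcomes:
                    out[(spec.variable, label, p, o)] = _run_cell(
                        sub, p, o, config, f"subgroup:{spec.variable}",
                        seed_label=f"{spec.variable}={label}")
    return out


@dataclass
class ReportBundle:
    config: ScenarioConfig
    analysis: AnalysisSet
    base_case: dict
    sensitivity: dict
    subgroups: dict
    baseline: pd.DataFrame
    cost_summary: pd.DataFrame


def run_all(participants: pd.DataFrame, limits: PlausibilityLimits,
            unit_costs: UnitCostTable,
            intervention_spec: InterventionCostSpec | None,
            config: ScenarioConfig) -> ReportBundle:
    """End-to-end: screen, cost, describe, then all bootstrap scenarios."""
    aset = prepare_analysis_set(participants, limits, unit_costs,
                                intervention_spec)
    return ReportBundle(
        config=config,
        analysis=aset,
        base_case=run_base_case(aset, config),
        sensitivity=run_sensitivity(aset, config),
        subgroups=run_subgroups(aset, config),
        baseline=baseline_table(aset.participants),
        cost_summary=summarize_costs(aset.costs, n_boot=1000, seed=config.seed),
    )
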