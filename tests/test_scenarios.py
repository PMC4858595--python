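"""Scenario orchestration: subgroups, sensitivity toggles, reporting."""

import numpy as np
import pandas as pd
import pytest

from ceatrial import generate_trial
from ceatrial.config import (default_intervention_spec, default_limits,
                             default_unit_costs)
from ceatrial.reporting import cea_table, render_reports
from ceatrial.scenarios import (ScenarioConfig, SubgroupSpec,
                                default_subgroups, dichotomize,
                                prepare_analysis_set, run_all, run_base_case,
                                run_sensitivity, run_subgroups)
from .conftest import clean_scenario


@pytest.fixture(scope="module")
def aset():
    df, _ = generate_trial(clean_scenario(seed=42))
    return prepare_analysis_set(df, default_limits(), default_unit_costs(),
                                default_intervention_spec())


@pytest.fixture(scope="module")
def config():
    return ScenarioConfig(n_reps=400, seed=10)


class TestDichotomize:
    @pytest.mark.parametrize("variable,value,label", [
        ("age", 16, "15-16"), ("age", 17, ">=17"),
        ("religion", "Catholic", "religious"),
        ("religion", "none", "not religious"),
        ("ethnicity", "Turkish", "non-Dutch"),
        ("ethnicity", "Dutch", "Dutch"),
        ("education", "low", "low"),
        ("gender", "female", "female"),
    ])
    def test_default_rules(self, variable, value, label):
        spec = next(s for s in default_subgroups() if s.variable == variable)
        assert dichotomize({variable: value}, spec) == label

    def test_uncovered_value_rejected(self):
        spec = SubgroupSpec("gender", {"male": "a", "female": "b"})
        with pytest.raises(KeyError, match="unicorn"):
            dichotomize({"gender": "unicorn"}, spec)

    def test_rule_must_have_two_labels(self):
        with pytest.raises(ValueError):
            SubgroupSpec("gender", {"male": "a", "female": "a"})


class TestBaseCase:
    def test_null_scenario_cis_cover_zero(self):
        sc = clean_scenario(arm_effect_weekly=0.0, arm_effect_binge=0.0,
                            secular_drift_weekly=0.0, secular_drift_binge=0.0,
                            seed=9)
        df, _ = generate_trial(sc)
        aset0 = prepare_analysis_set(df, default_limits(),
                                     default_unit_costs(), None)
        res = run_base_case(aset0, ScenarioConfig(n_reps=800, seed=4))
        cell = res[("societal", "weekly")].estimator
        lo, hi = cell.ci_effect_
        assert lo < 0 < hi

    def test_effects_identical_across_perspectives(self, aset, config):
        res = run_base_case(aset, config)
        for outcome in ("weekly", "binge"):
            hc = res[("healthcare", outcome)].distribution
            so = res[("societal", outcome)].distribution
            np.testing.assert_array_equal(hc.delta_effects, so.delta_effects)

    def test_deterministic_rerun(self, aset, config):
        r1 = run_base_case(aset, config)
        r2 = run_base_case(aset, config)
        for key in r1:
            np.testing.assert_array_equal(r1[key].distribution.replicates,
                                          r2[key].distribution.replicates)


class TestSensitivity:
    def test_no_outliers_equals_base_case(self, aset, config):
        base = run_base_case(aset, config)
        big = ScenarioConfig(n_reps=config.n_reps, seed=config.seed,
                             outlier_threshold=1e9)
        sens = run_sensitivity(aset, big)
        for p in ("healthcare", "societal"):
            np.testing.assert_array_equal(
                sens[("outlier_excluded", p, "weekly")].distribution.replicates,
                base[(p, "weekly")].distribution.replicates)

    def test_zero_substance_costs_equals_societal_base(self, config):
        df, _ = generate_trial(clean_scenario(seed=13))
        df = df.copy()
        for cat in ("cigarette_packs", "soft_drug_units", "hard_drug_units"):
            df[cat] = 0.0
        a = prepare_analysis_set(df, default_limits(), default_unit_costs(),
                                 default_intervention_spec())
        base = run_base_case(a, config)
        sens = run_sensitivity(a, config)
        np.testing.assert_array_equal(
            sens[("ex_substance", "societal_ex_substance",
                  "weekly")].distribution.replicates,
            base[("societal", "weekly")].distribution.replicates)

    def test_outlier_exclusion_lowers_arm_mean(self, config):
        df, _ = generate_trial(clean_scenario(seed=14))
        df = df.copy()
        # one massive (but plausible per-category) cost in the control arm
        target = df[df["arm"] == "control"].index[0]
        df.loc[target, "hospital_days"] = 20.0  # ~9600 EUR, over threshold
        a = prepare_analysis_set(df, default_limits(), default_unit_costs(),
                                 default_intervention_spec())
        base = run_base_case(a, config)
        sens = run_sensitivity(a, config)
        before = base[("societal", "weekly")].estimator.arm_summaries_
        after = sens[("outlier_excluded", "societal",
                      "weekly")].estimator.arm_summaries_
        assert after["control"].mean_cost < before["control"].mean_cost
        n_over = int(((a.data["arm"] == "control")
                      & (a.data["cost_societal_perspective"] > 5000)).sum())
        assert n_over >= 1
        assert after["control"].n == before["control"].n - n_over


class TestSubgroups:
    def test_partition_of_analyzed_n(self, aset, config):
        res = run_subgroups(aset, config)
        total = len(aset.data)
        for variable in ("gender", "age", "education", "religion",
                         "ethnicity"):
            ns = [r.estimator.arm_summaries_["intervention"].n
                  + r.estimator.arm_summaries_["control"].n
                  for (v, lab, p, o), r in res.items()
                  if v == variable and p == "societal" and o == "weekly"]
            assert sum(ns) == total

    def test_partition_brackets_base_case_effect(self, aset, config):
        base = run_base_case(aset, config)
        res = run_subgroups(aset, config)
        # the point estimates of a full partition must bracket the
        # base-case point estimate (weighted-mean argument)
        de_base = base[("societal", "weekly")].estimator.delta_effect_
        des = [r.estimator.delta_effect_ for (v, lab, p, o), r in res.items()
               if v == "gender" and p == "societal" and o == "weekly"]
        assert min(des) <= de_base <= max(des)

    def test_constructed_heterogeneity_in_age(self):
        """An effect present only in the >=17 stratum shows up there."""
        gaps = []
        for seed in range(3):
            sc = clean_scenario(arm_effect_weekly=0.0, seed=700 + seed)
            df, _ = generate_trial(sc)
            df = df.copy()
            old_iv = (df["age"] >= 17) & (df["arm"] == "intervention")
            df.loc[old_iv, "weekly_glasses_t1"] -= 3.0  # extra reduction
            df["weekly_glasses_t1"] = df["weekly_glasses_t1"].clip(lower=0)
            a = prepare_analysis_set(df, default_limits(),
                                     default_unit_costs(), None)
            res = run_subgroups(a, ScenarioConfig(n_reps=200, seed=seed))
            de = {lab: r.estimator.delta_effect_
                  for (v, lab, p, o), r in res.items()
                  if v == "age" and p == "societal" and o == "weekly"}
            gaps.append(de[">=17"] - de["15-16"])
        assert np.mean(gaps) > 1.0

    def test_empty_arm_cell_warns_and_skips(self, config):
        df, _ = generate_trial(clean_scenario(seed=15))
        df = df.copy()
        # remove every female from the control arm
        df = df[~((df["arm"] == "control") & (df["gender"] == "female"))]
        a = prepare_analysis_set(df, default_limits(), default_unit_costs(),
                                 None)
        cfg = ScenarioConfig(n_reps=50, seed=1)
        with pytest.warns(UserWarning, match="gender=female"):
            res = run_subgroups(a, cfg)
        assert not any(lab == "female" for (v, lab, p, o) in res)


class TestRendering:
    def test_quadrant_columns_sum_to_about_100(self, aset, config, tmp_path):
        res = run_base_case(aset, config)
        tab = cea_table(res, ("perspective", "outcome"))
        iv_rows = tab[tab["arm"] == "intervention"]
        sums = iv_rows[["pct_NE", "pct_NW", "pct_SW", "pct_SE"]].sum(axis=1)
        assert ((sums - 100).abs() <= 1).all()

    def test_render_is_reproducible(self, tmp_path):
        df, _ = generate_trial(clean_scenario(seed=16))
        cfg = ScenarioConfig(n_reps=100, seed=2, subgroups=[])
        bundle = run_all(df, default_limits(), default_unit_costs(),
                         default_intervention_spec(), cfg)
        m1 = render_reports(bundle, tmp_path / "a")
        m2 = render_reports(bundle, tmp_path / "b")
        assert m1["config_sha256"] == m2["config_sha256"]
        f1 = (tmp_path / "a" / "cea_base_case.csv").read_bytes()
        f2 = (tmp_path / "b" / "cea_base_case.csv").read_bytes()
        assert f1 == f2
        assert m1["sections"]["subgroups"] == "omitted (no cells)"
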