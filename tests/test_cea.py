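"""The bootstrap CEA engine: point estimates, replicates, quadrants, CEACs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ceatrial.cea import (DOMINANT, INFERIOR, UNDEFINED, ArmSummary,
                          BootstrapCEA, bootstrap_cea, ceac,
                          classify_quadrant, median_icer, nmb_summary,
                          percentile_ci, point_increments)


def _frame(iv_costs, iv_effects, c_costs, c_effects):
    n_i, n_c = len(iv_costs), len(c_costs)
    return pd.DataFrame({
        "arm": ["intervention"] * n_i + ["control"] * n_c,
        "cost": list(iv_costs) + list(c_costs),
        "effect": list(iv_effects) + list(c_effects),
    })


class TestPointIncrements:
    def test_published_base_case_healthcare(self):
        iv = ArmSummary("intervention", 387, 139.08, -0.78)
        c = ArmSummary("control", 303, 125.32, -1.51)
        res = point_increments(iv, c)
        assert res.delta_cost == pytest.approx(13.76)
        assert res.delta_effect == pytest.approx(0.73)
        assert res.point_icer == pytest.approx(18.85, abs=0.005)

    def test_published_base_case_societal(self):
        iv = ArmSummary("intervention", 387, 336.71, -0.78)
        c = ArmSummary("control", 303, 262.68, -1.51)
        res = point_increments(iv, c)
        assert res.delta_cost == pytest.approx(74.03)
        assert res.delta_effect == pytest.approx(0.73)

    def test_identical_arms_undefined(self):
        s = ArmSummary("intervention", 10, 50.0, 1.0)
        c = ArmSummary("control", 10, 50.0, 1.0)
        assert point_increments(s, c).point_icer == UNDEFINED

    def test_dominance_labels(self):
        c = ArmSummary("control", 10, 100.0, 0.0)
        dom = point_increments(ArmSummary("intervention", 10, 50.0, 1.0), c)
        inf = point_increments(ArmSummary("intervention", 10, 150.0, -1.0), c)
        assert dom.point_icer == DOMINANT
        assert inf.point_icer == INFERIOR


class TestClassifyQuadrant:
    @pytest.mark.parametrize("dc,de,quadrant", [
        (10, 1, "NE"), (-10, 1, "SE"), (-10, -1, "SW"), (10, -1, "NW"),
        (0, 0, "SW"), (0, 1, "SE"), (10, 0, "NW"),
    ])
    def test_conventions(self, dc, de, quadrant):
        assert classify_quadrant(dc, de) == quadrant


class TestBootstrap:
    def test_constant_data_collapses_to_point(self):
        df = _frame([60.0] * 4, [2.0] * 4, [50.0] * 4, [1.0] * 4)
        dist = bootstrap_cea(df, n_reps=200, seed=0)
        assert np.all(dist.delta_costs == 10.0)
        assert np.all(dist.delta_effects == 1.0)
        assert dist.quadrant_proportions["NE"] == 1.0

    def test_same_seed_identical(self):
        df = _frame([1.0, 5.0, 9.0], [0.1, 0.5, 0.9], [2.0, 4.0], [0.2, 0.4])
        d1 = bootstrap_cea(df, n_reps=300, seed=42)
        d2 = bootstrap_cea(df, n_reps=300, seed=42)
        np.testing.assert_array_equal(d1.replicates, d2.replicates)
        assert d1.quadrant_proportions == d2.quadrant_proportions

    def test_quadrant_proportions_sum_to_one(self):
        df = _frame([1.0, -5.0, 9.0], [0.4, -0.5, 0.9], [2.0, 4.0, -1.0],
                    [0.2, 0.4, -0.3])
        dist = bootstrap_cea(df, n_reps=999, seed=5)
        assert sum(dist.quadrant_proportions.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_per_arm", [2, 3])
    def test_exhaustive_enumeration_oracle(self, n_per_arm):
        """Quadrant proportions match exact enumeration of all within-arm
        resamples, within 3-sigma multinomial bounds at 5000 replications."""
        rng = np.random.default_rng(2024)
        iv_c = rng.normal(60, 30, n_per_arm)
        iv_e = rng.normal(0.5, 1.0, n_per_arm)
        c_c = rng.normal(50, 30, n_per_arm)
        c_e = rng.normal(0.0, 1.0, n_per_arm)
        exact = {q: 0.0 for q in ("NE", "NW", "SW", "SE")}
        draws = list(itertools.product(range(n_per_arm), repeat=n_per_arm))
        for di in draws:
            for dc_ in draws:
                dcost = iv_c[list(di)].mean() - c_c[list(dc_)].mean()
                deff = iv_e[list(di)].mean() - c_e[list(dc_)].mean()
                exact[classify_quadrant(dcost, deff)] += 1
        total = len(draws) ** 2
        exact = {q: v / total for q, v in exact.items()}
        df = _frame(iv_c, iv_e, c_c, c_e)
        dist = bootstrap_cea(df, n_reps=5000, seed=17)
        for q, p in exact.items():
            se = np.sqrt(max(p * (1 - p), 1e-12) / 5000)
            assert abs(dist.quadrant_proportions[q] - p) <= 3 * se + 1e-9

    def test_bootstrap_mean_converges_to_point(self):
        rng = np.random.default_rng(9)
        df = _frame(rng.lognormal(3, 1, 40), rng.normal(0.5, 1, 40),
                    rng.lognormal(3, 1, 30), rng.normal(0, 1, 30))
        est = BootstrapCEA(n_reps=50_000, seed=1).fit(df)
        dc = est.distribution_.delta_costs
        se = dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(dc.mean() - est.delta_cost_) <= 3 * se

    def test_empty_arm_rejected(self):
        df = _frame([1.0, 2.0], [0.1, 0.2], [], [])
        with pytest.raises(ValueError, match="empty arm"):
            bootstrap_cea(df, n_reps=10, seed=0)

    def test_cluster_resampling_option(self):
        df = _frame([1.0, 2.0, 8.0, 9.0], [0.1, 0.2, 0.8, 0.9],
                    [3.0, 4.0, 6.0, 7.0], [0.3, 0.4, 0.6, 0.7])
        df["cluster_id"] = ["a", "a", "b", "b", "c", "c", "d", "d"]
        dist = bootstrap_cea(df, n_reps=200, seed=3, resample="cluster")
        assert dist.replicates.shape == (200, 2)


class TestMedianIcer:
    def _dist(self, pairs, point=(10.0, 2.0)):
        df = _frame([point[0] + 50, 50 - point[0]], [point[1], -point[1]],
                    [50.0, 50.0], [0.0, 0.0])
        dist = bootstrap_cea(df, n_reps=2, seed=0)
        dist.replicates = np.array(pairs, dtype=float)
        return dist

    def test_single_replicate(self):
        dist = self._dist([(10.0, 2.0)])
        assert median_icer(dist) == pytest.approx(5.0)

    def test_odd_count_median(self):
        dist = self._dist([(10, 1), (20, 1), (30, 1)])
        assert median_icer(dist) == pytest.approx(20.0)

    def test_sorted_ratio_oracle_mixed_quadrants(self):
        rng = np.random.default_rng(12)
        pairs = np.column_stack([rng.normal(5, 20, 501),
                                 rng.normal(0.3, 1, 501)])
        pairs[pairs[:, 1] == 0, 1] = 0.1
        dist = self._dist(pairs)
        ratios = sorted(pairs[:, 0] / pairs[:, 1])
        assert median_icer(dist) == pytest.approx(ratios[250])

    def test_point_dominance_label_reported(self):
        df = _frame([40.0, 40.0], [1.0, 1.0], [50.0, 50.0], [0.0, 0.0])
        dist = bootstrap_cea(df, n_reps=50, seed=0)
        assert median_icer(dist) == DOMINANT


class TestCeac:
    def test_dominant_replicates_probability_one(self):
        df = _frame([49.0] * 3, [1.0] * 3, [50.0] * 3, [0.0] * 3)
        dist = bootstrap_cea(df, n_reps=100, seed=0)
        curve = ceac(dist, np.arange(0.0, 501.0, 50.0))
        assert np.all(curve.probabilities == 1.0)

    def test_lambda_zero_is_negative_cost_mass(self):
        rng = np.random.default_rng(3)
        df = _frame(rng.normal(50, 30, 20), rng.normal(0.5, 1, 20),
                    rng.normal(50, 30, 20), rng.normal(0, 1, 20))
        dist = bootstrap_cea(df, n_reps=2000, seed=8)
        curve = ceac(dist, np.array([0.0, 100.0]))
        assert curve.probabilities[0] == pytest.approx(
            (dist.delta_costs < 0).mean())

    def test_hand_counted_fraction(self):
        pairs = [(-30, 1), (-10, -1), (10, 1), (40, 1), (60, 1),
                 (80, 2), (100, 1), (20, -1), (0, 0), (49, 1)]
        df = _frame([1.0, 2.0], [0.1, 0.2], [3.0, 4.0], [0.3, 0.4])
        dist = bootstrap_cea(df, n_reps=2, seed=0)
        dist.replicates = np.array(pairs, dtype=float)
        curve = ceac(dist, np.array([50.0]))
        # NMB = 50*dE - dC > 0 for: (-30,1)=80, (-10,-1)=-40, (10,1)=40,
        # (40,1)=10, (60,1)=-10, (80,2)=20, (100,1)=-50, (20,-1)=-70,
        # (0,0)=0, (49,1)=1  -> 5 of 10
        assert curve.probabilities[0] == pytest.approx(0.5)

    def test_monotone_when_effects_nonnegative_and_limit(self):
        rng = np.random.default_rng(6)
        df = _frame(rng.normal(60, 20, 15), rng.uniform(0.2, 1.5, 15),
                    rng.normal(50, 20, 15), rng.uniform(0.0, 0.1, 15))
        dist = bootstrap_cea(df, n_reps=3000, seed=4)
        # arm effect supports are separated, so every replicate has dE > 0
        assert np.all(dist.delta_effects > 0)
        grid = np.arange(0.0, 2001.0, 10.0)
        curve = ceac(dist, grid)
        assert np.all(np.diff(curve.probabilities) >= 0)
        # lambda -> infinity limit: fraction of replicates with dE > 0
        huge = ceac(dist, np.array([1e9]))
        assert huge.probabilities[0] == pytest.approx(
            (dist.delta_effects > 0).mean(), abs=1e-3)

    def test_invalid_grid_rejected(self):
        df = _frame([1.0, 2.0], [0.1, 0.2], [3.0, 4.0], [0.3, 0.4])
        dist = bootstrap_cea(df, n_reps=5, seed=0)
        with pytest.raises(ValueError):
            ceac(dist, np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            ceac(dist, np.array([-1.0, 5.0]))


class TestPercentileCI:
    def test_constant_values_zero_width(self):
        assert percentile_ci([4.0, 4.0, 4.0]) == (4.0, 4.0)

    def test_linear_interpolation_oracle(self):
        values = np.arange(1.0, 101.0)
        lo, hi = percentile_ci(values, 0.95)
        # manual linear-interpolation quantile on the sorted sample
        def q(p):
            h = (100 - 1) * p
            lo_i = int(np.floor(h))
            frac = h - lo_i
            s = np.sort(values)
            return s[lo_i] + frac * (s[min(lo_i + 1, 99)] - s[lo_i])
        assert lo == pytest.approx(q(0.025))
        assert hi == pytest.approx(q(0.975))

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_levels_rejected(self, level):
        with pytest.raises(ValueError):
            percentile_ci([1.0, 2.0], level)


def test_nmb_summary_consistent_with_ceac():
    rng = np.random.default_rng(10)
    df = _frame(rng.normal(60, 20, 25), rng.normal(0.5, 1, 25),
                rng.normal(50, 20, 25), rng.normal(0, 1, 25))
    dist = bootstrap_cea(df, n_reps=1000, seed=2)
    s = nmb_summary(dist, wtp=100.0)
    curve = ceac(dist, np.array([100.0]))
    assert s["p_cost_effective"] == pytest.approx(curve.probabilities[0])
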