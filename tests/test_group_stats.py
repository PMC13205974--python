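"""Nonparametric framework: Brunner-Munzel, effect sizes, BH-FDR, battery."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from patellakin.exceptions import InvalidArgumentError
from patellakin.group_stats import (
    bh_adjust,
    brunner_munzel,
    omnibus_and_posthoc,
    rank_biserial,
    relative_effect,
    sensitivity_battery,
    sensitivity_grid,
    significance_tier,
)


class TestBrunnerMunzel:
    def test_identical_multisets_symmetric(self):
        x = [1.0, 2.0, 2.0, 3.0]
        res = brunner_munzel(x, list(x))
        assert res.relative_effect == pytest.approx(0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_small_samples_match_permutation_oracle(self, rng):
        """At n <= 8 the t-approximation p tracks a full-enumeration
        permutation p of the relative effect to within 0.05 (the Satterthwaite
        approximation and the discrete permutation law differ by a few percent
        at these sample sizes)."""
        worst = 0.0
        for trial in range(5):
            x = rng.normal(0, 1, 7)
            y = rng.normal(0.6, 1, 8)
            res = brunner_munzel(x, y)
            pooled = np.concatenate([x, y])
            obs = abs(relative_effect(x, y) - 0.5)
            count = total = 0
            for pick in combinations(range(15), 7):
                mask = np.zeros(15, dtype=bool)
                mask[list(pick)] = True
                stat = abs(relative_effect(pooled[mask], pooled[~mask]) - 0.5)
                count += stat >= obs - 1e-12
                total += 1
            worst = max(worst, abs(res.pvalue - count / total))
        assert worst < 0.05

    def test_complete_separation_uses_permutation_fallback(self):
        res = brunner_munzel([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], seed=0)
        assert res.method == "exact-permutation"
        assert 0.0 < res.pvalue <= 0.2  # C(6,3)=20 arrangements, two extreme
        assert res.relative_effect == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 2, 20)
        a = brunner_munzel(x, y)
        b = brunner_munzel(np.exp(x), np.exp(y))
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-12)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)

    def test_type_one_error_calibrated_heteroscedastic(self):
        """Under Normal(0,1) vs Normal(0,3) with n=10/40 the rejection rate at
        alpha=0.05 stays within [0.03, 0.07] over 10 000 null replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 3, 40)
            rejections += brunner_munzel(x, y).pvalue < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_sample_size_validated(self):
        with pytest.raises(InvalidArgumentError):
            brunner_munzel([1.0], [2.0, 3.0])


class TestRankBiserial:
    def test_complete_separation_and_ties(self):
        assert rank_biserial([5, 6], [1, 2]) == -1.0
        assert rank_biserial([1, 2], [1, 2]) == 0.0

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 17)
        assert rank_biserial(x, y) == pytest.approx(-rank_biserial(y, x), abs=1e-12)

    def test_first_group_larger_gives_negative_sign(self, rng):
        x = rng.normal(10, 1, 30)
        y = rng.normal(0, 1, 30)
        assert rank_biserial(x, y) < -0.9


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])
        assert np.allclose(bh_adjust([0.5]), [0.5])

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_dominates_raw_and_preserves_order(self, pvals):
        adjusted = bh_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(adjusted <= 1.0)
        # deterministic and rank-order preserving
        assert np.allclose(bh_adjust(pvals), adjusted, atol=0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh_adjust([0.5, 1.5])


class TestOmnibusAndPosthoc:
    def test_identical_groups_all_ns(self, rng):
        values = np.tile(rng.normal(0, 1, 20), 3)
        labels = np.repeat([1, 2, 3], 20)
        res = omnibus_and_posthoc(values, labels, family="metric")
        assert all(c.significance == "ns" for c in res.comparisons)
        assert res.omnibus_p > 0.05

    def test_group_parameter_separation_significant(self):
        """Groups drawn at the three published amplitude parameters
        (5/36/23) separate with adjusted p < 0.001 in nearly all replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 50
        for _ in range(reps):
            g1 = np.clip(rng.normal(35.11, 6.56, 5), 0, None)
            g2 = np.clip(rng.normal(15.67, 6.59, 36), 0, None)
            g3 = np.clip(rng.normal(2.82, 2.41, 23), 0, None)
            values = np.concatenate([g1, g2, g3])
            labels = np.repeat([1, 2, 3], [5, 36, 23])
            res = omnibus_and_posthoc(values, labels, family="max_lateral", seed=0)
            hits += all(c.p_adjusted < 0.001 for c in res.comparisons)
        assert hits >= 45

    def test_omnibus_p_uniform_under_null(self):
        """Kruskal-Wallis omnibus p is uniform under the null (KS check)."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(2000):
            values = rng.normal(0, 1, 60)
            labels = np.repeat([1, 2, 3], 20)
            pvals.append(float(sps.kruskal(values[:20], values[20:40], values[40:]).pvalue))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_group_flagged_untestable(self, rng):
        values = np.concatenate([[1.0], rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        labels = np.array([1] + [2] * 10 + [3] * 10)
        res = omnibus_and_posthoc(values, labels, family="m")
        by_pair = {c.pair: c for c in res.comparisons}
        assert by_pair[(1, 2)].method == "untestable"
        assert np.isnan(by_pair[(1, 2)].p_raw)
        assert np.isfinite(by_pair[(2, 3)].p_adjusted)

    def test_adjusted_dominates_raw_within_family(self, rng):
        values = np.concatenate([rng.normal(i, 1, 15) for i in range(3)])
        labels = np.repeat([1, 2, 3], 15)
        res = omnibus_and_posthoc(values, labels, family="m")
        for c in res.comparisons:
            assert c.p_adjusted >= c.p_raw - 1e-15


class TestSignificanceTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "ns"), (float("nan"), "na")],
    )
    def test_tiers(self, p, tier):
        assert significance_tier(p) == tier


class TestSensitivityBattery:
    def test_huge_effect_consistent_significant(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)
        pvals, verdict = sensitivity_battery(x, y, seed=0)
        assert len(pvals) == 8
        assert all(p < 0.001 for p in pvals.values())
        assert verdict == "consistent-significant"

    def test_identical_samples_nothing_significant(self, rng):
        x = rng.normal(0, 1, 25)
        pvals, verdict = sensitivity_battery(x, x.copy(), seed=0)
        finite = [p for p in pvals.values() if np.isfinite(p)]
        assert all(p > 0.05 for p in finite)
        assert verdict != "consistent-significant"

    def test_marginal_effect_yields_inconsistent_verdict(self):
        """Near power ~0.5 the eight tests disagree across the grid."""
        r = np.random.default_rng(0)
        x = r.normal(0, 1, 25)
        y = r.normal(0.45, 1, 25)
        pvals, verdict = sensitivity_battery(x, y, seed=0)
        assert verdict == "inconsistent"

    def test_grid_shape_and_range(self, rng):
        import pandas as pd

        data = pd.DataFrame(
            {
                "a": np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 12)]),
                "b": np.concatenate([rng.normal(5, 1, 10), rng.normal(5, 1, 12)]),
            }
        )
        labels = np.array([1] * 10 + [2] * 12)
        grid = sensitivity_grid(data, labels, (1, 2), seed=0)
        assert grid.shape == (2, 8)
        vals = grid.to_numpy()
        assert np.all((vals[np.isfinite(vals)] >= 0) & (vals[np.isfinite(vals)] <= 1))
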