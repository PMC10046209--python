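"""ANOVA, paired t, Bonferroni, and the analysis report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import figground as fg
from figground.stats import MultipleComparisonPolicy


class TestOneWayAnova:
    def test_identical_groups_give_zero_f_unit_p(self):
        res = fg.one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0
        assert res.p == 1.0
        assert (res.df_between, res.df_within) == (2, 6)

    def test_constant_equal_groups_define_f_as_zero(self):
        res = fg.one_way_anova([[5, 5], [5, 5]])
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, 9) for loc in (0.0, 0.5, 1.2)]
        ours = fg.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert ours.F == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_single_value_groups_rejected(self):
        with pytest.raises(ValueError):
            fg.one_way_anova([[1.0], [2.0, 3.0]])


class TestAnovaFromSummary:
    def test_peripheral_static_summaries_give_f_41_6(self):
        res = fg.one_way_anova_from_summary([39, 13, 12], [10, 6, 4], 9)
        assert res.F == pytest.approx(41.63, abs=0.05)
        assert (res.df_between, res.df_within) == (2, 24)
        assert res.p < 1e-6

    def test_equal_means_give_zero_f(self):
        res = fg.one_way_anova_from_summary([10, 10, 10], [2, 3, 4], 9)
        assert res.F == 0.0

    def test_large_shift_gives_tiny_p(self):
        res = fg.one_way_anova_from_summary([10, 10, 110], [10, 10, 10], 9)
        assert res.p < 1e-6

    def test_consistent_with_raw_data_anova(self):
        """Exact agreement when fed the summaries of actual samples."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 2.0, 9) for m in (3.0, 4.0, 6.0)]
        raw = fg.one_way_anova(groups)
        summ = fg.one_way_anova_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups], 9
        )
        assert summ.F == pytest.approx(raw.F, rel=1e-12)
        assert summ.p == pytest.approx(raw.p, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fg.one_way_anova_from_summary([1, 2], [1, 1], 1)


class TestPairedT:
    def test_identical_vectors_give_t0_p1(self):
        res = fg.paired_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and res.df == 2

    def test_hand_arithmetic_differences_1_2_3(self):
        res = fg.paired_t([2, 4, 6], [1, 2, 3])
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-12)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert fg.paired_t(a, b).t == -fg.paired_t(b, a).t

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1.0, 1.0, 9), rng.normal(0.0, 1.0, 9)
        ours = fg.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_nonzero_mean_is_degenerate(self):
        res = fg.paired_t([2, 2, 2], [1, 1, 1])
        assert res.degenerate and res.p == 0.0 and np.isinf(res.t)

    def test_type_one_error_near_nominal_alpha(self):
        """Null differences at n=9 reject at ~ the adjusted alpha."""
        rng = np.random.default_rng(17)
        alpha = 0.05 / 3
        n_rep, n = 4000, 9
        d = rng.normal(size=(n_rep, n))
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        rate = (p < alpha).mean()
        assert rate == pytest.approx(alpha, abs=0.006)
        # spot-check the vectorized nulls against our implementation
        res = fg.paired_t(d[0], np.zeros(n))
        assert res.t == pytest.approx(t[0], rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("family,m,expected", [
        (0.05, 3, 0.05 / 3), (0.05, 1, 0.05), (0.01, 2, 0.005),
    ])
    def test_adjusted_alpha(self, family, m, expected):
        policy = MultipleComparisonPolicy(family_alpha=family, m=m)
        assert fg.bonferroni(policy) == pytest.approx(expected)

    def test_three_comparisons_print_as_0_017(self):
        assert f"{fg.bonferroni(MultipleComparisonPolicy()):.3f}" == "0.017"

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            MultipleComparisonPolicy(m=0)


class TestReport:
    def _agg(self, values_by_cond, n=9):
        rows = []
        for (task, ecc), vals in values_by_cond.items():
            for i, v in enumerate(vals):
                rows.append({"observer_id": i, "task": task,
                             "eccentricity": ecc, "value": v})
        return pd.DataFrame(rows)

    def test_single_condition_yields_summary_only(self):
        agg = self._agg({("static", 0.0): [30.0, 35.0, 40.0]})
        rep = fg.report(agg)
        assert rep.anova.empty and rep.ttests.empty
        assert len(rep.summary) == 1

    def test_constant_equal_conditions_flag_nothing(self):
        agg = self._agg({("static", 0.0): [30.0] * 9, ("dynamic", 0.0): [30.0] * 9})
        rep = fg.report(agg)
        assert not rep.ttests["significant"].any()

    def test_fewer_than_two_observers_rejected(self):
        agg = self._agg({("static", 0.0): [30.0]})
        with pytest.raises(ValueError):
            fg.report(agg)

    def test_calibrated_simulation_flags_walker_above_static(self):
        agg = fg.simulate_experiment(seed=12)
        rep = fg.report(agg)
        row = rep.ttests[(rep.ttests["a"] == "walker@0") & (rep.ttests["b"] == "static@0")]
        if row.empty:
            row = rep.ttests[(rep.ttests["a"] == "static@0") & (rep.ttests["b"] == "walker@0")]
        assert bool(row["significant"].iloc[0])

    def test_report_text_and_csv_outputs(self, tmp_path):
        agg = self._agg({("static", 0.0): list(np.linspace(30, 50, 9)),
                         ("walker", 0.0): list(np.linspace(80, 110, 9))})
        rep = fg.report(agg)
        text = rep.to_text()
        assert "ANOVA" in text and "paired t" in text
        rep.write_csv(tmp_path)
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "ttests.csv").exists()


class TestPatternChecks:
    def test_hand_built_pattern_table(self):
        rng = np.random.default_rng(0)
        conds = {}
        for task, means in (("walker", (94, 24, 13)), ("dynamic", (50, 18, 12)),
                            ("static", (45, 13, 12))):
            for ecc, m in zip((0.0, 15.0, 30.0), means):
                conds[(task, ecc)] = m + rng.normal(0, 2, 9)
        # strong separation, tiny noise: everything but static-vs-dynamic significant
        rows = []
        for (task, ecc), vals in conds.items():
            for i, v in enumerate(vals):
                rows.append({"observer_id": i, "task": task,
                             "eccentricity": ecc, "value": v})
        agg = pd.DataFrame(rows)
        checks = fg.pattern_checks(agg)
        assert checks["walker_gt_static"]
        assert checks["walker_gt_dynamic"]
        assert checks["central_gt_periphery"]

    def test_replication_harness_component_rates(self):
        out = fg.replication_rate(10, seed=3)
        assert out.checks.shape[0] == 10
        assert out.per_check_rates["walker_gt_static"] >= 0.8
        assert out.per_check_rates["central_gt_periphery"] >= 0.8
        assert 0.0 <= out.rate <= 1.0
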