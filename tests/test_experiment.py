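"""Design orchestration, aggregation and summaries."""

import numpy as np
import pandas as pd
import pytest

import figground as fg
from figground.experiment import Condition, best_size_design, full_design
from figground.observers import CohortSpec

from conftest import cutoff_respond_fn


class TestDesignGrids:
    def test_full_design_covers_every_table_cell(self):
        design = full_design()
        assert len(design) == 3 * (3 + 3 + 4)
        assert all(isinstance(c, Condition) for c in design)

    def test_best_size_design_has_one_cell_per_condition(self):
        design = best_size_design()
        assert len(design) == 9
        assert {(c.task, c.eccentricity) for c in design} == set(fg.DEFAULT_GROUP_STATS)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            Condition("static", 0.0, 40.0)


class TestRunCondition:
    def test_cutoff_observer_yields_three_identical_thresholds(self):
        cond = Condition("static", 0.0, 4.0)
        out = fg.run_condition(cutoff_respond_fn(47), cond, seed=1)
        assert out == [47.5, 47.5, 47.5]

    def test_parametric_observer_reproducible_given_seed(self):
        obs = fg.PsychometricObserver(T=40, beta=4)
        cond = Condition("walker", 0.0, 16.0)
        a = fg.run_condition(fg.make_respond_fn(obs), cond, seed=9)
        b = fg.run_condition(fg.make_respond_fn(obs), cond, seed=9)
        assert a == b
        assert all(t is not None and t > 0 for t in a)


class TestRunDesign:
    def test_row_count_9_observers_1_task_3_ecc_3_repeats(self):
        cohort = fg.sample_cohort(seed=2)
        design = best_size_design(tasks=("static",))
        table = fg.run_design(cohort, design, seed=3)
        assert len(table) == 9 * 3 * 3
        assert set(table["task"]) == {"static"}

    def test_same_master_seed_gives_identical_table(self):
        cohort = fg.sample_cohort(seed=2)
        design = best_size_design(tasks=("dynamic",))
        a = fg.run_design(cohort, design, seed=7)
        b = fg.run_design(cohort, design, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_central_threshold_means_track_cohort_calibration(self):
        """Simulated group means sit near the calibration targets.

        The staircase measures the 84.1 %-correct point, which for a
        guessing observer lies ~0.9*beta below T, so the comparison
        allows that offset plus sampling error.
        """
        central = {c: v for c, v in fg.DEFAULT_GROUP_STATS.items() if c[1] == 0.0}
        spec = CohortSpec(conditions=central)
        design = [Condition(t, 0.0, fg.BEST_SIZES[(t, 0.0)]) for t, _ in central]
        sums = {c: [] for c in central}
        for s in np.random.SeedSequence(31).spawn(8):
            a, b = s.spawn(2)
            table = fg.run_design(fg.sample_cohort(spec, seed=a), design, seed=b)
            for (task, ecc), _ in central.items():
                sums[(task, ecc)].append(
                    table[table["task"] == task]["threshold"].mean())
        bias = 0.9 * spec.beta
        for cond, (mean, sd) in central.items():
            grand = np.mean(sums[cond])
            assert abs(grand - (mean - bias)) < 2 * sd / np.sqrt(9), cond

    def test_walker_central_exceeds_peripheral_thresholds(self):
        spec = CohortSpec(conditions={c: v for c, v in fg.DEFAULT_GROUP_STATS.items()
                                      if c[0] == "walker"})
        design = best_size_design(tasks=("walker",))
        table = fg.run_design(fg.sample_cohort(spec, seed=4), design, seed=5)
        means = table.groupby("eccentricity")["threshold"].mean()
        assert means[0.0] > means[15.0] > means[30.0]


class TestAggregation:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["observer_id", "task", "eccentricity",
                                           "size", "repeat", "threshold", "ok"])

    def test_single_size_aggregate_is_mean_of_repeats(self):
        t = self._table([(0, "static", 0.0, 4.0, r, v, True)
                         for r, v in enumerate([30.0, 40.0, 35.0])])
        agg = fg.best_size_aggregate(t)
        assert agg["value"].iloc[0] == pytest.approx(35.0)

    def test_best_size_takes_max_over_size_means(self):
        rows = []
        for size, v in [(4.0, 30.0), (8.0, 39.0), (16.0, 35.0)]:
            rows += [(0, "static", 0.0, size, r, v, True) for r in range(3)]
        agg = fg.best_size_aggregate(self._table(rows))
        assert agg["value"].iloc[0] == 39.0

    def test_adding_a_size_never_decreases_the_aggregate(self):
        rows = [(0, "static", 0.0, 4.0, r, 30.0, True) for r in range(3)]
        base = fg.best_size_aggregate(self._table(rows))["value"].iloc[0]
        rows += [(0, "static", 0.0, 8.0, r, 20.0, True) for r in range(3)]
        more = fg.best_size_aggregate(self._table(rows))["value"].iloc[0]
        assert more >= base

    def test_median_combination_available(self):
        t = self._table([(0, "static", 0.0, 4.0, r, v, True)
                         for r, v in enumerate([10.0, 20.0, 90.0])])
        assert fg.best_size_aggregate(t, combine="median")["value"].iloc[0] == 20.0

    def test_failed_staircases_are_excluded_not_imputed(self):
        t = self._table([
            (0, "static", 0.0, 4.0, 0, 30.0, True),
            (0, "static", 0.0, 4.0, 1, np.nan, False),
        ])
        agg = fg.best_size_aggregate(t)
        assert agg["value"].iloc[0] == 30.0


class TestSummarize:
    def test_constant_values_have_zero_sd_and_se(self):
        agg = pd.DataFrame({
            "observer_id": range(4), "task": "static",
            "eccentricity": 0.0, "value": 39.0,
        })
        s = fg.summarize(agg)
        assert s["sd"].iloc[0] == 0.0 and s["se"].iloc[0] == 0.0

    def test_two_observer_hand_arithmetic(self):
        agg = pd.DataFrame({
            "observer_id": [0, 1], "task": "static",
            "eccentricity": 0.0, "value": [10.0, 20.0],
        })
        s = fg.summarize(agg)
        assert s["mean"].iloc[0] == 15.0
        assert s["sd"].iloc[0] == pytest.approx(7.0711, abs=1e-3)
        assert s["se"].iloc[0] == pytest.approx(5.0)
        assert s["n"].iloc[0] == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fg.summarize(pd.DataFrame(columns=["task", "eccentricity", "value"]))


class TestMakeTrialClip:
    @pytest.mark.parametrize("task,n_figure", [
        ("static", 12), ("dynamic", 12), ("walker", 13),
    ])
    def test_trial_clip_counts_and_placement(self, task, n_figure, central_layout):
        rng = np.random.default_rng(0)
        clip = fg.make_trial_clip(task, "grouped", 25, central_layout, rng)
        assert int(clip.figure_mask.sum()) == n_figure
        assert clip.noise_count == 25
        assert clip.size == pytest.approx(16.0)

    def test_peripheral_trial_clip_is_magnified_and_shifted(self):
        rng = np.random.default_rng(1)
        clip = fg.make_trial_clip("walker", "grouped", 0, fg.Layout(30.0, 40.0), rng)
        assert clip.center[0] == pytest.approx(30.0)
        assert clip.size == pytest.approx(40.0)


class TestPeripheralJitter:
    def test_no_jitter_at_fixation(self, walker_clip):
        j = fg.PeripheralJitter(coeff=0.05)
        out = j.apply(walker_clip, np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, walker_clip.positions)

    def test_jitter_scales_with_eccentricity(self, walker_clip):
        j = fg.PeripheralJitter(coeff=0.05)
        rng = np.random.default_rng(0)
        far = fg.scale_to_layout(walker_clip, fg.Layout(30.0, 16.0))
        near = fg.scale_to_layout(walker_clip, fg.Layout(15.0, 16.0))
        d_far = np.std(j.apply(far, rng).positions - far.positions)
        d_near = np.std(j.apply(near, rng).positions - near.positions)
        assert d_far == pytest.approx(0.05 * 30.0, rel=0.05)
        assert d_near == pytest.approx(0.05 * 15.0, rel=0.05)
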