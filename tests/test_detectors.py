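"""Mechanistic detectors: scores, invariances, calibration."""

import numpy as np
import pytest

import figground as fg
from figground.detectors import DetectorParams, _equal_error_criterion


def translate_field(clip, dx, dy):
    out = clip.copy()
    out.positions = clip.positions + np.array([dx, dy])
    x0, y0, x1, y1 = clip.bbox
    out.bbox = (x0 + dx, y0 + dy, x1 + dx, y1 + dy)
    return out


def permute_dots(clip, seed=0):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(clip.n_dots)
    out = clip.copy()
    out.positions = clip.positions[:, perm]
    out.diameters = clip.diameters[perm]
    out.provenance = clip.provenance[perm]
    return out


class TestColumnScore:
    def test_clean_grouped_clip_scores_near_one(self):
        for k in (3, 4):
            clip = fg.generate_static_grouping(fg.GroupingParams(n_columns=k))
            assert fg.column_score(clip) >= 0.95

    def test_clean_scrambled_clip_scores_below_criterion(self):
        for seed in range(5):
            clip = fg.generate_static_grouping(truth="scrambled", seed=seed)
            assert fg.column_score(clip) < fg.DEFAULT_STATIC_CRITERION

    def test_fewer_than_12_dots_is_an_error(self, walker_clip):
        clip = walker_clip.copy()
        clip.positions = clip.positions[:, :5]
        clip.diameters = clip.diameters[:5]
        clip.provenance = clip.provenance[:5]
        with pytest.raises(ValueError, match="12"):
            fg.column_score(clip)

    def test_noise_erodes_the_grouped_scrambled_separation_monotonically(self):
        """Clean grouped clips score highest; the class gap shrinks with N.

        The raw grouped score itself is not monotone in N: moderate
        noise perturbs the fitted abscissae (score dips) while dense
        noise supplies column-like dots everywhere (score saturates
        towards 1 for both classes -- the chance floor).  What decays
        monotonically is the grouped-minus-scrambled separation.
        """
        levels = [0, 120, 400]
        g_means, s_means = [], []
        for n in levels:
            g, s = [], []
            for seed in range(15):
                grouped = fg.embed_noise(fg.generate_static_grouping(),
                                         fg.NoiseParams(count=n), seed=seed)
                scram = fg.embed_noise(
                    fg.generate_static_grouping(truth="scrambled", seed=seed + 100),
                    fg.NoiseParams(count=n), seed=seed)
                g.append(fg.column_score(grouped))
                s.append(fg.column_score(scram))
            g_means.append(np.mean(g))
            s_means.append(np.mean(s))
        assert g_means[0] >= max(g_means)  # clean grouped clips score highest
        assert s_means[0] < s_means[1] < s_means[2]
        gaps = [g - s for g, s in zip(g_means, s_means)]
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_invariant_to_dot_order_and_rigid_translation(self):
        clip = fg.embed_noise(fg.generate_static_grouping(truth="scrambled", seed=3),
                              fg.NoiseParams(count=30), seed=4)
        base = fg.column_score(clip)
        assert fg.column_score(permute_dots(clip)) == pytest.approx(base, abs=1e-12)
        assert fg.column_score(translate_field(clip, 7.0, -3.0)) == pytest.approx(base, abs=1e-9)


class TestCoherenceScore:
    def test_grouped_clip_without_noise_scores_one(self):
        clip = fg.generate_dynamic_grouping()
        assert fg.coherence_score(clip) == 1.0

    def test_scrambled_clip_scores_below_half_on_average(self):
        vals = [
            fg.coherence_score(fg.generate_dynamic_grouping(truth="scrambled", seed=s))
            for s in range(20)
        ]
        assert np.mean(vals) < 0.5

    def test_static_clip_rejected(self):
        clip = fg.generate_static_grouping()
        with pytest.raises(ValueError):
            fg.coherence_score(clip)

    def test_invariant_to_dot_order_and_rigid_translation(self):
        clip = fg.embed_noise(fg.generate_dynamic_grouping(truth="scrambled", seed=1),
                              fg.NoiseParams(count=40), seed=2)
        base = fg.coherence_score(clip)
        assert fg.coherence_score(permute_dots(clip)) == pytest.approx(base, abs=1e-12)
        assert fg.coherence_score(translate_field(clip, -4.0, 2.0)) == pytest.approx(base, abs=1e-9)

    def test_scrambled_score_rises_with_noise(self):
        means = []
        for n in (0, 500):
            vals = [
                fg.coherence_score(fg.embed_noise(
                    fg.generate_dynamic_grouping(truth="scrambled", seed=s),
                    fg.NoiseParams(count=n), seed=s + 50))
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestWalkerScore:
    def test_self_match_residual_is_tiny(self, walker_clip, template_bank):
        assert fg.walker_score(walker_clip, template_bank=template_bank) < 0.02

    def test_all_five_directions_match_their_template(self, template_bank):
        for d in fg.DIRECTIONS:
            clip = fg.generate_walker(fg.WalkerParams(direction=d))
            assert fg.walker_score(clip, template_bank=template_bank) < 0.02

    def test_scrambled_scores_strictly_worse(self, walker_clip, template_bank):
        for seed in range(5):
            scr = fg.scramble_walker(walker_clip, seed=seed)
            assert (fg.walker_score(scr, template_bank=template_bank)
                    > fg.walker_score(walker_clip, template_bank=template_bank))

    def test_noise_free_separation_is_perfect(self, walker_clip, template_bank):
        grouped = [fg.walker_score(
            fg.generate_walker(fg.WalkerParams(direction=d, phase0=2 * np.pi * k / 30)),
            template_bank=template_bank)
            for d in (90.0, 0.0) for k in (0, 7, 15)]
        scrambled = [fg.walker_score(fg.scramble_walker(walker_clip, seed=s),
                                     template_bank=template_bank) for s in range(6)]
        assert max(grouped) < min(scrambled)

    def test_invariant_to_dot_order_and_rigid_translation(self, walker_clip, template_bank):
        clip = fg.embed_noise(walker_clip, fg.NoiseParams(count=30), seed=1)
        base = fg.walker_score(clip, template_bank=template_bank)
        assert fg.walker_score(permute_dots(clip), template_bank=template_bank) == \
            pytest.approx(base, abs=1e-12)
        assert fg.walker_score(translate_field(clip, 5.0, 1.0), template_bank=template_bank) == \
            pytest.approx(base, abs=1e-9)

    def test_empty_template_bank_rejected(self, walker_clip):
        with pytest.raises(ValueError, match="template"):
            fg.walker_score(walker_clip, template_bank=np.empty((0, 30, 13, 2)))

    def test_non_walker_clip_rejected(self, template_bank):
        clip = fg.generate_dynamic_grouping()
        with pytest.raises(ValueError):
            fg.walker_score(clip, template_bank=template_bank)


class TestCalibrationAndResponse:
    def test_uncalibrated_detector_raises_state_error(self, walker_clip, template_bank):
        det = fg.Detector(task="walker", params=DetectorParams(),
                          template_bank=template_bank)
        with pytest.raises(RuntimeError, match="calibrat"):
            det.classify(walker_clip)

    def test_equal_error_criterion_sits_in_the_gap(self):
        c = _equal_error_criterion(np.array([0.1, 0.2]), np.array([0.8, 0.9]),
                                   grouped_is_low=True)
        assert 0.2 < c < 0.8

    def test_equal_error_criterion_balances_overlap(self):
        g = np.array([0.1, 0.2, 0.4, 0.6])
        s = np.array([0.3, 0.5, 0.7, 0.8])
        c = _equal_error_criterion(g, s, grouped_is_low=True)
        hit = np.mean(g < c)
        cr = np.mean(s >= c)
        assert abs(hit - cr) <= 0.25

    def test_calibrated_detectors_are_perfect_on_clean_clips(self, small_detectors,
                                                             central_layout):
        dets, cfg = small_detectors
        rng = np.random.default_rng(55)
        for task, det in dets.items():
            for truth in ("grouped", "scrambled"):
                for _ in range(10):
                    clip = fg.make_trial_clip(task, truth, 0, central_layout, rng, cfg)
                    assert det.classify(clip) == truth, (task, truth)

    def test_heavy_noise_drives_accuracy_to_chance(self, small_detectors, central_layout):
        dets, cfg = small_detectors
        rng = np.random.default_rng(56)
        for task, det in dets.items():
            hits = 0
            trials = 16
            for i in range(trials):
                truth = "grouped" if i % 2 == 0 else "scrambled"
                clip = fg.make_trial_clip(task, truth, 2000, central_layout, rng, cfg)
                hits += det.classify(clip) == truth
            assert 0.2 <= hits / trials <= 0.8, task
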