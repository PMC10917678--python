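"""Generator contracts: determinism, ground-truth closure, planted effects."""

import numpy as np
import pytest

from pupreact.reactivity import apply_trial_exclusion, classify_habituation
from pupreact.stats import compare_habituation_fractions
from pupreact.synthetic import (ArenaSpec, CohortSpec, StackSpec, StartleSpec,
                                evoked_trace, generate_arena_trajectory,
                                generate_cohort, generate_confocal_stack,
                                generate_puff_session, generate_puff_video,
                                generate_startle_table)


class TestDeterminism:
    def test_puff_session_bit_identical(self):
        spec = CohortSpec(seed=7)
        a, ta = generate_puff_session(spec, "mutant", 3)
        b, tb = generate_puff_session(spec, "mutant", 3)
        assert [t.peak for t in a.repeated_trials] == \
            [t.peak for t in b.repeated_trials]
        assert ta == tb

    def test_session_independent_of_generation_order(self):
        spec = CohortSpec(seed=7)
        generate_puff_session(spec, "control", 0)
        a, _ = generate_puff_session(spec, "mutant", 3)
        b, _ = generate_puff_session(spec, "mutant", 3)
        assert [t.peak for t in a.ramp_trials] == [t.peak for t in b.ramp_trials]

    def test_video_bit_identical(self):
        spec = CohortSpec(seed=11)
        s1, t1, _ = generate_puff_video(spec, "control", 0, amplitude=5.0)
        s2, t2, _ = generate_puff_video(spec, "control", 0, amplitude=5.0)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.values, t2.values)

    def test_stack_bit_identical(self):
        spec = StackSpec(seed=4, n_terminals=10, shape=(4, 96, 96))
        a, _ = generate_confocal_stack(spec)
        b, _ = generate_confocal_stack(spec)
        assert np.array_equal(a.channels["receptor"], b.channels["receptor"])

    def test_arena_bit_identical(self):
        spec = ArenaSpec(seed=5, duration=30)
        a, _ = generate_arena_trajectory(spec)
        b, _ = generate_arena_trajectory(spec)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestPuffSession:
    def test_closed_form_decay_product(self):
        # fully habituating cohort, 10% decay, no noise:
        # trial-10 / trial-1 amplitude = 0.9^9
        spec = CohortSpec(seed=1, habituation_prob=1.0, habituation_decay=0.1,
                          amplitude_noise_sd=0.0, baseline_noise_sd=0.0)
        s, truth = generate_puff_session(spec, "control", 0)
        ratio = s.repeated_trials[9].peak / s.repeated_trials[0].peak
        assert ratio == pytest.approx(0.9 ** 9, abs=1e-12)
        assert truth["habituating"] is True

    def test_unity_multiplier_matches_distributions(self):
        spec = CohortSpec(seed=2, genotype_multiplier=1.0,
                          habituation_prob=0.0, n_control=250, n_mutant=250)
        sessions, _ = generate_cohort(spec)
        means = {"control": [], "mutant": []}
        for s in sessions:
            means[s.genotype].append(np.mean([t.peak for t in s.repeated_trials]))
        diff = abs(np.mean(means["control"]) - np.mean(means["mutant"]))
        pooled_se = np.sqrt(np.var(means["control"]) / 250
                            + np.var(means["mutant"]) / 250)
        assert diff < 4 * pooled_se

    def test_ground_truth_closure(self):
        """Every generated trial appears once in the truth record."""
        spec = CohortSpec(seed=3)
        s, truth = generate_puff_session(spec, "control", 1)
        assert len(truth["ramp_amplitudes"]) == len(s.ramp_trials)
        assert len(truth["repeated_amplitudes"]) == len(s.repeated_trials)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            CohortSpec(evoked_gain_control=float("nan"))
        with pytest.raises(ValueError, match="increasing"):
            CohortSpec(intensity_levels=(0.5, 0.25))
        with pytest.raises(ValueError, match="habituation_prob"):
            CohortSpec(habituation_prob=1.5)


class TestPuffVideo:
    def test_zero_amplitude_frames_identical_up_to_noise(self):
        spec = CohortSpec(seed=6)
        stack, _, _ = generate_puff_video(spec, "control", 0, amplitude=0.0,
                                          pixel_noise_sd=0.0)
        assert np.allclose(stack.frames, stack.frames[0])

    def test_subpixel_ramp_ground_truth_peak(self):
        tr = evoked_trace(2.5, 120.0, 15, 60)
        assert tr.values.max() == pytest.approx(2.5)

    def test_square_pulse_centroid_moves_exactly(self):
        """Noiseless render: blob centroid shifts by the planted displacement."""
        spec = CohortSpec(seed=8)
        stack, trace, info = generate_puff_video(spec, "control", 0,
                                                 amplitude=10.0,
                                                 pixel_noise_sd=0.0)
        k = int(np.argmax(trace.values))
        def centroid_x(img):
            w = img.sum()
            return (img * np.arange(img.shape[1])[None, :]).sum() / w
        shift = centroid_x(stack.frames[k]) - centroid_x(stack.frames[0])
        assert shift == pytest.approx(trace.values[k], abs=0.05)

    def test_too_small_frame_rejected(self):
        spec = CohortSpec(seed=6)
        with pytest.raises(ValueError, match="too small"):
            generate_puff_video(spec, "control", 0, amplitude=100.0,
                                shape=(64, 96))


class TestStartle:
    def test_all_responses_nonnegative(self):
        spec = StartleSpec(seed=9, lognormal_sd=0.6)
        sess, _ = generate_startle_table(spec, "mutant")
        assert all(t.response >= 0 for t in sess.trials)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError, match="ppi_effect"):
            StartleSpec(ppi_effect=1.5)

    def test_block_structure_present(self):
        sess, _ = generate_startle_table(StartleSpec(seed=1), "control")
        blocks = {t.block for t in sess.trials}
        assert blocks == {"pulse_alone", "prepulse_alone", "mixed"}


class TestStack:
    def test_zero_fraction_no_hosted_puncta(self):
        spec = StackSpec(seed=2, coloc_fraction=0.0,
                         background_puncta_density=0.0, n_terminals=15,
                         shape=(4, 128, 128), poisson_scale=0.0,
                         gaussian_sd=0.0)
        stack, labels = generate_confocal_stack(spec)
        assert labels["n_colocalized"] == 0
        assert len(labels["puncta"]) == 0
        assert stack.channels["receptor"].max() == 0.0

    def test_full_fraction_all_terminals_colocalized(self):
        spec = StackSpec(seed=3, coloc_fraction=1.0, n_terminals=20,
                         shape=(6, 192, 192))
        _, labels = generate_confocal_stack(spec)
        assert labels["n_colocalized"] == 20
        assert all(t["colocalized"] for t in labels["terminals"])

    def test_round_to_count_draw(self):
        spec = StackSpec(seed=4, coloc_fraction=0.4, n_terminals=50)
        _, labels = generate_confocal_stack(spec)
        assert labels["n_colocalized"] == 20
        hosted = [p for p in labels["puncta"] if p["host"] > 0]
        assert len(hosted) == 20

    def test_unplaceable_request_errors(self):
        spec = StackSpec(seed=5, n_terminals=500, shape=(3, 64, 64),
                         max_retries=20)
        with pytest.raises(RuntimeError, match="place"):
            generate_confocal_stack(spec)

    def test_z_step_bounds_enforced(self):
        with pytest.raises(ValueError, match="z voxel"):
            StackSpec(voxel_size=(0.3, 0.1, 0.1))


class TestNullCohorts:
    def test_null_rejection_rate_at_most_nominal(self):
        """Exact one-sided Fisher on null cohorts rejects at <= alpha
        (+ Monte-Carlo slack); conservatism is expected."""
        rej = 0
        n = 300
        for c in range(n):
            spec = CohortSpec(seed=50_000 + c,
                              habituation_prob={"control": 0.6, "mutant": 0.6})
            sessions, _ = generate_cohort(spec)
            res = [classify_habituation(apply_trial_exclusion(s))
                   for s in sessions]
            _, p = compare_habituation_fractions(res, "control", "mutant")
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert rej / n <= 0.05 + 2 * se
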