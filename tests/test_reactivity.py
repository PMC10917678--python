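"""Air-puff reactivity endpoints: exclusions, means, habituation, opto."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupreact.reactivity import (OptoSession, PuffSession, PuffTrial,
                                 apply_trial_exclusion, classify_habituation,
                                 genotype_difference_sign,
                                 habituation_inclusion,
                                 habituation_sensitivity, intensity_response,
                                 repeated_mean, score_opto_session)
from pupreact.synthetic import CohortSpec, generate_cohort, generate_puff_session

INTENSITIES = (0.10, 0.25, 0.50, 0.75, 1.0)


def make_session(repeated_peaks, ramp_peaks=None, baselines=None,
                 first_baseline=0.0, **kw):
    ramp_peaks = ramp_peaks if ramp_peaks is not None else [1, 2, 3, 4, 5]
    n = len(repeated_peaks)
    baselines = baselines if baselines is not None else [0.0] * n
    baselines = list(baselines)
    baselines[0] = first_baseline if first_baseline else baselines[0]
    ramp = [PuffTrial(intensity=i, peak=p, baseline_movement=0.0)
            for i, p in zip(INTENSITIES, ramp_peaks)]
    rep = [PuffTrial(intensity=1.0, peak=p, baseline_movement=b)
           for p, b in zip(repeated_peaks, baselines)]
    return PuffSession(animal_id="a", genotype="control",
                       ramp_trials=ramp, repeated_trials=rep, **kw)


class TestTrialExclusion:
    def test_quiet_baselines_keep_all_trials(self):
        s = apply_trial_exclusion(make_session([10.0] * 10))
        assert not any(t.excluded for t in s.ramp_trials + s.repeated_trials)

    def test_trial_above_threshold_excluded(self):
        s = make_session([10.0] * 10)
        s.repeated_trials[4].baseline_movement = 2 * s.movement_threshold
        out = apply_trial_exclusion(s)
        flags = [t.excluded for t in out.repeated_trials]
        assert flags == [False] * 4 + [True] + [False] * 5
        assert out.repeated_trials[4].exclusion_reason == "baseline_movement"

    def test_threshold_is_strict(self):
        s = make_session([10.0] * 10)
        s.repeated_trials[0].baseline_movement = s.movement_threshold
        out = apply_trial_exclusion(s)
        assert not out.repeated_trials[0].excluded

    def test_planted_contaminated_trials_recovered(self):
        spec = CohortSpec(seed=21, contamination_prob=0.25)
        for idx in range(6):
            sess, truth = generate_puff_session(spec, "mutant", idx)
            out = apply_trial_exclusion(sess)
            trials = out.ramp_trials + out.repeated_trials
            found = [k for k, t in enumerate(trials) if t.excluded]
            assert found == truth["contaminated_trials"]


class TestIntensityResponse:
    def test_full_ramp_reported(self):
        table = intensity_response(make_session([10.0] * 10))
        assert len(table) == 5
        assert table["peak_px"].notna().all()

    def test_excluded_intensity_reported_missing(self):
        s = make_session([10.0] * 10)
        s.ramp_trials[2].excluded = True
        s.ramp_trials[2].exclusion_reason = "baseline_movement"
        table = intensity_response(s)
        assert len(table) == 5
        assert table["peak_px"].isna().sum() == 1
        assert np.isnan(table.loc[table.intensity_psi == 0.5, "peak_px"]).all()

    def test_noiseless_generator_peaks_linear_in_intensity(self):
        spec = CohortSpec(seed=3, amplitude_noise_sd=0.0, baseline_noise_sd=0.0,
                          habituation_prob=0.0)
        sess, truth = generate_puff_session(spec, "control", 0)
        table = intensity_response(sess)
        expected = truth["gain"] * table["intensity_psi"].to_numpy()
        assert np.allclose(table["peak_px"].to_numpy(), expected)


class TestRepeatedMean:
    def test_equal_trials(self):
        assert repeated_mean(make_session([7.0] * 10)) == 7.0

    def test_excluded_trial_dropped_from_mean(self):
        s = make_session([10.0] * 9 + [0.0])
        s.repeated_trials[9].excluded = True
        s.repeated_trials[9].exclusion_reason = "baseline_movement"
        assert repeated_mean(s) == 10.0

    def test_all_excluded_raises(self):
        s = make_session([1.0] * 10)
        for t in s.repeated_trials:
            t.excluded, t.exclusion_reason = True, "baseline_movement"
        with pytest.raises(ValueError, match="excluded"):
            repeated_mean(s)


class TestInclusion:
    def test_boundary_not_included(self):
        # peak must STRICTLY exceed (1 + 0.20) x baseline
        s = make_session([12.0] + [10.0] * 9, first_baseline=10.0)
        assert habituation_inclusion(s) is False

    def test_just_above_boundary_included(self):
        s = make_session([12.1] + [10.0] * 9, first_baseline=10.0)
        assert habituation_inclusion(s) is True

    def test_zero_baseline_any_positive_peak_included(self):
        s = make_session([0.5] + [10.0] * 9)
        assert habituation_inclusion(s) is True

    def test_literal_rule_differs(self):
        s = make_session([5.0] + [10.0] * 9, first_baseline=10.0)
        assert habituation_inclusion(s, rule="margin") is False
        assert habituation_inclusion(s, rule="literal") is True

    def test_excluded_first_trial_unclassifiable(self):
        s = make_session([10.0] * 10)
        s.repeated_trials[0].excluded = True
        s.repeated_trials[0].exclusion_reason = "baseline_movement"
        with pytest.raises(ValueError, match="not classifiable"):
            habituation_inclusion(s)


class TestClassifyHabituation:
    def test_thirty_percent_drop_habituated(self):
        s = make_session([10, 10, 10, 9, 9, 9, 8, 7, 7, 7])
        r = classify_habituation(s)
        assert r.H == pytest.approx(0.30)
        assert r.habituated is True

    def test_exact_cutoff_not_habituated(self):
        s = make_session([10, 10, 10, 9, 9, 9, 8, 7.5, 7.5, 7.5])
        r = classify_habituation(s)
        assert r.H == pytest.approx(0.25)
        assert r.habituated is False  # strict >

    def test_increasing_responses_negative_index(self):
        s = make_session([5, 5, 5, 7, 7, 7, 9, 10, 10, 10])
        r = classify_habituation(s)
        assert r.H == pytest.approx(-1.0)
        assert r.habituated is False

    def test_insufficient_block_trials_unclassifiable(self):
        s = make_session([10.0] * 10)
        for t in s.repeated_trials[1:3]:
            t.excluded, t.exclusion_reason = True, "baseline_movement"
        r = classify_habituation(s)
        assert r.included and r.habituated is None
        assert "insufficient" in r.reason

    def test_partial_exclusion_uses_surviving_trials(self):
        s = make_session([10, 10, 99, 9, 9, 9, 8, 7, 7, 99])
        for k in (2, 9):
            s.repeated_trials[k].excluded = True
            s.repeated_trials[k].exclusion_reason = "baseline_movement"
        r = classify_habituation(s)
        assert r.first_block_mean == pytest.approx(10.0)
        assert r.last_block_mean == pytest.approx(7.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.1, 100.0),
           st.lists(st.floats(0.5, 50.0), min_size=10, max_size=10))
    def test_scale_invariance(self, lam, peaks):
        """Multiplying every peak by lambda > 0 leaves H and flags unchanged."""
        a = classify_habituation(make_session(peaks))
        b = classify_habituation(make_session([lam * p for p in peaks]))
        assert a.habituated == b.habituated and a.included == b.included
        if a.H is not None:
            assert a.H == pytest.approx(b.H, rel=1e-9, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1.0, 50.0), min_size=10, max_size=10),
           st.floats(0.1, 10.0), st.integers(0, 2))
    def test_monotonicity_in_block_peaks(self, peaks, bump, idx):
        """Raising a last-block peak never increases H; first-block never decreases."""
        base = classify_habituation(make_session(peaks)).H
        up_last = list(peaks)
        up_last[7 + idx] += bump
        assert classify_habituation(make_session(up_last)).H <= base + 1e-12
        up_first = list(peaks)
        up_first[idx] += bump
        assert classify_habituation(make_session(up_first)).H >= base - 1e-12


class TestCutoffSensitivity:
    def test_uniform_H_fractions_step_at_cutoff(self):
        # all animals at H = 0.35: habituating below, not at 0.40
        sessions = [make_session([10, 10, 10, 8, 8, 8, 6.5, 6.5, 6.5, 6.5])
                    for _ in range(4)]
        table = habituation_sensitivity(sessions)
        by = {c: sub["fraction"].iloc[0] for c, sub in table.groupby("cutoff")}
        assert by[0.20] == by[0.25] == by[0.30] == 1.0
        assert by[0.40] == 0.0

    def test_single_animal_fractions_are_binary(self):
        table = habituation_sensitivity([make_session([10.0] * 10)])
        assert set(table["fraction"]).issubset({0.0, 1.0})

    def test_separated_cohorts_same_sign_at_all_cutoffs(self):
        spec = CohortSpec(seed=17, habituation_prob={"control": 0.9,
                                                     "mutant": 0.1})
        sessions, _ = generate_cohort(spec)
        table = habituation_sensitivity(sessions)
        signs = genotype_difference_sign(table, "control", "mutant")
        assert set(signs.values()) == {1}


class TestOptoScoring:
    def test_plain_mean(self):
        assert score_opto_session(OptoSession(peaks=[10, 20, 30, 40, 50])) == 30

    def test_fall_over_substitutes_cap(self):
        s = OptoSession(peaks=[10, 10, 10, 10, 0],
                        fell_over=[False] * 4 + [True])
        assert score_opto_session(s) == pytest.approx((40 + 106.383) / 5)

    def test_all_fall_overs(self):
        s = OptoSession(peaks=[0.0] * 5, fell_over=[True] * 5)
        assert score_opto_session(s) == pytest.approx(106.383)

    def test_wrong_trial_count_rejected(self):
        with pytest.raises(ValueError, match="5 trials"):
            score_opto_session(OptoSession(peaks=[1, 2, 3]))
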