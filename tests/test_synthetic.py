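"""Generators: determinism, ground-truth structure, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from vrstim import (
    GazeTruthParams,
    StudyDesign,
    VitalGroundTruth,
    detect_fixations_idt,
    generate_eye_frames,
    generate_gaze_trace,
    generate_item_responses,
    generate_questionnaire,
    generate_vitals,
)


class TestStudyDesign:
    def test_nonpositive_count_rejected_naming_field(self):
        with pytest.raises(ValueError, match="n_participants"):
            StudyDesign(n_participants=0)
        with pytest.raises(ValueError, match="gaze_rate"):
            StudyDesign(n_participants=5, gaze_rate=0)

    def test_epochs_outside_video_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            StudyDesign(n_participants=5, video_duration=100.0,
                        target_epochs=[(90.0, 120.0)])

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            StudyDesign(n_participants=5, video_duration=100.0,
                        target_epochs=[(0.0, 30.0), (20.0, 50.0)])


class TestGazeTrace:
    def test_same_seed_gives_identical_streams(self):
        d = StudyDesign(n_participants=1, n_videos=1, video_duration=30.0)
        a, _ = generate_gaze_trace(d, seed=9)
        b, _ = generate_gaze_trace(d, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_blinks_means_all_valid(self):
        d = StudyDesign(n_participants=1, n_videos=1, video_duration=30.0)
        p = GazeTruthParams(blink_rate_per_min=0.0)
        samples, truth = generate_gaze_trace(d, p, seed=1)
        assert samples["valid"].all()
        assert truth.blink_intervals == []

    def test_sample_rate_matches_design(self):
        d = StudyDesign(n_participants=1, n_videos=1, video_duration=10.0)
        samples, _ = generate_gaze_trace(d, seed=2)
        assert len(samples) == 600
        assert np.allclose(np.diff(samples["t_s"]), 1 / 60.0)

    def test_samples_inside_blinks_flagged_invalid(self):
        d = StudyDesign(n_participants=1, n_videos=1, video_duration=60.0)
        p = GazeTruthParams(blink_rate_per_min=20.0)
        samples, truth = generate_gaze_trace(d, p, seed=3)
        t = samples["t_s"].to_numpy()
        for s, e in truth.blink_intervals:
            assert not samples.loc[(t >= s) & (t < e), "valid"].any()

    def test_target_epochs_have_longer_true_fixations(self):
        d = StudyDesign(n_participants=1, n_videos=2, video_duration=120.0)
        samples, truth = generate_gaze_trace(d, seed=4)
        fix = truth.events[truth.events["kind"] == "fixation"].copy()
        fix["dur"] = fix["end_s"] - fix["start_s"]
        t0 = fix["start_s"] % d.video_duration
        on = pd.Series(False, index=fix.index)
        for s, e in d.target_epochs:
            on |= (t0 >= s) & (t0 < e)
        assert fix.loc[on, "dur"].mean() > fix.loc[~on, "dur"].mean()

    def test_idt_recovers_event_count_with_tight_truth(self):
        # fixed 200 ms fixations with 0.3 deg jitter: the detector should
        # recover the scheduled event count within a few percent
        d = StudyDesign(n_participants=1, n_videos=1, video_duration=120.0)
        p = GazeTruthParams(fix_dur_mean_ms=200.0, fix_dur_mean_target_ms=200.1,
                            fix_dur_sd_ms=0.0, blink_rate_per_min=0.0)
        samples, truth = generate_gaze_trace(d, p, seed=5)
        fix, _ = detect_fixations_idt(samples)
        n_true = int((truth.events["kind"] == "fixation").sum())
        assert abs(len(fix) - n_true) / n_true <= 0.05


class TestEyeFrames:
    def test_noiseless_darkest_pixels_are_exactly_the_disc(self):
        frames, truth = generate_eye_frames(1, (50, 40), 10, image_size_px=(100, 80))
        img = frames[0]
        yy, xx = np.mgrid[0:80, 0:100]
        inside = np.hypot(xx - 50, yy - 40) <= 9.0  # strictly interior
        outside = np.hypot(xx - 50, yy - 40) > 11.0
        assert (img[inside] < 60).all()
        assert (img[outside] > 150).all()

    def test_all_closure_frames_contain_no_disc(self):
        frames, _ = generate_eye_frames(3, (50, 40), 10, closure_frames={0, 1, 2},
                                        image_size_px=(100, 80))
        for f in frames:
            assert f.min() > 100  # uniform lid, no dark disc anywhere

    def test_out_of_bounds_pupil_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            generate_eye_frames(1, (5, 5), 20, image_size_px=(100, 80))
        with pytest.raises(ValueError, match="radius"):
            generate_eye_frames(1, (50, 40), 2, image_size_px=(100, 80))

    def test_seeded_determinism(self):
        a, _ = generate_eye_frames(4, (50, 40), 12, noise_sd=6.0, seed=7,
                                   image_size_px=(100, 80))
        b, _ = generate_eye_frames(4, (50, 40), 12, noise_sd=6.0, seed=7,
                                   image_size_px=(100, 80))
        assert np.array_equal(a, b)


class TestVitals:
    def test_all_sds_zero_and_no_trend_gives_constant_baselines(self):
        d = StudyDesign(n_participants=3)
        truth = VitalGroundTruth(beta_time=0.0, beta_age_time=0.0,
                                 random_intercept_sd=0.0, random_slope_sd=0.0,
                                 residual_sd=0.0, beta_time_per_signal={})
        vit = generate_vitals(d, truth, [0.0, 0.0, 0.0], seed=1)
        for sig, base in truth.baseline_means.items():
            assert np.allclose(vit[sig], base)

    def test_deterministic_fixed_effect_line_when_noise_free(self):
        d = StudyDesign(n_participants=2)
        truth = VitalGroundTruth(beta_time=-0.5, beta_age_time=0.0,
                                 random_intercept_sd=0.0, random_slope_sd=0.0,
                                 residual_sd=0.0, beta_time_per_signal={})
        vit = generate_vitals(d, truth, [0.0, 0.0], seed=1)
        expected = truth.baseline_means["hf"] - 0.5 * vit["time_index"]
        assert np.allclose(vit["hf"], expected)

    def test_spo2_has_no_time_trend_by_default_and_stays_in_range(self):
        d = StudyDesign(n_participants=4)
        truth = VitalGroundTruth(random_intercept_sd=0.0, random_slope_sd=0.0,
                                 residual_sd=0.0)
        vit = generate_vitals(d, truth, [0.0] * 4, seed=2)
        per = vit.groupby("participant_id")["spo2"]
        assert (per.nunique() == 1).all()
        assert vit["spo2"].between(0, 100).all()

    def test_age_interaction_applies_to_map_only(self):
        d = StudyDesign(n_participants=2)
        truth = VitalGroundTruth(beta_time=0.0, beta_age_time=-0.1,
                                 random_intercept_sd=0.0, random_slope_sd=0.0,
                                 residual_sd=0.0, beta_time_per_signal={})
        vit = generate_vitals(d, truth, [0.0, 10.0], seed=3)
        young = vit[vit["participant_id"] == 1]
        old = vit[vit["participant_id"] == 2]
        assert np.allclose(young["hf"].to_numpy(), old["hf"].to_numpy())
        slope_old = np.polyfit(old["time_index"], old["map"], 1)[0]
        assert slope_old == pytest.approx(-1.0, abs=1e-9)

    def test_wrong_age_count_rejected(self):
        d = StudyDesign(n_participants=3)
        with pytest.raises(ValueError, match="ages"):
            generate_vitals(d, VitalGroundTruth(), [50.0], seed=1)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="corr"):
            VitalGroundTruth(intercept_slope_corr=1.5)


class TestQuestionnaire:
    def test_zero_sd_gives_exact_means(self):
        scores = generate_questionnaire({"usability": 4.0}, {"usability": 0.0}, n=5, seed=1)
        assert np.allclose(scores["usability"], 4.0)

    def test_mean_outside_scale_rejected(self):
        with pytest.raises(ValueError, match="usability"):
            generate_questionnaire({"usability": 5.5}, {"usability": 0.1}, n=5, seed=1)

    def test_empirical_means_near_requested(self):
        scores = generate_questionnaire(n=400, seed=2)
        # usability mean 4.5, sd 0.6: within 3 SE (clipping pulls slightly down)
        se = 0.6 / np.sqrt(400)
        assert abs(scores["usability"].mean() - 4.5) < 3 * se + 0.05

    def test_same_seed_identical_tables(self):
        a = generate_questionnaire(n=10, seed=3)
        b = generate_questionnaire(n=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_item_responses_are_integer_1_to_5(self):
        items = generate_item_responses(n=12, seed=4)
        vals = items[[f"item_{i}" for i in range(1, 17)]]
        assert vals.isin([1, 2, 3, 4, 5]).all().all()
        assert items["item_17"].isin([1, 2, 3]).all()
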