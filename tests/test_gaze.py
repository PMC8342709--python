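"""Gaze preprocessing, saccade detection, trial scoring, exclusions."""

import numpy as np
import pandas as pd
import pytest

from wmdecode.behavior import simulate_behavior
from wmdecode.design import generate_design
from wmdecode.gaze import (GazeRecord, behavior_summary,
                           detect_saccades, preprocess_gaze, recalibrate_run,
                           score_trial)
from wmdecode.gazesim import simulate_gaze, synth_trial_trace


def fixation_trace(duration=2.0, fs=500.0, noise_sd=0.0, offset=(0.0, 0.0),
                   rng=None):
    time = np.arange(0.0, duration, 1.0 / fs)
    x = np.full_like(time, offset[0])
    y = np.full_like(time, offset[1])
    if noise_sd and rng is not None:
        x = x + rng.normal(0, noise_sd, time.size)
        y = y + rng.normal(0, noise_sd, time.size)
    return GazeRecord(time=time, x=x, y=y,
                      valid=np.ones(time.size, dtype=bool),
                      events={"response_cue": duration * 0.75,
                              "target_return": duration},
                      fixation_epochs=[(0.0, duration * 0.5)])


class TestPreprocess:
    def test_noise_free_fixation_unchanged(self):
        rec = preprocess_gaze(fixation_trace())
        assert np.allclose(rec.x, 0.0, atol=1e-12)
        assert np.allclose(rec.y, 0.0, atol=1e-12)

    def test_drift_correction_removes_constant_offset(self):
        rec = preprocess_gaze(fixation_trace(offset=(0.5, -0.3)))
        assert np.allclose(rec.x, 0.0, atol=1e-9)
        assert np.allclose(rec.y, 0.0, atol=1e-9)

    def test_cubic_recalibration_recovers_true_positions(self, rng):
        distort = lambda v: 1.08 * v + 0.004 * v ** 2 - 0.0005 * v ** 3 + 0.3
        records, measured, truth = [], [], []
        for angle in np.arange(0, 360, 30):
            ex = 12 * np.cos(np.deg2rad(angle))
            ey = 12 * np.sin(np.deg2rad(angle))
            rec = synth_trial_trace((ex, ey))
            rec = GazeRecord(time=rec.time, x=distort(rec.x),
                             y=distort(rec.y), valid=rec.valid,
                             events=rec.events,
                             fixation_epochs=rec.fixation_epochs)
            records.append(rec)
            measured.append([rec.x[-1], rec.y[-1]])
            truth.append([ex, ey])
        fixed = recalibrate_run(records, np.array(measured), np.array(truth))
        for rec, (ex, ey) in zip(fixed, truth):
            assert abs(rec.x[-1] - ex) < 0.05
            assert abs(rec.y[-1] - ey) < 0.05


class TestDetectSaccades:
    def test_synthetic_saccade_found_within_one_sample(self):
        rec = synth_trial_trace((10.0, 0.0))
        events = detect_saccades(preprocess_gaze(rec))
        assert len(events) == 1
        assert abs(events[0].onset - rec.truth["saccade_onset"]) <= 1 / 500
        # onset/offset clip the slow tails of the velocity profile
        assert events[0].amplitude == pytest.approx(10.0, abs=0.5)

    def test_subthreshold_amplitude_ignored(self, rng):
        rec = fixation_trace(noise_sd=0.05, rng=rng)   # ~0.2 deg excursions
        assert detect_saccades(preprocess_gaze(rec, drift_correct=False)) == []

    def test_velocity_plateau_at_threshold_is_rejected(self):
        # constant 30 deg/s drift never *exceeds* the strict threshold;
        # power-of-two sampling keeps the computed speed float-exact
        n = 512
        time = np.arange(n) / 512.0
        ones = np.ones(n, bool)
        rec = GazeRecord(time=time, x=30.0 * time, y=np.zeros(n), valid=ones)
        assert detect_saccades(rec) == []
        rec_fast = GazeRecord(time=time, x=31.0 * time, y=np.zeros(n),
                              valid=ones)
        assert len(detect_saccades(rec_fast)) == 1

    def test_amplitude_threshold_is_sharp(self):
        """With speed and duration passing, events vanish as the gaze
        shift crosses 0.25 deg from above (bisection)."""
        def events(amp):
            time = np.arange(0.0, 0.5, 1 / 500)
            phase = np.clip((time - 0.2) / 0.02, 0.0, 1.0)  # 20 ms saccade
            x = amp * 0.5 * (1 - np.cos(np.pi * phase))
            rec = GazeRecord(time=time, x=x, y=np.zeros_like(x),
                             valid=np.ones(time.size, bool))
            # low velocity threshold isolates the amplitude criterion
            return detect_saccades(rec, velocity_thresh=10.0)
        lo, hi = 0.18, 1.0
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if events(mid):
                hi = mid
            else:
                lo = mid
        # the smallest detected gaze shift sits right at the 0.25 deg rule
        boundary = events(hi)[0]
        assert 0.25 <= boundary.amplitude < 0.26
        assert events(lo) == []


class TestScoring:
    def test_clean_trial_recovers_truth(self):
        rec = synth_trial_trace((12.0, 0.0), rt_s=0.3)
        pre = preprocess_gaze(rec)
        score = score_trial(pre, detect_saccades(pre), target_angle=0.0)
        assert not score["excluded"]
        assert score["memory_error"] == pytest.approx(0.0, abs=0.5)
        assert score["rt_ms"] == pytest.approx(300.0, abs=10.0)

    def test_exclusion_rules_on_hand_labeled_trials(self):
        """Ten constructed trials against hand-assigned exclusion decisions."""
        ecc = 12.0
        cases = [
            # (endpoint offset deg, rt_s, fixation bump deg, expected reasons)
            ((0.0, 0.0), 0.30, 0.0, set()),
            ((0.0, 0.0), 0.45, 0.0, set()),
            ((4.0, 0.0), 0.30, 0.0, set()),                  # 4 deg off: within tolerance
            ((6.0, 0.0), 0.30, 0.0, {"endpoint_error"}),
            ((-9.0, 0.0), 0.30, 0.0, {"small_amplitude", "endpoint_error"}),
            ((0.0, 0.0), 0.30, 2.6, {"fixation_break"}),
            ((0.0, 0.0), 0.30, 2.4, set()),
            ((0.0, 5.5), 0.30, 0.0, {"endpoint_error"}),
            ((0.0, 4.5), 0.30, 0.0, set()),
            ((0.0, 0.0), 1.20, 0.0, {"no_saccade"}),   # lands after reappearance window
        ]
        for (dx, dy), rt, bump, expected in cases:
            rec = synth_trial_trace((ecc + dx, dy), rt_s=rt)
            if bump:
                in_delay = (rec.time >= 5.0) & (rec.time < 6.0)
                rec.x[in_delay] += bump
            pre = preprocess_gaze(rec)
            score = score_trial(pre, detect_saccades(pre), target_angle=0.0)
            got = set(filter(None, score["exclusion_reason"].split(";")))
            assert got == expected, (dx, dy, rt, bump, got)

    def test_small_initial_saccade_excluded(self):
        rec = synth_trial_trace((3.0, 0.0))
        pre = preprocess_gaze(rec)
        score = score_trial(pre, detect_saccades(pre), target_angle=0.0)
        assert "small_amplitude" in score["exclusion_reason"]
        assert score["excluded"]


class TestBehaviorSummary:
    def _records(self, errors, pid="s1", cond="a"):
        n = len(errors)
        return pd.DataFrame({
            "participant_id": [pid] * n,
            "memory_error": errors,
            "rt_ms": [300.0] * n,
            "excluded": [False] * n}), [cond] * n

    def test_zero_errors_give_zero_sd(self):
        rec, cond = self._records([0.0, 0.0, 0.0])
        out = behavior_summary(rec, cond)
        assert out["precision_sd"].iloc[0] == 0.0

    def test_sample_sd_convention(self):
        rec, cond = self._records([-2.0, 0.0, 2.0])
        out = behavior_summary(rec, cond)
        assert out["precision_sd"].iloc[0] == pytest.approx(2.0)

    def test_precision_monotone_in_motor_noise(self):
        design = generate_design(6, seed=5)
        sds = []
        for motor in (2.0, 6.0, 12.0):
            beh = simulate_behavior(design, motor_sd=motor, seed=8)
            out = behavior_summary(beh.assign(excluded=False),
                                   design["condition"])
            sds.append(out["precision_sd"].mean())
        assert sds[0] < sds[1] < sds[2]

    def test_insufficient_trials_rejected(self):
        rec, cond = self._records([1.0])
        with pytest.raises(ValueError, match=">=2"):
            behavior_summary(rec, cond)


class TestEndToEndGaze:
    def test_detection_complete_and_no_spurious_events(self):
        design = generate_design(2, seed=71)
        beh = simulate_behavior(design, motor_sd=2.0, seed=72)
        for rec in simulate_gaze(design, beh, seed=73):
            events = detect_saccades(preprocess_gaze(rec))
            assert len(events) == 1
            assert abs(events[0].onset - rec.truth["saccade_onset"]) <= 1 / 500
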