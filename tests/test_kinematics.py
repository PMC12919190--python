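"""Task-signal construction, cycle detection, and the 12 kinematic features."""

import dataclasses

import numpy as np
import pytest

from kinescore.errors import InsufficientCyclesError, MissingJointError
from kinescore.kinematics import (FEATURE_NAMES, FeatureVector, Signal,
                                  compute_signal, extract_features,
                                  find_cycles, resample)
from kinescore.segmentation import TaskWindow
from kinescore.tasks import TASKS, TaskSpec

from conftest import make_sequence


def sine_signal(amp=1.0, freq=2.0, fps=100.0, duration=10.0, phase=0.0,
                noise=0.0, rng=None, decay_per_cycle=0.0):
    t = np.arange(int(duration * fps)) / fps
    envelope = 1.0 - decay_per_cycle * freq * t
    x = amp * envelope * np.sin(2 * np.pi * freq * t + phase)
    if noise:
        x = x + rng.normal(0, noise, x.size)
    return Signal(x, fps)


class TestTaskTable:
    def test_cue_counts_for_chair_and_gait(self):
        assert TASKS["arising_from_chair"].complexity == 2
        assert TASKS["gait"].complexity == 7

    def test_battery_has_thirteen_task_side_slots(self):
        from kinescore.tasks import task_side_slots
        assert len(task_side_slots()) == 13


class TestComputeSignal:
    def test_finger_tapping_distance_is_hypotenuse(self):
        n = 30
        seq = make_sequence({"right_thumb": np.tile([0.0, 0.0], (n, 1)),
                             "right_index": np.tile([3.0, 4.0], (n, 1))})
        sig = compute_signal(seq, TASKS["finger_tapping"], "right",
                             TaskWindow(0, n))
        np.testing.assert_allclose(sig.values, 5.0)

    def test_toe_tapping_reference_frame_gives_zero_signal(self):
        n = 30
        seq = make_sequence({"right_big_toe": np.tile([1.0, 7.0], (n, 1))})
        sig = compute_signal(seq, TASKS["toe_tapping"], "right",
                             TaskWindow(0, n))
        np.testing.assert_allclose(sig.values, 0.0)

    def test_hand_movement_mean_fingertip_distance(self):
        n = 20
        task = TaskSpec("hand_movement",
                        {"right": ("right_palm", "right_index", "right_middle")},
                        bilateral=True, complexity=5, signal_kind="hand_open")
        seq = make_sequence({
            "right_palm": np.tile([0.0, 0.0], (n, 1)),
            "right_index": np.tile([2.0, 0.0], (n, 1)),
            "right_middle": np.tile([0.0, 4.0], (n, 1)),
        })
        sig = compute_signal(seq, task, "right", TaskWindow(0, n))
        np.testing.assert_allclose(sig.values, 3.0)

    def test_missing_required_joint_rejected(self):
        seq = make_sequence({"right_thumb": np.zeros((10, 2))})
        with pytest.raises(MissingJointError):
            compute_signal(seq, TASKS["finger_tapping"], "right",
                           TaskWindow(0, 10))

    def test_gait_steps_baseline_subtracted(self):
        fps, n = 30.0, 240
        t = np.arange(n) / fps
        gap = 2.0 + 1.0 * 0.5 * (1 - np.cos(2 * np.pi * 1.5 * t))
        seq = make_sequence({
            "left_ankle": np.stack([-gap / 2, np.zeros(n)], axis=1),
            "right_ankle": np.stack([gap / 2, np.zeros(n)], axis=1),
        })
        sig = compute_signal(seq, TASKS["gait"], "n/a", TaskWindow(0, n))
        assert sig.values[0] == 0.0          # first step is the reference
        assert len(sig.values) >= 2
        assert sig.fps == pytest.approx(1.5, rel=0.1)   # steps per second

    def test_translation_invariance(self, rng):
        n = 60
        thumb = rng.uniform(0, 5, (n, 2))
        index = thumb + rng.uniform(1, 2, (n, 2))
        base = make_sequence({"right_thumb": thumb, "right_index": index})
        moved = make_sequence({"right_thumb": thumb + 17.0,
                               "right_index": index + 17.0})
        task = TASKS["finger_tapping"]
        s1 = compute_signal(base, task, "right", TaskWindow(0, n))
        s2 = compute_signal(moved, task, "right", TaskWindow(0, n))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)

    def test_rotation_invariance_of_distance_signal(self, rng):
        n = 60
        thumb = rng.uniform(0, 5, (n, 2))
        index = thumb + rng.uniform(1, 2, (n, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        base = make_sequence({"right_thumb": thumb, "right_index": index})
        spun = make_sequence({"right_thumb": thumb @ rot.T,
                              "right_index": index @ rot.T})
        task = TASKS["finger_tapping"]
        s1 = compute_signal(base, task, "right", TaskWindow(0, n))
        s2 = compute_signal(spun, task, "right", TaskWindow(0, n))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)


class TestFindCycles:
    def test_clean_sine_counts_periods(self):
        sig = sine_signal(freq=1.0, duration=5.0, fps=50.0, phase=-np.pi / 2)
        peaks, troughs = find_cycles(sig)
        assert len(peaks) == 5
        assert 4 <= len(troughs) <= 6

    def test_monotone_ramp_has_no_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            find_cycles(Signal(np.linspace(0, 1, 100), 30.0))

    def test_noise_below_prominence_floor_ignored(self, rng):
        clean = sine_signal(freq=1.0, duration=5.0, fps=50.0, phase=-np.pi / 2)
        noisy = sine_signal(freq=1.0, duration=5.0, fps=50.0, phase=-np.pi / 2,
                            noise=0.03, rng=rng)
        assert len(find_cycles(noisy)[0]) == len(find_cycles(clean)[0])

    def test_peaks_and_troughs_alternate(self, rng):
        sig = sine_signal(freq=2.0, noise=0.05, rng=rng)
        peaks, troughs = find_cycles(sig)
        merged = sorted([(p, "p") for p in peaks] + [(t, "t") for t in troughs])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestExtractFeatures:
    def test_pure_sine_closed_forms(self):
        amp, freq = 1.5, 2.0
        feats = extract_features(sine_signal(amp=amp, freq=freq))
        assert feats.avg_freq == pytest.approx(freq, abs=0.1)
        assert feats.avg_amp == pytest.approx(2 * amp, rel=0.05)
        assert abs(feats.dec_amp) <= 0.01 * amp
        assert feats.avg_peak_dist == pytest.approx(1 / freq, rel=0.02)
        # mean |d/dt sin| over a period = 2/pi * peak speed
        assert feats.avg_vel == pytest.approx(2 * np.pi * freq * amp * 2 / np.pi,
                                              rel=0.02)

    def test_constant_signal_zero_dynamics_and_na_cycles(self):
        feats = extract_features(Signal(np.full(100, 2.0), 30.0))
        assert feats.avg_vel == 0 and feats.avg_acc == 0 and feats.avg_jerk == 0
        assert np.isnan(feats.avg_amp) and np.isnan(feats.avg_peak_dist)

    def test_programmed_amplitude_decay_recovered(self):
        decay = 0.10
        amp = 2.0
        sig = sine_signal(amp=amp, freq=2.0, duration=5.0,
                          decay_per_cycle=decay)
        feats = extract_features(sig)
        peaks, troughs = find_cycles(sig)
        # oracle: slope of the true per-cycle peak-to-trough amplitudes
        envelope = 2 * amp * (1 - decay * np.arange(len(peaks)))
        true_slope = np.polyfit(np.arange(len(peaks)), envelope, 1)[0]
        assert feats.dec_amp < 0
        assert feats.dec_amp == pytest.approx(true_slope, rel=0.2)

    def test_scaling_scales_amplitude_not_frequency(self):
        base = sine_signal(amp=1.0, freq=2.0)
        scaled = Signal(base.values * 3.0, base.fps)
        f1, f2 = extract_features(base), extract_features(scaled)
        assert f2.avg_amp == pytest.approx(3.0 * f1.avg_amp, rel=1e-6)
        assert f2.avg_freq == pytest.approx(f1.avg_freq, abs=1e-9)

    def test_feature_order_is_frozen(self):
        assert FEATURE_NAMES == (
            "avg_vel", "avg_acc", "avg_jerk", "avg_freq", "max_fft",
            "avg_peak_dist", "avg_trough_dist", "avg_amp", "amp_std",
            "dec_amp", "dec_vel", "period_range")
        fv = FeatureVector(*range(12))
        assert fv.to_array().tolist() == list(map(float, range(12)))
        assert [f.name for f in dataclasses.fields(FeatureVector)] == list(FEATURE_NAMES)


class TestResample:
    def test_endpoints_and_length(self):
        sig = Signal(np.array([0.0, 1.0, 4.0]), 30.0)
        out = resample(sig, 7)
        assert out.shape == (7,)
        assert out[0] == 0.0 and out[-1] == 4.0
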