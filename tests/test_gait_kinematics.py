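import numpy as np
import pytest

from hydrogait.gait_kinematics import (
    detect_strides,
    lowpass_filter,
    read_markers,
    segment_states,
)
from hydrogait.synthetic_cohort import stride_length_for_speed

from conftest import make_markers


class TestReadMarkers:
    def test_roundtrip_preserves_sampling_rate(self, trial, tmp_path):
        path = tmp_path / "markers.csv"
        trial.to_csv(path)
        loaded = read_markers(path)
        assert loaded.sampling_rate == pytest.approx(60.0, rel=1e-6)
        assert np.allclose(loaded.xy("calcaneus"), trial.xy("calcaneus"), atol=1e-9)

    def test_short_gap_interpolated(self, trial, tmp_path):
        import pandas as pd

        path = tmp_path / "markers.csv"
        df = trial.data.copy()
        df.insert(0, "time", trial.time)
        df.loc[10:11, "calcaneus_y"] = np.nan  # 2-sample gap
        df.to_csv(path, index=False)
        loaded = read_markers(path)
        expected = np.interp(
            [10, 11], [9, 12], trial.y("calcaneus")[[9, 12]]
        )
        assert np.allclose(loaded.y("calcaneus")[10:12], expected, atol=1e-9)

    def test_long_gap_rejected(self, trial, tmp_path):
        path = tmp_path / "markers.csv"
        df = trial.data.copy()
        df.insert(0, "time", trial.time)
        df.loc[10:14, "xiphoid_x"] = np.nan  # 5-sample gap
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="gap"):
            read_markers(path)

    def test_missing_landmark_named(self, trial, tmp_path):
        path = tmp_path / "markers.csv"
        df = trial.data.drop(columns=["calcaneus_x", "calcaneus_y"])
        df.insert(0, "time", trial.time)
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="calcaneus"):
            read_markers(path)


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 1.7)
        assert np.allclose(lowpass_filter(x, 4.5, 60.0), x, atol=1e-9)

    def test_high_frequency_strongly_attenuated(self):
        t = np.arange(600) / 60.0
        x = np.sin(2 * np.pi * 20.0 * t)
        y = lowpass_filter(x, 4.5, 60.0)
        # interior amplitude, away from filter edge effects
        assert np.abs(y[100:-100]).max() < 0.1 * 1.0

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), 40.0, 60.0)


class TestSegmentStates:
    def test_static_vertical_shank_has_zero_angle(self):
        markers = make_markers(50)
        s = segment_states(markers)["shank"]
        assert np.allclose(s.angle, 0.0, atol=1e-12)
        assert np.allclose(s.angular_velocity, 0.0, atol=1e-9)

    def test_rigid_translation_gives_pure_linear_velocity(self):
        n, fs, v = 100, 60.0, 0.5
        shift = v * np.arange(n) / fs
        over = {}
        base = make_markers(n)
        for lm in ("fifth_metatarsal", "calcaneus", "lateral_malleolus",
                   "femoral_epicondyle", "greater_trochanter", "umbilicus",
                   "xiphoid"):
            over[f"{lm}_x"] = base.x(lm) + shift
        markers = make_markers(n, **over)
        for seg in segment_states(markers).values():
            assert np.allclose(seg.angular_velocity, 0.0, atol=1e-9)
            assert np.allclose(seg.prox_velocity[:, 0], v, atol=1e-9)
            assert np.allclose(seg.prox_velocity[:, 1], 0.0, atol=1e-9)

    def test_constant_rotation_recovered_by_central_difference(self):
        n, fs, omega, L = 120, 60.0, 1.0, 0.43
        t = np.arange(n) / fs
        theta = omega * t - 0.5  # sweep through vertical
        markers = make_markers(
            n,
            lateral_malleolus_x=0.0 + L * np.sin(theta),
            lateral_malleolus_y=0.50 - L * np.cos(theta),
        )
        s = segment_states(markers)["shank"]
        dt = 1 / fs
        # interior central differences: error O(dt^2) for the sinusoidal path
        assert np.allclose(s.angular_velocity[2:-2], omega, atol=omega * dt**2 * 10)

    def test_coincident_landmarks_rejected(self):
        markers = make_markers(10, lateral_malleolus_x=np.zeros(10),
                               lateral_malleolus_y=np.full(10, 0.50))
        with pytest.raises(ValueError, match="coincident"):
            segment_states(markers)


class TestDetectStrides:
    def test_recovers_generator_stride_length_and_speed(self, strides, participant):
        """Interior strides match the generator's ground truth within 2%."""
        sl_true = stride_length_for_speed(0.6, participant.stature)
        interior = strides[1:-1]
        assert len(interior) >= 3
        for s in interior:
            assert s.stride_length == pytest.approx(sl_true, rel=0.02)
            assert s.speed == pytest.approx(0.6, rel=0.02)
            assert 0 < s.single_support_displacement < s.stride_length

    def test_periodic_gait_gives_identical_strides(self, strides):
        """With a stride period that is a whole number of samples, detected
        stride lengths repeat exactly."""
        interior = strides[1:-1]
        lengths = {round(s.stride_length, 9) for s in interior}
        assert len(lengths) == 1

    def test_speed_times_duration_equals_stride_length(self, strides):
        for s in strides:
            assert s.speed * s.duration == pytest.approx(s.stride_length, rel=1e-9)

    def test_static_markers_yield_no_strides(self):
        with pytest.raises(ValueError, match="no strides"):
            detect_strides(make_markers(200))

    def test_detection_robust_to_digitization_noise(self, participant):
        """With realistic marker noise the debounced contact events still
        recover stride length and speed within 5%."""
        from hydrogait.gait_kinematics import filter_markers
        from hydrogait.synthetic_cohort import CohortConfig, generate_gait_trial

        cfg = CohortConfig(seed=1)  # default 5 mm marker noise
        trial = generate_gait_trial(participant, 0.85, 0.4, cfg, seed=3)
        interior = detect_strides(filter_markers(trial))[1:-1]
        sl_true = stride_length_for_speed(0.4, participant.stature)
        assert len(interior) >= 4
        for s in interior:
            assert s.stride_length == pytest.approx(sl_true, rel=0.05)
            assert s.speed == pytest.approx(0.4, rel=0.05)
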