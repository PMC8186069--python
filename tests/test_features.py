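"""Feature-derivation contracts: exact static/dynamic reconstruction,
posture-angle inversion, VeDBA closed forms, periodogram amplitudes,
magnetometry variables, decimation, and feature-table assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import hoofbeat as hb
from hoofbeat.core import intervals_to_frame
from hoofbeat.features import (
    _smoothing_samples,
    decompose_static_dynamic,
    default_registry,
    drop_magnetometry,
    magnetometry_features,
    oscillation_amplitude,
    smoothed_vedba,
)

from conftest import two_behaviour_species


class TestDecomposition:
    def test_constant_stream_is_all_static(self):
        acc = np.tile([0.0, 0.0, 1.0], (400, 1))
        static, dynamic = decompose_static_dynamic(acc, 40.0)
        assert np.allclose(static, [0.0, 0.0, 1.0])
        assert np.allclose(dynamic, 0.0)

    @given(
        arrays(np.float64, (250, 3), elements=st.floats(-2, 2, allow_nan=False))
    )
    def test_reconstruction_is_exact(self, acc):
        static, dynamic = decompose_static_dynamic(acc, 40.0)
        np.testing.assert_allclose(static + dynamic, acc, rtol=0, atol=1e-12)

    def test_fast_sinusoid_matches_dirichlet_attenuation(self):
        """The running mean of a tone is the tone scaled by the Dirichlet
        kernel of the window; the dynamic part carries the remainder."""
        rate, f, n = 40.0, 8.0, 2000
        t = np.arange(n) / rate
        z = np.sin(2 * np.pi * f * t)
        acc = np.column_stack([np.zeros(n), np.zeros(n), z])
        static, dynamic = decompose_static_dynamic(acc, rate, window_s=2.0)
        w = _smoothing_samples(rate, 2.0)
        gain = np.sin(np.pi * f * w / rate) / (w * np.sin(np.pi * f / rate))
        interior = slice(w, n - w)
        np.testing.assert_allclose(static[interior, 2], gain * z[interior], atol=1e-9)
        assert np.abs(static[interior, 2]).max() < 0.02  # period << window

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            decompose_static_dynamic(np.zeros((5, 3)), 40.0, window_s=2.0)


class TestVedba:
    def test_zero_dynamic_gives_zero(self):
        assert np.allclose(hb.vedba(np.zeros((10, 3))), 0.0)

    def test_three_four_five(self):
        assert hb.vedba(np.array([[0.3, 0.0, 0.4]]))[0] == pytest.approx(0.5)

    def test_smoothed_rectified_sinusoid_mean_2A_over_pi(self):
        rate, f, A = 40.0, 2.0, 0.7
        t = np.arange(4000) / rate
        dyn = np.column_stack([A * np.sin(2 * np.pi * f * t), np.zeros_like(t), np.zeros_like(t)])
        smv = smoothed_vedba(dyn, rate, window_s=2.0)
        interior = smv[100:-100]
        assert interior.mean() == pytest.approx(2 * A / np.pi, rel=0.01)


class TestPostureAngles:
    @pytest.mark.parametrize(
        "static,pitch,roll",
        [
            ((0.0, 0.0, 1.0), 0.0, 0.0),
            ((1.0, 0.0, 0.0), 90.0, 0.0),
            ((np.sin(np.radians(10)), 0.0, np.cos(np.radians(10))), 10.0, 0.0),
        ],
    )
    def test_known_orientations(self, static, pitch, roll):
        p, r = hb.posture_angles(np.array([static]))
        assert p[0] == pytest.approx(pitch, abs=1e-9)
        assert r[0] == pytest.approx(roll, abs=1e-9)

    def test_angles_bounded(self, rng):
        static = rng.normal(size=(200, 3))
        static = static[np.linalg.norm(static, axis=1) > 0.1]
        p, r = hb.posture_angles(static)
        assert np.all((p >= -90) & (p <= 90))
        assert np.all((r >= -90) & (r <= 90))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            hb.posture_angles(np.zeros((3, 3)))


class TestOscillationAmplitude:
    def test_constant_series_zero(self):
        assert np.allclose(oscillation_amplitude(np.ones(80), 40.0, 2.0), 0.0)

    def test_pure_tone_recovers_amplitude(self):
        """Tone at a DFT bin frequency: amplitude recovered exactly."""
        rate, A = 40.0, 0.45
        t = np.arange(800) / rate
        for f in (1.0, 2.5, 5.0):  # all multiples of 0.5 Hz = bin width at 2 s
            x = A * np.sin(2 * np.pi * f * t)
            amps = oscillation_amplitude(x, rate, 2.0)
            np.testing.assert_allclose(amps, A, atol=1e-9)

    def test_white_noise_amplitude_shrinks_with_window(self, rng):
        x = rng.normal(0, 1.0, size=40960)
        short = oscillation_amplitude(x, 40.0, window_s=0.8).mean()
        long = oscillation_amplitude(x, 40.0, window_s=12.8).mean()
        assert long < short

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            oscillation_amplitude(np.ones(10), 0.5, 2.0)


class TestMagnetometry:
    def test_constant_field_all_zero(self):
        mag = np.tile([0.3, 0.1, 0.5], (160, 1))
        out = magnetometry_features(mag, 40.0, 2.0)
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_constant_rotation_rate_recovered(self):
        """Horizontal field spinning at omega: angular change = omega/rate."""
        rate, omega = 40.0, np.radians(30.0)  # 30 deg/s
        t = np.arange(1600) / rate
        mag = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.zeros_like(t)])
        out = magnetometry_features(mag, rate, 2.0)
        np.testing.assert_allclose(out["mag_angle_change"], omega / rate, rtol=1e-6)

    def test_axis_permutation_symmetry(self, rng):
        mag = rng.normal(0.5, 0.2, size=(400, 3))
        out = magnetometry_features(mag, 40.0, 2.0)
        perm = magnetometry_features(mag[:, [1, 2, 0]], 40.0, 2.0)
        np.testing.assert_allclose(perm["mag_sd_x"], out["mag_sd_y"])
        np.testing.assert_allclose(perm["mag_sd_y"], out["mag_sd_z"])
        np.testing.assert_allclose(perm["mag_sd_z"], out["mag_sd_x"])
        np.testing.assert_allclose(perm["mag_norm_sd"], out["mag_norm_sd"])
        np.testing.assert_allclose(perm["mag_angle_change"], out["mag_angle_change"])

    def test_zero_norm_field_rejected(self):
        mag = np.zeros((100, 3))
        with pytest.raises(ValueError, match="degenerate"):
            magnetometry_features(mag, 40.0, 2.0)


class TestSubsample:
    def _stream(self, n=407, rate=40.0):
        t = np.arange(n) / rate
        data = pd.DataFrame(
            np.column_stack([t, np.zeros((n, 3)), np.ones((n, 3))]),
            columns=hb.core.SENSOR_COLUMNS,
        )
        return hb.SensorStream("a", "goat", "female", rate, data)

    def test_decimation_count(self):
        s = self._stream(n=407)
        out = hb.subsample(s, 10.0)
        assert out.n_samples == 407 // 4 + 1
        assert out.sample_rate_hz == 10.0

    def test_identity_at_native_rate(self):
        s = self._stream()
        assert hb.subsample(s, 40.0) is s

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            hb.subsample(self._stream(), 15.0)

    def test_decimate_then_decompose_is_not_decompose_then_decimate(self):
        """The pipeline fixes decimate-first; the orders genuinely differ."""
        rate, n = 40.0, 4000
        t = np.arange(n) / rate
        z = np.sin(2 * np.pi * 6.0 * t)
        acc = np.column_stack([z, z, z])
        dec_first, _ = decompose_static_dynamic(acc[::4], 10.0, 2.0)
        dec_later, _ = decompose_static_dynamic(acc, 40.0, 2.0)
        assert np.abs(dec_first - dec_later[::4]).max() > 0.01


class TestFeatureTable:
    def _single_behaviour(self, duration=60.0, rate=40.0):
        sp = two_behaviour_species()
        cfg = hb.SimulationConfig(
            species_profiles=(sp,), n_individuals={"test": 1},
            total_duration_s=duration, sample_rate_hz=rate,
            accel_noise_sd_g=0.0, mag_noise_sd=0.0, seed=0, bout_median_s=duration,
        )
        ind = hb.IndividualProfile("t01", "test", "female")
        return hb.generate_stream(sp, ind, cfg, seed=0)

    def test_row_count_and_single_label(self):
        stream, intervals = self._single_behaviour()
        iv = intervals_to_frame(intervals)
        one = iv.iloc[[0]].assign(end_s=60.0)
        table = hb.compute_feature_table(stream, one)
        assert len(table) == 30
        assert table["behaviour"].nunique() == 1

    def test_boundary_straddling_window_dropped(self):
        stream, _ = self._single_behaviour()
        iv = pd.DataFrame(
            {
                "individual_id": "t01", "species": "test", "sex": "female",
                "start_s": [0.0, 10.5], "end_s": [10.5, 60.0],
                "behaviour": ["walking", "standing"], "slope": [None, None],
            }
        )
        table = hb.compute_feature_table(stream, iv)
        # window [10, 12) straddles the 10.5 s boundary and must be absent
        assert 10.0 not in table["window_start_s"].to_numpy()
        assert len(table) == 29

    def test_registry_of_39_definitions_gives_39_columns(self, small_cohort):
        stream = small_cohort.streams[0]
        registry = default_registry()
        assert len(registry) == 39
        table = hb.compute_feature_table(stream, small_cohort.intervals, registry)
        assert len(hb.feature_columns(table)) == 39
        assert not table[hb.feature_columns(table)].isna().any().any()
        for name in ["static_x", "pitch", "smvedba", "psd1_y"]:
            assert name in table.columns

    def test_magnetometry_free_registry(self, small_cohort):
        registry = drop_magnetometry(default_registry())
        assert len(registry) == 34
        table = hb.compute_feature_table(
            small_cohort.streams[0], small_cohort.intervals, registry
        )
        assert not any(c.startswith("mag_") for c in hb.feature_columns(table))

    def test_noiseless_standing_pitch_recovered_to_a_tenth_degree(self):
        sp = two_behaviour_species(
            behaviours=(
                hb.BehaviourProfile("standing", pitch_deg=7.0, roll_deg=0.0),
                hb.BehaviourProfile("resting", pitch_deg=-15.0, roll_deg=0.0),
            )
        )
        cfg = hb.SimulationConfig(
            species_profiles=(sp,), n_individuals={"test": 1},
            total_duration_s=120.0, accel_noise_sd_g=0.0, mag_noise_sd=0.0, seed=1,
        )
        ind = hb.IndividualProfile("t01", "test", "female")
        stream, intervals = hb.generate_stream(sp, ind, cfg, seed=1)
        iv = intervals_to_frame(intervals)
        table = hb.compute_feature_table(stream, iv)
        standing = table[table["behaviour"] == "standing"].copy()
        # static smoothing bleeds across behaviour transitions; judge windows
        # at least one smoothing window clear of their interval's edges
        starts = iv["start_s"].to_numpy()
        idx = np.searchsorted(starts, standing["window_start_s"].to_numpy() + 1.0, "right") - 1
        margin_ok = (
            (standing["window_start_s"].to_numpy() - starts[idx] >= 2.0)
            & (iv["end_s"].to_numpy()[idx] - standing["window_start_s"].to_numpy() - 2.0 >= 2.0)
        )
        interior = standing[margin_ok]
        assert len(interior) > 5
        assert np.abs(interior["pitch"] - 7.0).max() < 0.1

    def test_empty_registry_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            hb.compute_feature_table(
                small_cohort.streams[0], small_cohort.intervals, registry=[]
            )
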