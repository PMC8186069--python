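"""Simulator contracts: orientation physics, interval tiling, determinism,
species morphology, and the ethogram realism check."""
import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

import hoofbeat as hb
from hoofbeat.core import intervals_to_frame, slope_category
from hoofbeat.profiles import draw_individual
from hoofbeat.simulate import gravity_device_frame

from conftest import two_behaviour_species


def _flat_individual(species="test", sex="female"):
    return hb.IndividualProfile(individual_id="t01", species=species, sex=sex)


def _noiseless_config(species, **overrides):
    kwargs = dict(
        species_profiles=(species,),
        n_individuals={species.species: 1},
        total_duration_s=120.0,
        accel_noise_sd_g=0.0,
        mag_noise_sd=0.0,
        seed=3,
    )
    kwargs.update(overrides)
    return hb.SimulationConfig(**kwargs)


class TestGenerateStream:
    def test_static_behaviour_is_pure_gravity(self):
        """Zero noise, pitch 0, roll 0: acceleration is (0, 0, 1) g."""
        sp = two_behaviour_species()
        cfg = _noiseless_config(sp)
        stream, intervals = hb.generate_stream(sp, _flat_individual(), cfg, seed=0)
        iv = intervals_to_frame(intervals)
        t = stream.time
        acc = stream.acc
        for _, row in iv[iv["behaviour"] == "standing"].iterrows():
            mask = (t >= row.start_s) & (t < row.end_s)
            assert np.allclose(acc[mask], [0.0, 0.0, 1.0], atol=1e-12)

    def test_static_acceleration_norm_is_one_g(self):
        sp = hb.SpeciesProfile(
            species="test",
            behaviours=(
                hb.BehaviourProfile("standing", pitch_deg=10.0, roll_deg=5.0),
                hb.BehaviourProfile("resting", pitch_deg=-20.0, roll_deg=15.0),
            ),
            individual_sd=0.0,
        )
        cfg = _noiseless_config(sp)
        stream, _ = hb.generate_stream(sp, _flat_individual(), cfg, seed=0)
        assert np.allclose(np.linalg.norm(stream.acc, axis=1), 1.0, atol=1e-12)

    def test_uphill_slope_tilts_surge_axis(self):
        """Walking on a +10 deg slope shows as +10 deg of device pitch."""
        sp = two_behaviour_species(slope_repertoire=(hb.core.SLOPE_UPHILL,))
        cfg = _noiseless_config(
            sp, slope_angle_ranges={hb.core.SLOPE_UPHILL: (10.0, 10.0)}
        )
        stream, intervals = hb.generate_stream(sp, _flat_individual(), cfg, seed=0)
        iv = intervals_to_frame(intervals)
        walking = iv[iv["behaviour"] == "walking"]
        assert not walking.empty
        t = stream.time
        for _, row in walking.iterrows():
            mask = (t >= row.start_s) & (t < row.end_s)
            # mean over whole strides cancels the gait oscillation
            mean_pitch = np.degrees(
                np.arcsin(np.clip(stream.acc[mask, 0], -1, 1))
            ).mean()
            assert row.slope == "uphill"
            assert row.slope_angle_deg == pytest.approx(10.0)
            assert mean_pitch == pytest.approx(10.0, abs=1.0)

    def test_closed_form_rotation_inverts(self):
        g = gravity_device_frame(12.0, 7.0)
        pitch, roll = hb.posture_angles(g.reshape(1, 3))
        assert pitch[0] == pytest.approx(12.0, abs=1e-9)
        expected_roll = np.degrees(np.arcsin(np.sin(np.radians(7.0)) * np.cos(np.radians(12.0))))
        assert roll[0] == pytest.approx(expected_roll, abs=1e-9)

    def test_same_seed_is_bit_identical(self):
        sp = two_behaviour_species()
        cfg = _noiseless_config(sp, accel_noise_sd_g=0.02, mag_noise_sd=0.01)
        s1, iv1 = hb.generate_stream(sp, _flat_individual(), cfg, seed=9)
        s2, iv2 = hb.generate_stream(sp, _flat_individual(), cfg, seed=9)
        pd.testing.assert_frame_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(intervals_to_frame(iv1), intervals_to_frame(iv2))
        s3, _ = hb.generate_stream(sp, _flat_individual(), cfg, seed=10)
        assert not s1.data.equals(s3.data)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            hb.SimulationConfig(total_duration_s=0.0)


class TestIntervalTiling:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_intervals_partition_every_stream(self, seed):
        cfg = hb.SimulationConfig(
            n_individuals={"ibex": 2, "goat": 2}, total_duration_s=200.0, seed=seed
        )
        cohort = hb.generate_cohort(cfg)
        for sid, g in cohort.intervals.groupby("individual_id"):
            g = g.sort_values("start_s")
            assert g["start_s"].iloc[0] == 0.0
            assert g["end_s"].iloc[-1] == pytest.approx(200.0)
            np.testing.assert_allclose(
                g["start_s"].iloc[1:].to_numpy(), g["end_s"].iloc[:-1].to_numpy()
            )

    def test_slope_category_consistent_with_angle(self, small_cohort):
        iv = small_cohort.intervals
        loco = iv[iv["slope"].notna()]
        assert not loco.empty
        for _, row in loco.iterrows():
            assert slope_category(row.slope_angle_deg) == row.slope
        assert iv.loc[iv["slope"].isna(), "slope_angle_deg"].isna().all()


class TestGenerateCohort:
    def test_default_cohort_has_fifteen_streams(self):
        cfg = hb.SimulationConfig(total_duration_s=30.0, seed=0)
        cohort = hb.generate_cohort(cfg)
        assert len(cohort.streams) == 15
        assert sorted(cohort.individuals["species"].value_counts().to_dict().items()) == [
            ("goat", 9), ("ibex", 6)
        ]

    def test_zero_individual_sd_gives_identical_profiles(self):
        sp = two_behaviour_species(species="goat")
        cfg = hb.SimulationConfig(
            species_profiles=(sp,), n_individuals={"goat": 4},
            sexes={"goat": ("female",) * 4}, total_duration_s=30.0, seed=1,
        )
        cohort = hb.generate_cohort(cfg)
        ind = cohort.individuals
        for col in ["stride_scale", "amp_scale", "pitch_offset_deg", "roll_offset_deg"]:
            assert ind[col].nunique() == 1

    def test_cohort_seed_determinism(self):
        cfg = hb.SimulationConfig(
            n_individuals={"ibex": 2, "goat": 1}, total_duration_s=60.0, seed=5
        )
        c1, c2 = hb.generate_cohort(cfg), hb.generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.intervals, c2.intervals)
        for s1, s2 in zip(c1.streams, c2.streams):
            pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_stride_scale_shifts_dominant_gait_frequency(self):
        """A 0.6x stride-scaled species walks at 0.6x the dominant frequency."""
        def walk_freq(stride_scale):
            sp = two_behaviour_species(species="s", stride_scale=stride_scale)
            cfg = hb.SimulationConfig(
                species_profiles=(sp,), n_individuals={"s": 1},
                sexes={"s": ("female",)}, total_duration_s=300.0,
                bout_median_s=40.0, accel_noise_sd_g=0.0, mag_noise_sd=0.0, seed=2,
            )
            cohort = hb.generate_cohort(cfg)
            stream = cohort.streams[0]
            iv = cohort.intervals
            peaks = []
            for _, row in iv[iv["behaviour"] == "walking"].iterrows():
                mask = (stream.time >= row.start_s) & (stream.time < row.end_s)
                z = stream.acc[mask, 2]
                if mask.sum() < 400:
                    continue
                f, p = periodogram(z - z.mean(), fs=stream.sample_rate_hz)
                peaks.append(f[np.argmax(p)])
            return np.mean(peaks)

        ratio = walk_freq(0.6) / walk_freq(1.0)
        assert ratio == pytest.approx(0.6, rel=0.15)


class TestRealismCheck:
    def _cohort_from_intervals(self, iv: pd.DataFrame) -> hb.Cohort:
        return hb.Cohort(streams=[], intervals=iv, individuals=pd.DataFrame(),
                         config=hb.SimulationConfig())

    def test_uniform_shares_flag_standing_as_under_represented(self):
        from hoofbeat.ethogram import IBEX, reference_ethogram
        names = hb.default_ibex().behaviour_names
        iv = pd.DataFrame(
            {
                "individual_id": "i1", "species": IBEX, "sex": "female",
                "start_s": np.arange(len(names)) * 10.0,
                "end_s": (np.arange(len(names)) + 1) * 10.0,
                "behaviour": names, "slope": None, "slope_angle_deg": None,
            }
        )
        target = reference_ethogram()
        report = hb.ethogram_realism_check(
            self._cohort_from_intervals(iv), target[target["species"] == IBEX]
        )
        standing = report[report["behaviour"] == "standing"].iloc[0]
        assert standing["target_s"] == pytest.approx(8714.1)
        assert standing["discrepancy"] < 0
        assert standing["flagged"]

    def test_matching_shares_have_zero_discrepancy(self, small_cohort):
        iv = small_cohort.intervals.copy()
        iv["duration_s"] = iv["end_s"] - iv["start_s"]
        target = (
            iv.groupby(["species", "behaviour"], as_index=False)["duration_s"]
            .sum().rename(columns={"duration_s": "total_s"})
        )
        report = hb.ethogram_realism_check(small_cohort, target)
        assert np.allclose(report["discrepancy"], 0.0, atol=1e-12)
        assert not report["flagged"].any()

    def test_hand_built_shares_match_manual_sums(self):
        iv = pd.DataFrame(
            {
                "individual_id": ["a", "a", "a"], "species": "goat", "sex": "female",
                "start_s": [0.0, 30.0, 40.0], "end_s": [30.0, 40.0, 60.0],
                "behaviour": ["standing", "walking", "eating"],
                "slope": [None, "flat", None], "slope_angle_deg": [None, 0.0, None],
            }
        )
        target = pd.DataFrame(
            {"species": ["goat"] * 3, "behaviour": ["standing", "walking", "eating"],
             "total_s": [30.0, 10.0, 20.0]}
        )
        report = hb.ethogram_realism_check(self._cohort_from_intervals(iv), target)
        shares = report.set_index("behaviour")["simulated_share"]
        assert shares["standing"] == pytest.approx(0.5)
        assert shares["walking"] == pytest.approx(10 / 60)
        assert shares["eating"] == pytest.approx(20 / 60)

    def test_unknown_target_behaviour_raises(self, small_cohort):
        target = pd.DataFrame(
            {"species": ["ibex"], "behaviour": ["flying"], "total_s": [10.0]}
        )
        with pytest.raises(KeyError, match="flying"):
            hb.ethogram_realism_check(small_cohort, target)


class TestProfiles:
    def test_static_behaviour_amplitude_capped(self):
        with pytest.raises(ValueError):
            hb.BehaviourProfile("weird", stride_hz=0.0, amp_g=(0.5, 0.0, 0.0))

    def test_individual_scales_positive(self):
        with pytest.raises(ValueError):
            hb.IndividualProfile("x", "goat", "female", stride_scale=0.0)

    def test_sex_effect_applies_to_draws(self):
        sp = hb.default_ibex()
        rng = np.random.default_rng(0)
        zero_sd = hb.SpeciesProfile(
            species=sp.species, behaviours=sp.behaviours, stride_scale=sp.stride_scale,
            individual_sd=0.0, sex_effects=sp.sex_effects,
        )
        male = draw_individual(zero_sd, "m", "male", rng)
        female = draw_individual(zero_sd, "f", "female", rng)
        assert male.stride_scale < female.stride_scale
        assert male.amp_scale > female.amp_scale
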