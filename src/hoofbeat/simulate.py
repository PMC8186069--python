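"""Synthetic biologging simulator.

Generates labelled tri-axial accelerometer + magnetometer streams with the
statistical structure a posture/gait behaviour classifier relies on:

* static acceleration = gravity seen in the device frame, set by behaviour
  posture (pitch/roll), individual posture offsets, and — for locomotion —
  the terrain slope angle added to pitch (uphill positive);
* dynamic acceleration = per-axis sinusoid at the behaviour's stride
  frequency plus one 2x harmonic, with heave leading surge by 90 degrees;
* magnetometry = a fixed local field vector seen through the same orientation,
  with a bounded per-behaviour heading random walk, so heading dynamics carry
  information the accelerometer lacks;
* i.i.d. Gaussian sensor noise on every channel.

Orientation convention: intrinsic heading-about-vertical, pitch-about-sway,
roll-about-surge.  With pitch p and roll r the device-frame gravity vector is
``(sin p, cos p sin r, cos p cos r)`` in (surge, sway, heave) — so the
pitch/roll estimators in :mod:`hoofbeat.features` invert it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    SENSOR_COLUMNS,
    SLOPE_CATEGORIES,
    SLOPE_DOWNHILL,
    SLOPE_FLAT,
    SLOPE_UPHILL,
    BehaviourInterval,
    SensorStream,
    intervals_to_frame,
    slope_category,
)
from .profiles import (
    BehaviourProfile,
    IndividualProfile,
    SpeciesProfile,
    default_species_profiles,
    draw_individual,
)

_DEG = math.pi / 180.0

#: default sexes per simulated cohort (mirrors 6 ibex incl. 2 trained males,
#: and 9 female zoo goats)
DEFAULT_SEXES = {
    "ibex": ("male", "male", "female", "female", "female", "female"),
    "goat": ("female",) * 9,
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the zoo deployments the reference ethogram comes from:
    40 Hz sampling, 6 ibex-like + 9 goat-like individuals, behaviour mix
    weighted by the reference ethogram shares, log-normal bout durations.
    """

    species_profiles: tuple[SpeciesProfile, ...] = field(default_factory=default_species_profiles)
    n_individuals: dict[str, int] = field(default_factory=lambda: {"ibex": 6, "goat": 9})
    sexes: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_SEXES))
    total_duration_s: float = 1800.0
    bout_median_s: float = 15.0
    bout_sigma: float = 0.7
    sample_rate_hz: float = 40.0
    accel_noise_sd_g: float = 0.02
    mag_noise_sd: float = 0.01
    local_field_vector: tuple[float, float, float] = (0.4, 0.0, 0.5)
    #: gait amplitude effort factors on (uphill, downhill) terrain
    slope_effort: tuple[float, float] = (1.1, 0.9)
    #: scale of the slope-angle contribution to pitch (0 removes the postural
    #: slope signature while keeping slope labels, for ablation experiments)
    slope_pitch_effect: float = 1.0
    #: |angle| draw ranges per slope category, degrees
    slope_angle_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            SLOPE_FLAT: (0.0, 2.5),
            SLOPE_UPHILL: (4.0, 12.0),
            SLOPE_DOWNHILL: (4.0, 12.0),
        }
    )
    #: mix fraction of uniform behaviour weights blended into ethogram shares
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.accel_noise_sd_g < 0 or self.mag_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be > 0")

    def species(self, name: str) -> SpeciesProfile:
        for sp in self.species_profiles:
            if sp.species == name:
                return sp
        raise KeyError(f"no species profile named {name!r}")


@dataclass
class Cohort:
    """Streams + labelled intervals for all individuals of all species."""

    streams: list[SensorStream]
    intervals: pd.DataFrame
    individuals: pd.DataFrame
    config: SimulationConfig

    def stream(self, individual_id: str) -> SensorStream:
        for s in self.streams:
            if s.individual_id == individual_id:
                return s
        raise KeyError(individual_id)

    @property
    def species(self) -> list[str]:
        return sorted(self.individuals["species"].unique())


def gravity_device_frame(pitch_deg: np.ndarray, roll_deg: np.ndarray) -> np.ndarray:
    """Device-frame unit gravity vector for given pitch/roll (degrees)."""
    p = np.asarray(pitch_deg, dtype=float) * _DEG
    r = np.asarray(roll_deg, dtype=float) * _DEG
    return np.stack(
        [np.sin(p), np.cos(p) * np.sin(r), np.cos(p) * np.cos(r)], axis=-1
    )


def field_device_frame(
    field_vector: np.ndarray,
    heading_deg: np.ndarray,
    pitch_deg: float,
    roll_deg: float,
) -> np.ndarray:
    """World field vector seen in the device frame.

    Applies the inverse of the intrinsic heading(Z) - pitch(Y) - roll(X)
    rotation sample-wise; ``heading_deg`` may be a vector.
    """
    mx, my, mz = (float(v) for v in np.asarray(field_vector, dtype=float))
    psi = np.asarray(heading_deg, dtype=float) * _DEG
    p = pitch_deg * _DEG
    r = roll_deg * _DEG
    # undo heading (rotate world field by -heading about vertical)
    c, s = np.cos(psi), np.sin(psi)
    x1 = c * mx + s * my
    y1 = -s * mx + c * my
    z1 = np.full_like(x1, mz)
    # undo pitch
    cp, sp = math.cos(p), math.sin(p)
    x2 = cp * x1 + sp * z1
    z2 = -sp * x1 + cp * z1
    # undo roll
    cr, sr = math.cos(r), math.sin(r)
    y3 = cr * y1 + sr * z2
    z3 = -sr * y1 + cr * z2
    return np.stack([x2, y3, z3], axis=-1)


def _draw_bouts(
    species: SpeciesProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[BehaviourProfile, str | None, float, float]]:
    """Tile the stream with bouts: (behaviour, slope category, angle, duration).

    The first bouts cycle once through the full repertoire (shuffled) so every
    behaviour is represented for every individual; subsequent bouts are drawn
    with ethogram-share weights, preserving the observed imbalance regime.
    """
    names = list(species.behaviour_names)
    weights = np.array([species.behaviour(n).weight for n in names], dtype=float)
    weights = weights / weights.sum()
    mu = math.log(config.bout_median_s)

    order = list(rng.permutation(names))
    bouts: list[tuple[BehaviourProfile, str | None, float, float]] = []
    total = 0.0
    while total < config.total_duration_s:
        name = order.pop(0) if order else str(rng.choice(names, p=weights))
        prof = species.behaviour(name)
        duration = float(np.exp(rng.normal(mu, config.bout_sigma)))
        duration = max(duration, 4.0)  # bouts long enough to hold whole windows
        duration = min(duration, config.total_duration_s - total)
        if duration <= 0:
            break
        slope_cat: str | None = None
        angle = 0.0
        if prof.is_locomotion:
            repertoire = prof.slope_repertoire or species.slope_repertoire
            unknown = set(repertoire) - set(SLOPE_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown slope categories {sorted(unknown)}")
            slope_cat = str(rng.choice(list(repertoire)))
            lo, hi = config.slope_angle_ranges[slope_cat]
            mag = float(rng.uniform(lo, hi))
            if slope_cat == SLOPE_UPHILL:
                angle = mag
            elif slope_cat == SLOPE_DOWNHILL:
                angle = -mag
            else:
                angle = float(rng.uniform(-hi, hi)) if lo == 0.0 else mag
        bouts.append((prof, slope_cat, angle, duration))
        total += duration
    return bouts


def generate_stream(
    species_profile: SpeciesProfile,
    individual_profile: IndividualProfile,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[SensorStream, list[BehaviourInterval]]:
    """Simulate one individual's sensor stream and its labelled intervals.

    The intervals tile the stream exactly (half-open, no gaps or overlaps);
    locomotion intervals carry the slope category consistent with the signed
    slope angle used in the signal.
    """
    if config.total_duration_s <= 0:
        raise ValueError("total_duration_s must be > 0")
    rng = np.random.default_rng(seed)
    rate = config.sample_rate_hz
    n = int(round(config.total_duration_s * rate))
    t = np.arange(n) / rate

    bouts = _draw_bouts(species_profile, config, rng)
    starts = np.cumsum([0.0] + [b[3] for b in bouts])[:-1]
    ends = starts + np.array([b[3] for b in bouts])
    ends[-1] = config.total_duration_s

    acc = np.empty((n, 3))
    mag = np.empty((n, 3))
    intervals: list[BehaviourInterval] = []

    eff = species_profile.sex_effect(individual_profile.sex)
    heading = float(rng.uniform(0.0, 360.0))
    # heading volatility is specified per 40 Hz sample; rescale to this rate
    vol_scale = math.sqrt(40.0 / rate)
    up_effort, down_effort = config.slope_effort

    for (prof, slope_cat, angle, _), start, end in zip(bouts, starts, ends):
        i0 = int(np.searchsorted(t, start - 1e-9, side="left"))
        i1 = int(np.searchsorted(t, end - 1e-9, side="left"))
        m = i1 - i0
        if m <= 0:
            continue
        pitch = (
            prof.pitch_deg
            + individual_profile.pitch_offset_deg
            + angle * config.slope_pitch_effect
        )
        roll = prof.roll_deg + individual_profile.roll_offset_deg
        static = gravity_device_frame(pitch, roll)
        a = np.tile(static, (m, 1))

        if prof.stride_hz > 0:
            f = prof.stride_hz * species_profile.stride_scale * individual_profile.stride_scale
            amp = np.array(prof.amp_g) * species_profile.amp_scale * individual_profile.amp_scale
            if slope_cat == SLOPE_UPHILL:
                amp = amp * up_effort
            elif slope_cat == SLOPE_DOWNHILL:
                amp = amp * down_effort
            tau = np.arange(m) / rate
            phases = np.array([0.0, math.pi, math.pi / 2.0])  # heave leads surge by 90 deg
            arg = 2.0 * math.pi * f * tau[:, None] + phases[None, :]
            a = a + amp[None, :] * (np.sin(arg) + prof.harmonic_ratio * np.sin(2.0 * arg))

        # bounded heading random walk: AR(1) pull toward the bout's start
        # heading, h_k = base + 0.98 (h_{k-1} - base) + eps_k
        steps = rng.normal(0.0, prof.heading_volatility * vol_scale, size=m)
        h = heading + lfilter([1.0], [1.0, -0.98], steps)
        heading = float(h[-1])

        mag[i0:i1] = field_device_frame(config.local_field_vector, h, pitch, roll)
        acc[i0:i1] = a

        intervals.append(
            BehaviourInterval(
                individual_id=individual_profile.individual_id,
                species=individual_profile.species,
                sex=individual_profile.sex,
                start_s=float(start),
                end_s=float(end),
                behaviour=prof.name,
                slope=slope_cat,
                slope_angle_deg=angle if slope_cat is not None else None,
            )
        )

    if config.accel_noise_sd_g > 0:
        acc = acc + rng.normal(0.0, config.accel_noise_sd_g, size=acc.shape)
    if config.mag_noise_sd > 0:
        mag = mag + rng.normal(0.0, config.mag_noise_sd, size=mag.shape)

    data = pd.DataFrame(
        np.column_stack([t, acc, mag]), columns=SENSOR_COLUMNS
    )
    stream = SensorStream(
        individual_id=individual_profile.individual_id,
        species=individual_profile.species,
        sex=individual_profile.sex,
        sample_rate_hz=rate,
        data=data,
    )
    return stream, intervals


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate all individuals of all configured species.

    One master seed; per-individual child seeds are derived deterministically
    from the individual's global index, so cohorts are reproducible and any
    single stream can be regenerated in isolation.
    """
    streams: list[SensorStream] = []
    all_intervals: list[BehaviourInterval] = []
    individuals: list[dict] = []
    idx = 0
    for sp in config.species_profiles:
        n_ind = config.n_individuals.get(sp.species, 0)
        if n_ind < 1:
            continue
        sexes = config.sexes.get(sp.species, ("female",) * n_ind)
        for j in range(n_ind):
            sex = sexes[j % len(sexes)]
            ind_id = f"{sp.species}{j + 1:02d}"
            profile_rng = np.random.default_rng([int(config.seed), idx, 0])
            ind = draw_individual(sp, ind_id, sex, profile_rng)
            stream, intervals = generate_stream(
                sp, ind, config, np.random.SeedSequence([int(config.seed), idx, 1])
            )
            streams.append(stream)
            all_intervals.extend(intervals)
            individuals.append(
                {
                    "individual_id": ind_id,
                    "species": sp.species,
                    "sex": sex,
                    "stride_scale": ind.stride_scale,
                    "amp_scale": ind.amp_scale,
                    "pitch_offset_deg": ind.pitch_offset_deg,
                    "roll_offset_deg": ind.roll_offset_deg,
                }
            )
            idx += 1
    return Cohort(
        streams=streams,
        intervals=intervals_to_frame(all_intervals),
        individuals=pd.DataFrame(individuals),
        config=config,
    )


def ethogram_realism_check(
    cohort: Cohort,
    target_ethogram: pd.DataFrame,
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """Compare simulated behaviour-duration shares against a target ethogram.

    ``target_ethogram`` needs columns species, behaviour, total_s (slope-merged).
    Returns one row per (species, behaviour) with simulated and target time
    shares; rows whose share discrepancy exceeds ``flag_threshold`` in absolute
    value are flagged (negative discrepancy = under-represented).
    """
    repertoires = {sp.species: set(sp.behaviour_names) for sp in cohort.config.species_profiles}
    for _, row in target_ethogram.iterrows():
        rep = repertoires.get(row["species"])
        if rep is not None and row["behaviour"] not in rep:
            raise KeyError(
                f"target behaviour {row['behaviour']!r} absent from "
                f"{row['species']} simulator repertoire"
            )

    iv = cohort.intervals.copy()
    iv["duration_s"] = iv["end_s"] - iv["start_s"]
    sim = iv.groupby(["species", "behaviour"], as_index=False)["duration_s"].sum()
    sim["simulated_share"] = sim.groupby("species")["duration_s"].transform(
        lambda x: x / x.sum()
    )
    tgt = target_ethogram.copy()
    tgt["target_share"] = tgt.groupby("species")["total_s"].transform(lambda x: x / x.sum())
    out = pd.merge(
        sim.rename(columns={"duration_s": "simulated_s"}),
        tgt[["species", "behaviour", "total_s", "target_share"]].rename(
            columns={"total_s": "target_s"}
        ),
        on=["species", "behaviour"],
        how="outer",
    ).fillna({"simulated_s": 0.0, "simulated_share": 0.0, "target_s": 0.0, "target_share": 0.0})
    out["discrepancy"] = out["simulated_share"] - out["target_share"]
    out["flagged"] = out["discrepancy"].abs() > flag_threshold
    return out.sort_values(["species", "behaviour"]).reset_index(drop=True)
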