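"""Behaviour, individual and species profiles for the synthetic simulator.

The repertoire mirrors a caprid ethogram: three static postural behaviours
(standing, resting, eating), feeding on hind legs (browsing, goats only),
three maintenance/social behaviours (aggression, grooming, shaking) and
gaited locomotion (walking, trotting, running, plus climbing for ibex).
Locomotion behaviours are slope-modulated.

Per-behaviour signal parameters (postures, stride frequencies, amplitudes,
heading volatilities) are stipulated: the source observations report durations
only, not signal statistics, so values are chosen to be mechanically plausible
for collar-mounted tags (postural tilt separating static behaviours, gait
frequency/amplitude increasing from walk to run, vigorous high-frequency
shaking) — see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ethogram
from .core import SLOPE_CATEGORIES, SLOPE_DOWNHILL, SLOPE_FLAT, SLOPE_UPHILL

#: dynamic amplitude (g) above which a behaviour cannot be called static
STATIC_AMP_LIMIT_G = 0.05


@dataclass(frozen=True)
class BehaviourProfile:
    """Signal model parameters of one behaviour.

    ``stride_hz`` is the fundamental oscillation frequency (0 for static
    behaviours, which emit no deterministic dynamic signal); ``amp_g`` the
    per-axis (surge, sway, heave) dynamic amplitude; ``harmonic_ratio`` the
    relative amplitude of the 2x-frequency harmonic; ``heading_volatility``
    the sd (degrees/sample at 40 Hz) of the bounded heading random walk.
    """

    name: str
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    stride_hz: float = 0.0
    amp_g: tuple[float, float, float] = (0.0, 0.0, 0.0)
    harmonic_ratio: float = 0.0
    heading_volatility: float = 0.5
    is_locomotion: bool = False
    weight: float = 1.0
    slope_repertoire: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.stride_hz < 0:
            raise ValueError("stride_hz must be >= 0")
        if any(a < 0 for a in self.amp_g):
            raise ValueError("amp_g components must be >= 0")
        if self.stride_hz == 0 and any(a > STATIC_AMP_LIMIT_G for a in self.amp_g):
            raise ValueError(
                f"static behaviour {self.name!r} must have amp_g <= {STATIC_AMP_LIMIT_G} g"
            )
        if self.slope_repertoire is not None:
            unknown = set(self.slope_repertoire) - set(SLOPE_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown slope categories {sorted(unknown)}")


@dataclass(frozen=True)
class SexEffect:
    """Multiplicative morphology shift applied to one sex (dimorphism)."""

    stride_scale: float = 1.0
    amp_scale: float = 1.0
    pitch_offset_deg: float = 0.0


@dataclass(frozen=True)
class IndividualProfile:
    """Per-individual deviation from the species-level signal model."""

    individual_id: str
    species: str
    sex: str
    stride_scale: float = 1.0
    amp_scale: float = 1.0
    pitch_offset_deg: float = 0.0
    roll_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.stride_scale <= 0 or self.amp_scale <= 0:
            raise ValueError("stride_scale and amp_scale must be > 0")


@dataclass(frozen=True)
class SpeciesProfile:
    """Species-level repertoire and morphology.

    ``stride_scale`` encodes limb-length differences (short-legged animals
    cycle faster); ``individual_sd`` the sd of individual log-scales (and,
    scaled, of individual posture offsets); ``sex_effects`` optional per-sex
    morphology shifts for dimorphic species.
    """

    species: str
    behaviours: tuple[BehaviourProfile, ...]
    stride_scale: float = 1.0
    amp_scale: float = 1.0
    individual_sd: float = 0.15
    slope_repertoire: tuple[str, ...] = SLOPE_CATEGORIES
    sex_effects: dict[str, SexEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.behaviours) < 2:
            raise ValueError("species needs at least two behaviours")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")
        names = [b.name for b in self.behaviours]
        if len(set(names)) != len(names):
            raise ValueError("duplicate behaviour names in repertoire")

    def behaviour(self, name: str) -> BehaviourProfile:
        for b in self.behaviours:
            if b.name == name:
                return b
        raise KeyError(f"behaviour {name!r} not in {self.species} repertoire")

    @property
    def behaviour_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviours)

    def sex_effect(self, sex: str) -> SexEffect:
        return self.sex_effects.get(sex, SexEffect())


# -- default repertoires -----------------------------------------------------

# Shared caprid behaviours. Postures are device pitch/roll in degrees (head
# down while grazing tips the collar nose-down; browsing on hind legs tips it
# up; resting animals lie with the collar rolled).  Heading volatilities make
# magnetometry informative: active behaviours turn more.
_BASE_BEHAVIOURS: dict[str, BehaviourProfile] = {
    b.name: b
    for b in [
        BehaviourProfile("standing", pitch_deg=0.0, roll_deg=0.0, stride_hz=0.0,
                         amp_g=(0.005, 0.005, 0.005), heading_volatility=0.2),
        BehaviourProfile("resting", pitch_deg=-15.0, roll_deg=12.0, stride_hz=0.0,
                         amp_g=(0.003, 0.003, 0.003), heading_volatility=0.05),
        BehaviourProfile("eating", pitch_deg=-35.0, roll_deg=0.0, stride_hz=1.1,
                         amp_g=(0.05, 0.04, 0.06), harmonic_ratio=0.3,
                         heading_volatility=0.6),
        BehaviourProfile("browsing", pitch_deg=30.0, roll_deg=0.0, stride_hz=0.9,
                         amp_g=(0.06, 0.04, 0.07), harmonic_ratio=0.3,
                         heading_volatility=0.5),
        BehaviourProfile("aggression", pitch_deg=5.0, roll_deg=0.0, stride_hz=2.2,
                         amp_g=(0.35, 0.25, 0.45), harmonic_ratio=0.5,
                         heading_volatility=2.5),
        BehaviourProfile("grooming", pitch_deg=-20.0, roll_deg=25.0, stride_hz=1.6,
                         amp_g=(0.12, 0.10, 0.12), harmonic_ratio=0.3,
                         heading_volatility=0.4),
        BehaviourProfile("shaking", pitch_deg=0.0, roll_deg=0.0, stride_hz=7.5,
                         amp_g=(0.5, 0.7, 0.5), harmonic_ratio=0.2,
                         heading_volatility=1.5),
        BehaviourProfile("walking", pitch_deg=0.0, roll_deg=0.0, stride_hz=1.4,
                         amp_g=(0.18, 0.10, 0.28), harmonic_ratio=0.4,
                         heading_volatility=0.8, is_locomotion=True),
        BehaviourProfile("trotting", pitch_deg=0.0, roll_deg=0.0, stride_hz=2.4,
                         amp_g=(0.38, 0.18, 0.55), harmonic_ratio=0.35,
                         heading_volatility=0.5, is_locomotion=True),
        BehaviourProfile("running", pitch_deg=0.0, roll_deg=0.0, stride_hz=3.3,
                         amp_g=(0.65, 0.30, 0.95), harmonic_ratio=0.3,
                         heading_volatility=0.6, is_locomotion=True),
        BehaviourProfile("climbing", pitch_deg=0.0, roll_deg=0.0, stride_hz=1.1,
                         amp_g=(0.30, 0.22, 0.40), harmonic_ratio=0.4,
                         heading_volatility=1.2, is_locomotion=True,
                         slope_repertoire=(SLOPE_UPHILL, SLOPE_DOWNHILL)),
    ]
}


def _weighted_repertoire(species: str, names: list[str]) -> tuple[BehaviourProfile, ...]:
    shares = ethogram.behaviour_shares(species)
    return tuple(
        replace(_BASE_BEHAVIOURS[n], weight=float(shares[n])) for n in names
    )


def default_ibex() -> SpeciesProfile:
    """Alpine-ibex-like species: long-legged, sexually dimorphic, climbs."""
    names = ["standing", "resting", "eating", "aggression", "grooming", "shaking",
             "walking", "trotting", "running", "climbing"]
    return SpeciesProfile(
        species=ethogram.IBEX,
        behaviours=_weighted_repertoire(ethogram.IBEX, names),
        stride_scale=1.0,
        amp_scale=1.0,
        individual_sd=0.15,
        sex_effects={"male": SexEffect(stride_scale=0.85, amp_scale=1.3, pitch_offset_deg=6.0)},
    )


def default_goat() -> SpeciesProfile:
    """Pygmy-goat-like species: short-legged (faster stride), browses."""
    names = ["standing", "resting", "eating", "browsing", "aggression", "grooming",
             "shaking", "walking", "trotting", "running"]
    return SpeciesProfile(
        species=ethogram.GOAT,
        behaviours=_weighted_repertoire(ethogram.GOAT, names),
        stride_scale=1.45,
        amp_scale=0.8,
        individual_sd=0.15,
    )


def default_species_profiles() -> tuple[SpeciesProfile, SpeciesProfile]:
    return (default_ibex(), default_goat())


def draw_individual(
    species_profile: SpeciesProfile,
    individual_id: str,
    sex: str,
    rng: np.random.Generator,
) -> IndividualProfile:
    """Draw one individual's deviations from the species-level model.

    Stride and amplitude scales are log-normal around the species (and sex)
    baseline; posture offsets are Gaussian with sd proportional to
    ``individual_sd`` (30 deg/unit for pitch, 20 deg/unit for roll).
    """
    sd = species_profile.individual_sd
    eff = species_profile.sex_effect(sex)
    return IndividualProfile(
        individual_id=individual_id,
        species=species_profile.species,
        sex=sex,
        stride_scale=float(np.exp(rng.normal(0.0, sd))) * eff.stride_scale,
        amp_scale=float(np.exp(rng.normal(0.0, sd))) * eff.amp_scale,
        pitch_offset_deg=float(rng.normal(0.0, 30.0 * sd)) + eff.pitch_offset_deg,
        roll_offset_deg=float(rng.normal(0.0, 20.0 * sd)),
    )
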