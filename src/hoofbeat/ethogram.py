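"""Reference ethogram for captive Alpine ibex and pygmy goats.

Published observation totals (seconds per species and behaviour, with
locomotion behaviours subdivided by terrain slope) from video-annotated zoo
deployments of collar tags.  The simulator uses these shares as its bout-mix
target, and the down-sampling threshold used for class balancing is the median
of the pooled per-(species, behaviour) totals.

Ibex were never observed browsing (their food was on the floor); goats were
never observed climbing (no climbing structures in their enclosures).
"""
from __future__ import annotations

import math

import pandas as pd

IBEX = "ibex"
GOAT = "goat"

# (species, behaviour, total_s): per-behaviour observation totals as
# published (locomotion totals undivided).
_TOTALS = [
    (IBEX, "standing", 8714.1),
    (IBEX, "resting", 6165.9),
    (IBEX, "eating", 8104.7),
    (IBEX, "aggression", 590.7),
    (IBEX, "grooming", 242.7),
    (IBEX, "shaking", 164.0),
    (IBEX, "walking", 6027.7),
    (IBEX, "trotting", 327.1),
    (IBEX, "running", 332.9),
    (IBEX, "climbing", 338.4),
    (GOAT, "standing", 8665.3),
    (GOAT, "resting", 7863.6),
    (GOAT, "eating", 13295.9),
    (GOAT, "browsing", 1953.5),
    (GOAT, "aggression", 296.9),
    (GOAT, "grooming", 428.5),
    (GOAT, "shaking", 57.8),
    (GOAT, "walking", 5952.8),
    (GOAT, "trotting", 530.1),
    (GOAT, "running", 254.8),
]

# Slope subdivision of the locomotion behaviours.  The parts were published
# independently rounded, so they match the undivided totals only to within
# 0.1 s.
_SLOPE_RECORDS = [
    (IBEX, "walking", "flat", 4704.2),
    (IBEX, "walking", "uphill", 668.4),
    (IBEX, "walking", "downhill", 655.2),
    (IBEX, "trotting", "flat", 264.9),
    (IBEX, "trotting", "uphill", 20.7),
    (IBEX, "trotting", "downhill", 41.4),
    (IBEX, "running", "flat", 259.2),
    (IBEX, "running", "uphill", 34.0),
    (IBEX, "running", "downhill", 39.7),
    (IBEX, "climbing", "uphill", 160.0),
    (IBEX, "climbing", "downhill", 178.4),
    (GOAT, "walking", "flat", 4544.3),
    (GOAT, "walking", "uphill", 649.0),
    (GOAT, "walking", "downhill", 759.6),
    (GOAT, "trotting", "flat", 433.9),
    (GOAT, "trotting", "uphill", 28.2),
    (GOAT, "trotting", "downhill", 68.1),
    (GOAT, "running", "flat", 240.9),
    (GOAT, "running", "uphill", 9.2),
    (GOAT, "running", "downhill", 4.7),
]


def reference_ethogram(by_slope: bool = False) -> pd.DataFrame:
    """Reference observation totals per species and behaviour.

    Parameters
    ----------
    by_slope:
        Return the slope subdivisions of the locomotion behaviours instead of
        the undivided per-behaviour totals.
    """
    if by_slope:
        return pd.DataFrame(
            _SLOPE_RECORDS, columns=["species", "behaviour", "slope", "total_s"]
        )
    return pd.DataFrame(_TOTALS, columns=["species", "behaviour", "total_s"])


def behaviour_shares(species: str) -> pd.Series:
    """Fraction of observed time per behaviour for one species (sums to 1)."""
    df = reference_ethogram()
    df = df[df["species"] == species]
    if df.empty:
        raise KeyError(f"unknown species {species!r}")
    totals = df.set_index("behaviour")["total_s"]
    return totals / totals.sum()


def slope_shares(species: str, behaviour: str) -> pd.Series | None:
    """Fraction of a locomotion behaviour's time per slope category, or None."""
    df = reference_ethogram(by_slope=True)
    df = df[(df["species"] == species) & (df["behaviour"] == behaviour) & df["slope"].notna()]
    if df.empty:
        return None
    totals = df.set_index("slope")["total_s"]
    return totals / totals.sum()


def observation_total_minutes(species: str) -> int:
    """Total observed minutes for one species (floored to whole minutes)."""
    df = reference_ethogram()
    total_s = df.loc[df["species"] == species, "total_s"].sum()
    if total_s == 0:
        raise KeyError(f"unknown species {species!r}")
    return math.floor(total_s / 60.0)


def pooled_class_totals() -> pd.Series:
    """The pooled per-(species, behaviour) totals in seconds.

    Locomotion behaviours enter undivided (summed over slope), giving one
    total per species x behaviour combination across both species.
    """
    df = reference_ethogram()
    return df.set_index(["species", "behaviour"])["total_s"]
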