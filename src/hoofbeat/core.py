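"""Core containers and conventions shared across the pipeline.

Device frame follows the collar convention: x = surge (forward-back),
y = sway (left-right), z = heave (up-down).  Acceleration is in g,
magnetometry in arbitrary field units, time in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SENSOR_COLUMNS = ["time_s", "acc_x_g", "acc_y_g", "acc_z_g", "mag_x", "mag_y", "mag_z"]
ACC_COLUMNS = ["acc_x_g", "acc_y_g", "acc_z_g"]
MAG_COLUMNS = ["mag_x", "mag_y", "mag_z"]
INTERVAL_COLUMNS = ["individual_id", "species", "sex", "start_s", "end_s", "behaviour", "slope"]

#: metadata columns of a feature table; everything else is a feature.
META_COLUMNS = ["window_start_s", "individual_id", "species", "sex", "behaviour", "slope"]

SLOPE_FLAT = "flat"
SLOPE_UPHILL = "uphill"
SLOPE_DOWNHILL = "downhill"
SLOPE_CATEGORIES = (SLOPE_FLAT, SLOPE_UPHILL, SLOPE_DOWNHILL)

#: terrain is "flat" within +/- 2.5 degrees; steeper is uphill/downhill.
SLOPE_THRESHOLD_DEG = 2.5


def slope_category(angle_deg: float) -> str:
    """Categorise a signed terrain slope angle (uphill positive)."""
    if angle_deg > SLOPE_THRESHOLD_DEG:
        return SLOPE_UPHILL
    if angle_deg < -SLOPE_THRESHOLD_DEG:
        return SLOPE_DOWNHILL
    return SLOPE_FLAT


def child_seed(seed: int, *keys: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SensorStream:
    """Uniformly sampled tri-axial acceleration + magnetometry for one individual."""

    individual_id: str
    species: str
    sex: str
    sample_rate_hz: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SENSOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"sensor data missing columns: {missing}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        t = self.data["time_s"].to_numpy()
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, rtol=1e-6, atol=1e-6):
                raise ValueError("timestamps must be uniformly spaced at 1/sample_rate_hz")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) acceleration in g, columns surge/sway/heave."""
        return self.data[ACC_COLUMNS].to_numpy()

    @property
    def mag(self) -> np.ndarray:
        """(n, 3) magnetometer reading, device frame."""
        return self.data[MAG_COLUMNS].to_numpy()

    def with_data(self, data: pd.DataFrame, sample_rate_hz: float | None = None) -> "SensorStream":
        return SensorStream(
            individual_id=self.individual_id,
            species=self.species,
            sex=self.sex,
            sample_rate_hz=self.sample_rate_hz if sample_rate_hz is None else sample_rate_hz,
            data=data.reset_index(drop=True),
        )


@dataclass
class BehaviourInterval:
    """Half-open time span [start_s, end_s) labelled with one behaviour.

    ``slope`` is set only for locomotion behaviours; ``slope_angle_deg`` keeps
    the signed angle the simulator actually used (in-memory only, not part of
    the interval CSV interface).
    """

    individual_id: str
    species: str
    sex: str
    start_s: float
    end_s: float
    behaviour: str
    slope: str | None = None
    slope_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("interval must have positive duration")
        if self.slope is not None and self.slope not in SLOPE_CATEGORIES:
            raise ValueError(f"unknown slope category {self.slope!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def intervals_to_frame(intervals: Iterable[BehaviourInterval]) -> pd.DataFrame:
    """Flatten intervals into a long-format DataFrame (keeps slope_angle_deg)."""
    rows = [
        {
            "individual_id": iv.individual_id,
            "species": iv.species,
            "sex": iv.sex,
            "start_s": iv.start_s,
            "end_s": iv.end_s,
            "behaviour": iv.behaviour,
            "slope": iv.slope,
            "slope_angle_deg": iv.slope_angle_deg,
        }
        for iv in intervals
    ]
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS + ["slope_angle_deg"])


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table (everything non-meta)."""
    extra = [c for c in table.columns if c not in META_COLUMNS and c != "label"]
    return extra


def class_labels(table: pd.DataFrame, include_slope: bool = False) -> pd.Series:
    """Classification target labels for a feature table.

    With ``include_slope`` locomotion rows become ``behaviour_slope`` classes
    (e.g. ``walking_uphill``), mirroring slope-subdivided ethograms.
    """
    labels = table["behaviour"].astype(str).copy()
    if include_slope and "slope" in table.columns:
        has_slope = table["slope"].notna()
        labels[has_slope] = labels[has_slope] + "_" + table.loc[has_slope, "slope"].astype(str)
    return labels
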