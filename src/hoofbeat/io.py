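"""CSV / YAML / JSON interfaces.

Sensor CSV: ``time_s, acc_x_g, acc_y_g, acc_z_g, mag_x, mag_y, mag_z`` (one
file per individual, header mandatory).  Interval CSV: ``individual_id,
species, sex, start_s, end_s, behaviour, slope`` with half-open intervals and
``NA`` slope for non-locomotion rows.  Cohorts live in a directory with one
sensor + one interval file per individual plus a JSON manifest.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import INTERVAL_COLUMNS, SENSOR_COLUMNS, SensorStream
from .dataset import SplitPlan
from .features import FeatureDefinition
from .simulate import Cohort, SimulationConfig


def write_sensor_csv(stream: SensorStream, path: str | Path) -> None:
    stream.data[SENSOR_COLUMNS].to_csv(path, index=False)


def read_sensor_csv(
    path: str | Path, individual_id: str, species: str, sex: str
) -> SensorStream:
    data = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"{path}: missing sensor columns {missing}")
    t = data["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return SensorStream(
        individual_id=individual_id, species=species, sex=sex,
        sample_rate_hz=round(rate, 6), data=data,
    )


def write_intervals_csv(intervals: pd.DataFrame, path: str | Path) -> None:
    out = intervals[INTERVAL_COLUMNS].copy()
    out["slope"] = out["slope"].fillna("NA")
    out.to_csv(path, index=False)


def read_intervals_csv(path: str | Path) -> pd.DataFrame:
    iv = pd.read_csv(path)
    missing = [c for c in INTERVAL_COLUMNS if c not in iv.columns]
    if missing:
        raise ValueError(f"{path}: missing interval columns {missing}")
    iv["slope"] = iv["slope"].replace("NA", np.nan)
    return iv


def write_cohort(cohort: Cohort, out_dir: str | Path, force: bool = False) -> Path:
    """Write one sensor + one interval CSV per individual plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force to overwrite)")
    manifest = {
        "sample_rate_hz": cohort.config.sample_rate_hz,
        "seed": cohort.config.seed,
        "individuals": [],
    }
    for stream in cohort.streams:
        sid = stream.individual_id
        write_sensor_csv(stream, out / f"{sid}_sensor.csv")
        iv = cohort.intervals[cohort.intervals["individual_id"] == sid]
        write_intervals_csv(iv, out / f"{sid}_intervals.csv")
        manifest["individuals"].append(
            {"individual_id": sid, "species": stream.species, "sex": stream.sex}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort_streams(in_dir: str | Path) -> tuple[list[SensorStream], pd.DataFrame]:
    """Load the streams and pooled intervals of a cohort directory."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    streams = []
    intervals = []
    for ind in manifest["individuals"]:
        sid = ind["individual_id"]
        streams.append(
            read_sensor_csv(d / f"{sid}_sensor.csv", sid, ind["species"], ind["sex"])
        )
        intervals.append(read_intervals_csv(d / f"{sid}_intervals.csv"))
    return streams, pd.concat(intervals, ignore_index=True)


def write_registry_yaml(registry: Sequence[FeatureDefinition], path: str | Path) -> None:
    payload = [dataclasses.asdict(d) for d in registry]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_registry_yaml(path: str | Path) -> list[FeatureDefinition]:
    payload = yaml.safe_load(Path(path).read_text())
    return [FeatureDefinition(**d) for d in payload]


def write_split_plan(plan: SplitPlan, path: str | Path) -> None:
    payload = {
        "design": plan.design,
        "fold": plan.fold,
        "fraction": plan.fraction,
        "train_ids": np.asarray(plan.train_ids).tolist(),
        "validation_ids": np.asarray(plan.validation_ids).tolist(),
        "train_individuals": list(plan.train_individuals),
        "validation_individuals": list(plan.validation_individuals),
    }
    Path(path).write_text(json.dumps(payload))


def read_split_plan(path: str | Path) -> SplitPlan:
    payload = json.loads(Path(path).read_text())
    return SplitPlan(
        design=payload["design"],
        train_ids=np.asarray(payload["train_ids"]),
        validation_ids=np.asarray(payload["validation_ids"]),
        fold=payload["fold"],
        fraction=payload["fraction"],
        train_individuals=tuple(payload["train_individuals"]),
        validation_individuals=tuple(payload["validation_individuals"]),
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file.

    Unknown keys raise a validation error naming the key; species profiles
    use the package defaults (the YAML overrides scalar conditions only).
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)} - {"species_profiles"}
    unknown = set(payload) - valid
    if unknown:
        raise KeyError(f"unknown simulation config keys: {sorted(unknown)}")
    if "sexes" in payload:
        payload["sexes"] = {k: tuple(v) for k, v in payload["sexes"].items()}
    if "local_field_vector" in payload:
        payload["local_field_vector"] = tuple(payload["local_field_vector"])
    if "slope_effort" in payload:
        payload["slope_effort"] = tuple(payload["slope_effort"])
    if "slope_angle_ranges" in payload:
        payload["slope_angle_ranges"] = {
            k: tuple(v) for k, v in payload["slope_angle_ranges"].items()
        }
    return SimulationConfig(**payload)
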