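"""Accelerometry and magnetometry feature derivation.

The classifier's predictors follow the standard collar-tag recipe: raw
acceleration is split into a *static* part (centred running mean per axis,
reflecting posture relative to gravity) and a *dynamic* part (raw minus
static, reflecting body movement).  From these come posture angles (pitch and
roll), VeDBA (the Euclidean norm of the three dynamic axes) and its smoothed
variant, per-window summary statistics of each axis, the dominant oscillation
amplitude per axis (periodogram peak over a 2 s window), and five
magnetometry variables (per-axis variability plus two full-body-rotation
proxies on the combined field vector).

Features are computed over consecutive non-overlapping windows (2 s by
default); each window is labelled by the behaviour interval that fully
contains it, and windows straddling an interval boundary are dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ACC_COLUMNS,
    MAG_COLUMNS,
    META_COLUMNS,
    BehaviourInterval,
    SensorStream,
    intervals_to_frame,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 2.0


def _smoothing_samples(sample_rate_hz: float, window_s: float) -> int:
    """Centred running-mean width in samples: forced odd, minimum 3."""
    w = int(round(window_s * sample_rate_hz))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    return w


def decompose_static_dynamic(
    acc: np.ndarray, sample_rate_hz: float, window_s: float = DEFAULT_WINDOW_S
) -> tuple[np.ndarray, np.ndarray]:
    """Split acceleration into static (posture) and dynamic (movement) parts.

    Static is the centred running mean per axis over ``window_s`` (edges
    handled by shrinking the window); dynamic is raw minus static, so
    ``static + dynamic == raw`` exactly at every sample.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    w = _smoothing_samples(sample_rate_hz, window_s)
    if len(acc) < w:
        raise ValueError(
            f"stream of {len(acc)} samples is shorter than one "
            f"{w}-sample smoothing window"
        )
    static = (
        pd.DataFrame(acc).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    return static, acc - static


def vedba(dynamic: np.ndarray) -> np.ndarray:
    """Per-sample vectorial dynamic body acceleration (norm of dynamic axes)."""
    return np.linalg.norm(np.atleast_2d(np.asarray(dynamic, dtype=float)), axis=1)


def smoothed_vedba(
    dynamic: np.ndarray, sample_rate_hz: float, window_s: float = DEFAULT_WINDOW_S
) -> np.ndarray:
    """smVeDBA: running mean of the VeDBA series over the feature window."""
    v = vedba(dynamic)
    w = _smoothing_samples(sample_rate_hz, window_s)
    return pd.Series(v).rolling(w, center=True, min_periods=1).mean().to_numpy()


def posture_angles(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and roll (degrees) from the static acceleration vector.

    pitch = arcsin(static surge / |static|), roll = arcsin(static sway /
    |static|); both in [-90, 90].  Raises on zero-norm static vectors, whose
    orientation is undefined.
    """
    static = np.atleast_2d(np.asarray(static, dtype=float))
    norm = np.linalg.norm(static, axis=1)
    if np.any(norm <= 0):
        raise ValueError("zero-norm static acceleration: orientation undefined")
    pitch = np.degrees(np.arcsin(np.clip(static[:, 0] / norm, -1.0, 1.0)))
    roll = np.degrees(np.arcsin(np.clip(static[:, 1] / norm, -1.0, 1.0)))
    return pitch, roll


def _window_matrix(x: np.ndarray, samples_per_window: int) -> np.ndarray:
    n_win = len(x) // samples_per_window
    return np.asarray(x, dtype=float)[: n_win * samples_per_window].reshape(
        n_win, samples_per_window
    )


def _dominant_amplitude(windows: np.ndarray) -> np.ndarray:
    """Amplitude of the dominant non-zero-frequency periodogram component.

    Operates row-wise on an (m, n) matrix of mean-removed windows; returns the
    sinusoid-equivalent amplitude (2|X_k|/n, Nyquist term |X|/n).
    """
    m, n = windows.shape
    centred = windows - windows.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(centred, axis=1))
    amps = 2.0 * spec / n
    if n % 2 == 0:  # Nyquist bin is not doubled
        amps[:, -1] = spec[:, -1] / n
    if amps.shape[1] <= 1:
        return np.zeros(m)
    return amps[:, 1:].max(axis=1)


def oscillation_amplitude(
    series: np.ndarray, sample_rate_hz: float, window_s: float = DEFAULT_WINDOW_S
) -> np.ndarray:
    """Dominant oscillation amplitude per non-overlapping window of one axis.

    Windows hold ``round(window_s * sample_rate_hz)`` samples; at least 2 are
    required (at very low rates only the Nyquist component is resolvable,
    which is exactly how low sampling rates degrade gait information).
    """
    spw = int(round(window_s * sample_rate_hz))
    if spw < 2:
        raise ValueError("window must contain at least 2 samples")
    series = np.asarray(series, dtype=float)
    if len(series) < spw:
        raise ValueError("series shorter than one window")
    return _dominant_amplitude(_window_matrix(series, spw))


def magnetometry_features(
    mag: np.ndarray, sample_rate_hz: float, window_s: float = DEFAULT_WINDOW_S
) -> pd.DataFrame:
    """Five magnetometry variables per non-overlapping window.

    Per-axis windowed standard deviations, the windowed sd of the field-vector
    norm, and the mean angular change per sample (radians) of the normalised
    field vector — a proxy for full-body rotation.
    """
    mag = np.atleast_2d(np.asarray(mag, dtype=float))
    spw = int(round(window_s * sample_rate_hz))
    if spw < 2:
        raise ValueError("window must contain at least 2 samples")
    norms = np.linalg.norm(mag, axis=1)
    if np.any(norms <= 0):
        raise ValueError("zero-norm magnetometer sample: degenerate field")
    unit = mag / norms[:, None]
    dots = np.clip(np.einsum("ij,ij->i", unit[:-1], unit[1:]), -1.0, 1.0)
    angle = np.concatenate([[0.0], np.arccos(dots)])  # first sample has no step

    out = {}
    for i, name in enumerate(["mag_sd_x", "mag_sd_y", "mag_sd_z"]):
        out[name] = _window_matrix(mag[:, i], spw).std(axis=1)
    out["mag_norm_sd"] = _window_matrix(norms, spw).std(axis=1)
    W = _window_matrix(angle, spw)
    # drop each window's leading placeholder step
    out["mag_angle_change"] = W[:, 1:].mean(axis=1) if spw > 1 else W.mean(axis=1)
    return pd.DataFrame(out)


def subsample(stream: SensorStream, target_hz: float) -> SensorStream:
    """Decimate a stream to ``target_hz`` (must divide the native rate).

    Keeps every (rate/target)-th sample starting at the first; subsampling
    happens before any feature derivation in the pipeline.
    """
    ratio = stream.sample_rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"target rate {target_hz} Hz does not divide {stream.sample_rate_hz} Hz"
        )
    k = int(round(ratio))
    if k == 1:
        return stream
    return stream.with_data(stream.data.iloc[::k], sample_rate_hz=target_hz)


# -- feature registry --------------------------------------------------------


@dataclass(frozen=True)
class FeatureDefinition:
    """One named feature: where it comes from and how it is computed."""

    name: str
    source_channel: str  # acc_x|acc_y|acc_z|acc|mag_x|mag_y|mag_z|mag|derived
    kind: str  # static | dynamic | posture | energy | magnetometry
    window_s: float = DEFAULT_WINDOW_S
    formula_id: str = ""

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not self.formula_id:
            object.__setattr__(self, "formula_id", self.name)


def default_registry(window_s: float = DEFAULT_WINDOW_S) -> list[FeatureDefinition]:
    """The 39-variable candidate registry.

    Per acceleration axis: static mean and sd, dynamic mean/sd/min/max/range
    and mean absolute value, and the dominant oscillation amplitude (psd1_*).
    Whole-body: pitch, roll, VeDBA mean/sd/max, smoothed VeDBA, ODBA.  Plus
    the five magnetometry variables.
    """
    defs: list[FeatureDefinition] = []
    axes = {"x": "acc_x", "y": "acc_y", "z": "acc_z"}
    for ax, src in axes.items():
        defs.append(FeatureDefinition(f"static_{ax}", src, "static", window_s))
        defs.append(FeatureDefinition(f"static_sd_{ax}", src, "static", window_s))
    for ax, src in axes.items():
        for stat in ["mean", "sd", "min", "max", "range", "absmean"]:
            defs.append(FeatureDefinition(f"dyn_{stat}_{ax}", src, "dynamic", window_s))
    for ax, src in axes.items():
        defs.append(FeatureDefinition(f"psd1_{ax}", src, "energy", window_s))
    defs.append(FeatureDefinition("pitch", "acc", "posture", window_s))
    defs.append(FeatureDefinition("roll", "acc", "posture", window_s))
    for name in ["vedba_mean", "vedba_sd", "vedba_max", "smvedba", "odba_mean"]:
        defs.append(FeatureDefinition(name, "acc", "energy", window_s))
    for ax in ["x", "y", "z"]:
        defs.append(FeatureDefinition(f"mag_sd_{ax}", f"mag_{ax}", "magnetometry", window_s))
    defs.append(FeatureDefinition("mag_norm_sd", "mag", "magnetometry", window_s))
    defs.append(FeatureDefinition("mag_angle_change", "mag", "magnetometry", window_s))
    names = [d.name for d in defs]
    assert len(names) == 39 and len(set(names)) == 39
    return defs


def registry_names(registry: Sequence[FeatureDefinition]) -> list[str]:
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in registry")
    return names


def drop_magnetometry(registry: Sequence[FeatureDefinition]) -> list[FeatureDefinition]:
    """Registry restricted to accelerometry-only variables."""
    return [d for d in registry if d.kind != "magnetometry"]


def _compute_all_window_features(
    stream: SensorStream, window_s: float, smoothing_window_s: float
) -> pd.DataFrame:
    rate = stream.sample_rate_hz
    spw = int(round(window_s * rate))
    if spw < 2:
        raise ValueError("window must contain at least 2 samples")
    acc = stream.acc
    static, dynamic = decompose_static_dynamic(acc, rate, smoothing_window_s)
    pitch, roll = posture_angles(static)
    v = vedba(dynamic)
    smv = smoothed_vedba(dynamic, rate, smoothing_window_s)
    odba = np.abs(dynamic).sum(axis=1)

    out: dict[str, np.ndarray] = {}
    for i, ax in enumerate(["x", "y", "z"]):
        W = _window_matrix(static[:, i], spw)
        out[f"static_{ax}"] = W.mean(axis=1)
        out[f"static_sd_{ax}"] = W.std(axis=1)
        D = _window_matrix(dynamic[:, i], spw)
        out[f"dyn_mean_{ax}"] = D.mean(axis=1)
        out[f"dyn_sd_{ax}"] = D.std(axis=1)
        out[f"dyn_min_{ax}"] = D.min(axis=1)
        out[f"dyn_max_{ax}"] = D.max(axis=1)
        out[f"dyn_range_{ax}"] = out[f"dyn_max_{ax}"] - out[f"dyn_min_{ax}"]
        out[f"dyn_absmean_{ax}"] = np.abs(D).mean(axis=1)
        out[f"psd1_{ax}"] = _dominant_amplitude(D)
    out["pitch"] = _window_matrix(pitch, spw).mean(axis=1)
    out["roll"] = _window_matrix(roll, spw).mean(axis=1)
    V = _window_matrix(v, spw)
    out["vedba_mean"] = V.mean(axis=1)
    out["vedba_sd"] = V.std(axis=1)
    out["vedba_max"] = V.max(axis=1)
    out["smvedba"] = _window_matrix(smv, spw).mean(axis=1)
    out["odba_mean"] = _window_matrix(odba, spw).mean(axis=1)

    mag_df = magnetometry_features(stream.mag, rate, window_s)
    for c in mag_df.columns:
        out[c] = mag_df[c].to_numpy()
    return pd.DataFrame(out)


def compute_feature_table(
    stream: SensorStream,
    intervals: Iterable[BehaviourInterval] | pd.DataFrame,
    registry: Sequence[FeatureDefinition] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    smoothing_window_s: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Windowed, labelled feature table for one stream.

    Consecutive non-overlapping windows of ``window_s``; a window is kept only
    if it lies entirely inside one behaviour interval (label assignment by
    containment; boundary-straddling windows are dropped and logged).
    """
    if registry is None:
        registry = default_registry(window_s)
    names = registry_names(registry)
    if not names:
        raise ValueError("empty feature registry")

    if isinstance(intervals, pd.DataFrame):
        iv = intervals[intervals["individual_id"] == stream.individual_id]
    else:
        iv = intervals_to_frame(
            [i for i in intervals if i.individual_id == stream.individual_id]
        )
    iv = iv.sort_values("start_s").reset_index(drop=True)
    if iv.empty:
        raise ValueError(f"no intervals for individual {stream.individual_id!r}")

    feats = _compute_all_window_features(stream, window_s, smoothing_window_s)
    unknown = set(names) - set(feats.columns)
    if unknown:
        raise KeyError(f"registry features without a formula: {sorted(unknown)}")

    n_win = len(feats)
    t0 = stream.time[0]
    win_start = t0 + np.arange(n_win) * window_s
    win_end = win_start + window_s
    starts = iv["start_s"].to_numpy()
    ends = iv["end_s"].to_numpy()
    mid = win_start + window_s / 2.0
    idx = np.searchsorted(starts, mid, side="right") - 1
    idx = np.clip(idx, 0, len(iv) - 1)
    eps = 1e-9
    contained = (starts[idx] <= win_start + eps) & (win_end <= ends[idx] + eps)
    n_drop = int((~contained).sum())
    if n_drop:
        logger.debug(
            "%s: dropped %d/%d boundary-straddling windows",
            stream.individual_id, n_drop, n_win,
        )
    shortest = (iv["end_s"] - iv["start_s"]).min()
    if shortest < window_s:
        logger.warning(
            "%s: shortest interval (%.2f s) shorter than window (%.2f s); "
            "windows inside it are dropped", stream.individual_id, shortest, window_s,
        )

    keep = np.where(contained)[0]
    kept_iv = iv.iloc[idx[keep]]
    table = pd.DataFrame(
        {
            "window_start_s": win_start[keep],
            "individual_id": stream.individual_id,
            "species": stream.species,
            "sex": stream.sex,
            "behaviour": kept_iv["behaviour"].to_numpy(),
            "slope": kept_iv["slope"].to_numpy(),
        }
    )
    for name, formula in zip(names, (d.formula_id for d in registry)):
        table[name] = feats[formula].to_numpy()[keep]
    return table.reset_index(drop=True)


def cohort_feature_table(
    cohort,
    registry: Sequence[FeatureDefinition] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    target_hz: float | None = None,
    smoothing_window_s: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Concatenated feature table for every stream of a cohort.

    With ``target_hz`` streams are decimated first (decimate-then-derive is
    the fixed pipeline order).
    """
    tables = []
    for stream in cohort.streams:
        s = subsample(stream, target_hz) if target_hz else stream
        tables.append(
            compute_feature_table(
                s, cohort.intervals, registry=registry, window_s=window_s,
                smoothing_window_s=smoothing_window_s,
            )
        )
    return pd.concat(tables, ignore_index=True)
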