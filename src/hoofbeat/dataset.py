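"""Dataset assembly: ethogram summaries, class balancing, behaviour
reduction, and the two train/validation split designs.

Two split designs are supported.  The *random* design splits feature-table
rows 60/40 stratified by behaviour, so every individual contributes to both
sides (consecutive windows are autocorrelated, which inflates this design's
accuracy — deliberately left as-is, since that is the property the
individual-split comparison exposes).  The *per-individual* design places
whole individuals on one side only, enumerating all individual subsets whose
row share is within a tolerance band of the training fraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .core import child_seed

DEFAULT_DROP_BEHAVIOURS = ("aggression", "grooming", "shaking")


@dataclass
class SplitPlan:
    """One train/validation partition of a feature table's rows."""

    design: str  # "random" | "per_individual"
    train_ids: np.ndarray
    validation_ids: np.ndarray
    fold: int = 0
    fraction: float = 0.6
    train_individuals: tuple[str, ...] = ()
    validation_individuals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        train = set(np.asarray(self.train_ids).tolist())
        val = set(np.asarray(self.validation_ids).tolist())
        if train & val:
            raise ValueError("train and validation rows overlap")
        if self.design == "per_individual" and set(self.train_individuals) & set(
            self.validation_individuals
        ):
            raise ValueError("per-individual split shares individuals across sides")


def ethogram_summary(
    intervals: pd.DataFrame, by_slope: bool = False
) -> pd.DataFrame:
    """Observation totals per (species, behaviour[, slope]).

    ``total_s`` sums over all individuals; ``mean_s``/``sd_s`` are computed
    across the per-individual totals of the individuals that displayed the
    behaviour (sample sd, 0 for a single individual).
    """
    iv = intervals.copy()
    iv["duration_s"] = iv["end_s"] - iv["start_s"]
    keys = ["species", "behaviour"] + (["slope"] if by_slope else [])
    per_ind = iv.groupby(keys + ["individual_id"], dropna=False, sort=False)[
        "duration_s"
    ].sum()
    grouped = per_ind.groupby(keys, dropna=False, sort=False)
    out = pd.DataFrame(
        {
            "total_s": grouped.sum(),
            "mean_s": grouped.mean(),
            "sd_s": grouped.std(ddof=1).fillna(0.0),
        }
    ).reset_index()
    return out


def median_duration_threshold(summary: pd.DataFrame) -> float:
    """Median of the pooled per-(species, behaviour) total durations.

    Locomotion behaviours enter as their undivided totals (slope merged);
    the result is the down-sampling threshold for class balancing.
    """
    if summary.empty:
        raise ValueError("empty ethogram summary")
    df = summary
    if "slope" in df.columns:
        df = df.groupby(["species", "behaviour"], as_index=False)["total_s"].sum()
    return float(np.median(df["total_s"].to_numpy()))


def balance_classes(
    table: pd.DataFrame,
    threshold_s: float,
    seed: int = 0,
    label_col: str = "behaviour",
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Randomly down-sample majority classes to about ``threshold_s``.

    Classes whose total labelled duration (rows x window) exceeds the
    threshold lose whole windows uniformly at random; classes at or below it
    are untouched.  Seeded and reproducible; never increases any class.
    """
    if threshold_s <= 0:
        raise ValueError("threshold_s must be > 0")
    rng = np.random.default_rng(seed)
    max_rows = int(np.floor(threshold_s / window_s))
    kept = []
    for label, group in table.groupby(label_col, sort=True):
        if len(group) * window_s > threshold_s:
            sel = rng.choice(group.index.to_numpy(), size=max_rows, replace=False)
            kept.append(np.sort(sel))
        else:
            kept.append(group.index.to_numpy())
    keep_idx = np.sort(np.concatenate(kept))
    return table.loc[keep_idx]


def reduce_behaviours(
    table: pd.DataFrame,
    drop_list: Sequence[str] = DEFAULT_DROP_BEHAVIOURS,
    label_col: str = "behaviour",
) -> pd.DataFrame:
    """Remove behaviours deemed less ethologically relevant.

    Unknown names in ``drop_list`` raise (guards typos); dropping every class
    raises too.
    """
    present = set(table[label_col].unique())
    unknown = set(drop_list) - present
    if unknown:
        raise KeyError(f"behaviours not present in table: {sorted(unknown)}")
    out = table[~table[label_col].isin(set(drop_list))]
    if out.empty:
        raise ValueError("all behaviour classes dropped")
    return out


def split_random(
    table: pd.DataFrame,
    fraction: float = 0.6,
    seed: int = 0,
    label_col: str = "behaviour",
) -> SplitPlan:
    """Stratified-by-behaviour random row split at ``fraction`` training share."""
    labels = table[label_col]
    counts = labels.value_counts()
    singles = counts[counts < 2]
    if not singles.empty:
        raise ValueError(
            f"classes with a single row cannot be split: {sorted(singles.index)}"
        )
    idx = table.index.to_numpy()
    train, val = train_test_split(
        idx,
        train_size=fraction,
        stratify=labels.to_numpy(),
        random_state=child_seed(seed, 0),
    )
    return SplitPlan(
        design="random",
        train_ids=np.sort(train),
        validation_ids=np.sort(val),
        fraction=fraction,
    )


def split_by_individual(
    table: pd.DataFrame,
    fraction: float = 0.6,
    tolerance: float = 0.10,
    max_folds: int | None = None,
    seed: int = 0,
) -> list[SplitPlan]:
    """All individual-level splits near the target training fraction.

    Enumerates every subset of individuals whose share of rows lies within
    ``tolerance`` of ``fraction``; each admissible subset becomes one fold's
    training side (so a subset and its complement are distinct folds).  If no
    subset is admissible the band widens in 5-point steps with a warning.
    ``max_folds`` caps the list by seeded subsampling.
    """
    counts = table.groupby("individual_id").size()
    individuals = list(counts.index)
    if len(individuals) < 2:
        raise ValueError("individual split needs at least 2 individuals")
    total = counts.sum()

    def admissible(tol: float) -> list[tuple[str, ...]]:
        subsets = []
        for k in range(1, len(individuals)):
            for combo in combinations(individuals, k):
                share = counts[list(combo)].sum() / total
                if abs(share - fraction) <= tol:
                    subsets.append(combo)
        return subsets

    tol = tolerance
    subsets = admissible(tol)
    while not subsets and tol < 1.0:
        tol += 0.05
        warnings.warn(
            f"no individual subset within ±{tolerance:.0%} of {fraction:.0%}; "
            f"widening band to ±{tol:.0%}"
        )
        subsets = admissible(tol)
    if not subsets:
        raise ValueError("no admissible individual split found")

    if max_folds is not None and len(subsets) > max_folds:
        rng = np.random.default_rng(child_seed(seed, 1))
        pick = rng.choice(len(subsets), size=max_folds, replace=False)
        subsets = [subsets[i] for i in np.sort(pick)]

    plans = []
    for fold, combo in enumerate(subsets):
        train_mask = table["individual_id"].isin(combo)
        plans.append(
            SplitPlan(
                design="per_individual",
                train_ids=table.index.to_numpy()[train_mask.to_numpy()],
                validation_ids=table.index.to_numpy()[~train_mask.to_numpy()],
                fold=fold,
                fraction=fraction,
                train_individuals=tuple(combo),
                validation_individuals=tuple(i for i in individuals if i not in combo),
            )
        )
    return plans
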