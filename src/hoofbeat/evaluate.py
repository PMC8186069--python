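"""Model scoring, k-fold aggregation, sampling-frequency sweeps,
cross-species transfer, and the random-label null model.

Per-class metrics are one-vs-rest: precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 their harmonic mean; overall accuracy is the confusion-matrix
trace over the total, reported as a percentage.  Undefined ratios (zero
denominators) are reported as 0 and flagged; classes absent from the
validation side are excluded from the mean F1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .classify import TrainedClassifier, refine_features, train_forest, predict
from .core import child_seed, class_labels, feature_columns
from .features import cohort_feature_table, default_registry, drop_magnetometry


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of observed (rows) vs predicted (columns) labels."""

    labels: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class EvaluationReport:
    """Scores of one fitted model on one validation set."""

    accuracy_pct: float
    per_class: pd.DataFrame  # precision, recall, f1, support, flagged
    f1_mean: float
    f1_sd: float
    n: int
    confusion: ConfusionMatrix | None = None
    metadata: dict = field(default_factory=dict)


def confusion(
    observed: Sequence, predicted: Sequence, labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Exact cross-tabulation of observed vs predicted labels."""
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted labels differ in length")
    if len(observed) == 0:
        raise ValueError("empty label vectors")
    if labels is None:
        labels = sorted(set(observed.tolist()) | set(predicted.tolist()))
    labels = [str(l) for l in labels]
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        counts[index[str(o)], index[str(p)]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def metrics(cm: ConfusionMatrix, accuracy_form: str = "standard") -> EvaluationReport:
    """Score a confusion matrix.

    ``accuracy_form="standard"`` is trace/total (the percentage of correctly
    classified rows).  ``"printed"`` reproduces, for audit purposes, the
    per-class ratio TP over the full one-vs-rest total — an alternative
    formulation occasionally printed in the literature that divides each
    class's true positives by all outcomes; its aggregate is the mean of
    those per-class ratios.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / pr, 0.0)
    flagged = (tp + fp == 0) | (tp + fn == 0)

    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
            "flagged": flagged,
        },
        index=cm.labels,
    )
    if accuracy_form == "standard":
        accuracy = 100.0 * tp.sum() / cm.total
    elif accuracy_form == "printed":
        accuracy = 100.0 * float(np.mean(tp / cm.total))
    else:
        raise ValueError(f"unknown accuracy_form {accuracy_form!r}")

    present = per_class["support"] > 0
    f1_present = per_class.loc[present, "f1"]
    return EvaluationReport(
        accuracy_pct=float(accuracy),
        per_class=per_class,
        f1_mean=float(f1_present.mean()),
        f1_sd=float(f1_present.std(ddof=1)) if present.sum() > 1 else 0.0,
        n=cm.total,
        confusion=cm,
    )


def aggregate_folds(reports: Iterable[EvaluationReport]) -> pd.DataFrame:
    """Unweighted mean and sd of the headline metrics across folds."""
    reports = list(reports)
    if not reports:
        raise ValueError("no fold reports to aggregate")
    rows = pd.DataFrame(
        {
            "accuracy_pct": [r.accuracy_pct for r in reports],
            "f1_mean": [r.f1_mean for r in reports],
        }
    )
    out = pd.DataFrame(
        {"mean": rows.mean(), "sd": rows.std(ddof=1).fillna(0.0)}
    )
    return out


def evaluate_split(
    table: pd.DataFrame,
    plan: ds.SplitPlan,
    n_trees: int = 500,
    seed: int = 0,
    label_col: str = "behaviour",
    features: Sequence[str] | None = None,
) -> EvaluationReport:
    """Train on the plan's training rows, score on its validation rows."""
    train = table.loc[plan.train_ids]
    val = table.loc[plan.validation_ids]
    clf = train_forest(train, n_trees=n_trees, seed=seed, label_col=label_col,
                       features=features)
    pred = predict(clf, val)
    labels = sorted(set(table[label_col].astype(str)))
    report = metrics(confusion(val[label_col].astype(str), pred.astype(str), labels))
    report.metadata = {"design": plan.design, "fold": plan.fold,
                       "n_train": len(train), "n_val": len(val)}
    return report


def evaluate_individual_folds(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    label_col: str = "behaviour",
    features: Sequence[str] | None = None,
    fraction: float = 0.6,
    max_folds: int | None = 10,
) -> tuple[list[EvaluationReport], pd.DataFrame]:
    """All (capped) individual-split folds and their aggregate."""
    plans = ds.split_by_individual(table, fraction=fraction, max_folds=max_folds,
                                   seed=seed)
    reports = [
        evaluate_split(table, p, n_trees=n_trees, seed=child_seed(seed, 100 + p.fold),
                       label_col=label_col, features=features)
        for p in plans
    ]
    return reports, aggregate_folds(reports)


def frequency_sweep(
    cohort,
    frequencies: Sequence[float] = (40, 20, 10, 5, 1),
    magnetometry: Sequence[bool] = (True, False),
    design: str = "random",
    seed: int = 0,
    n_trees: int = 500,
    window_s: float = 2.0,
    refine: bool = False,
    max_folds: int = 5,
    label_col: str = "behaviour",
) -> pd.DataFrame:
    """Run the full pipeline per (species x frequency x magnetometry) cell.

    Each cell: decimate -> derive features -> (optionally refine the feature
    set consistently across species) -> split -> train -> score.  Returns one
    row per cell with accuracy and mean F1 (aggregated over folds for the
    per-individual design).
    """
    base_rate = cohort.streams[0].sample_rate_hz
    for f in frequencies:
        if abs(base_rate / f - round(base_rate / f)) > 1e-9:
            raise ValueError(f"{f} Hz does not divide the base rate {base_rate} Hz")

    rows = []
    for freq in frequencies:
        full = cohort_feature_table(cohort, target_hz=freq, window_s=window_s)
        for mag_on in magnetometry:
            registry = default_registry(window_s)
            if not mag_on:
                registry = drop_magnetometry(registry)
            feats = [d.name for d in registry]
            tables = {
                sp: full[full["species"] == sp].reset_index(drop=True)
                for sp in cohort.species
            }
            selected: Sequence[str] | None = feats
            if refine:
                trace = refine_features(
                    {sp: t for sp, t in tables.items()},
                    seed=child_seed(seed, int(freq), int(mag_on)),
                    features=feats, label_col=label_col,
                )
                selected = trace.selected
            for sp, t in tables.items():
                sp_key = sum(sp.encode())  # stable across processes, unlike hash()
                cell_seed = child_seed(seed, int(freq), int(mag_on), sp_key)
                if design == "random":
                    plan = ds.split_random(t, seed=cell_seed, label_col=label_col)
                    rep = evaluate_split(t, plan, n_trees=n_trees, seed=cell_seed,
                                         label_col=label_col, features=selected)
                    acc, acc_sd = rep.accuracy_pct, 0.0
                    f1m, f1sd = rep.f1_mean, rep.f1_sd
                elif design == "per_individual":
                    _, agg = evaluate_individual_folds(
                        t, n_trees=n_trees, seed=cell_seed, label_col=label_col,
                        features=selected, max_folds=max_folds,
                    )
                    acc, acc_sd = agg.loc["accuracy_pct", "mean"], agg.loc["accuracy_pct", "sd"]
                    f1m, f1sd = agg.loc["f1_mean", "mean"], agg.loc["f1_mean", "sd"]
                else:
                    raise ValueError(f"unknown design {design!r}")
                rows.append(
                    {
                        "species": sp,
                        "frequency_hz": freq,
                        "magnetometry": mag_on,
                        "design": design,
                        "accuracy_pct": acc,
                        "accuracy_sd": acc_sd,
                        "f1_mean": f1m,
                        "f1_sd": f1sd,
                        "n_rows": len(t),
                        "n_features": len(selected),
                    }
                )
    return pd.DataFrame(rows)


def cross_species_transfer(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    shared_behaviours_only: bool = True,
    sex_filter: str | None = None,
    label_col: str = "behaviour",
    n_trees: int = 500,
    seed: int = 0,
    features: Sequence[str] | None = None,
    classifier: TrainedClassifier | None = None,
) -> EvaluationReport:
    """Train on one species, evaluate on another.

    With ``shared_behaviours_only`` both sides are restricted to the label
    intersection (behaviours unobserved in either species are excluded).
    ``sex_filter`` restricts the *test* individuals (sex-specific variant).
    A pre-trained ``classifier`` may be supplied to score several test
    subsets without refitting.
    """
    train = train_table
    test = test_table
    if shared_behaviours_only:
        shared = sorted(set(train[label_col]) & set(test[label_col]))
        if not shared:
            raise ValueError("no behaviours shared between species")
        train = train[train[label_col].isin(shared)]
        test = test[test[label_col].isin(shared)]
    if sex_filter is not None:
        test = test[test["sex"] == sex_filter]
        if test.empty:
            raise ValueError(f"no test individuals of sex {sex_filter!r}")
    if classifier is None:
        classifier = train_forest(train, n_trees=n_trees, seed=seed,
                                  label_col=label_col, features=features)
    pred = predict(classifier, test)
    labels = sorted(set(train[label_col].astype(str)) | set(test[label_col].astype(str)))
    rep = metrics(confusion(test[label_col].astype(str), pred.astype(str), labels))
    rep.metadata = {
        "train_species": sorted(train_table["species"].unique().tolist()),
        "test_species": sorted(test_table["species"].unique().tolist()),
        "sex_filter": sex_filter,
        "n_train": len(train),
        "n_test": len(test),
    }
    return rep


def random_label_null(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    label_col: str = "behaviour",
    fraction: float = 0.6,
) -> EvaluationReport:
    """Chance-level reference: retrain on labels redrawn i.i.d.

    Labels are regenerated with the empirical class proportions, then the
    usual random-split pipeline is run, giving the accuracy expected when the
    sensor signal carries no information about the (random) labels.
    """
    labels = table[label_col].astype(str)
    classes = labels.value_counts(normalize=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for a null model")
    rng = np.random.default_rng(child_seed(seed, 7))
    null = table.copy()
    null[label_col] = rng.choice(classes.index.to_numpy(), size=len(table),
                                 p=classes.to_numpy())
    # re-draw until every class has >= 2 rows so the stratified split is valid
    tries = 0
    while null[label_col].value_counts().min() < 2 and tries < 10:
        null[label_col] = rng.choice(classes.index.to_numpy(), size=len(table),
                                     p=classes.to_numpy())
        tries += 1
    plan = ds.split_random(null, seed=child_seed(seed, 8), label_col=label_col)
    rep = evaluate_split(null, plan, n_trees=n_trees, seed=child_seed(seed, 9),
                         label_col=label_col)
    rep.metadata["null"] = True
    return rep
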