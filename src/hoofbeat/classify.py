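"""Random-forest training and the feature-refinement workflow.

The classifier is a 500-tree random forest (bootstrap per tree, Gini
splitting, square-root feature subsampling at each node) with mean-decrease-
in-Gini importances and out-of-bag error.  Refinement follows the standard
two-stage recipe: correlated variables (|Pearson r| >= 0.70) lose their
less-important member, then recursive feature elimination scores shrinking
candidate subsets with cross-validation and keeps the subset maximising CV
accuracy (ties favour the smaller set).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core import child_seed, feature_columns

DEFAULT_N_TREES = 500


@dataclass
class TrainedClassifier:
    """Fitted forest plus the metadata needed to audit and reuse it."""

    model: RandomForestClassifier
    feature_names: list[str]
    importances: pd.Series  # mean Gini decrease per feature
    oob_error: float
    classes: list[str]
    metadata: dict = field(default_factory=dict)


@dataclass
class PrunedFeature:
    removed: str
    kept: str
    r: float


@dataclass
class RefinementTrace:
    """Record of the feature-refinement pipeline for one model family."""

    candidates: list[str]
    removed_by_correlation: list[PrunedFeature] = field(default_factory=list)
    rfe_sizes: list[int] = field(default_factory=list)
    rfe_scores: list[float] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    @property
    def removed_names(self) -> list[str]:
        return [p.removed for p in self.removed_by_correlation]


def _xy(
    table: pd.DataFrame, label_col: str, features: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(features) if features is not None else feature_columns(table)
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    X = table[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    y = table[label_col].to_numpy()
    return X, y, names


def train_forest(
    table: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    label_col: str = "behaviour",
    features: Sequence[str] | None = None,
    n_jobs: int = 1,
    metadata: dict | None = None,
) -> TrainedClassifier:
    """Fit a bootstrap forest on a labelled feature table.

    Deterministic given ``seed``; requires at least two classes.
    """
    X, y, names = _xy(table, label_col, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training table has a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        max_features="sqrt",
        random_state=child_seed(seed, 0),
        n_jobs=n_jobs,
    )
    with warnings.catch_warnings():
        # tiny training sets can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(X, y)
    return TrainedClassifier(
        model=model,
        feature_names=names,
        importances=pd.Series(model.feature_importances_, index=names),
        oob_error=float(1.0 - model.oob_score_),
        classes=[str(c) for c in model.classes_],
        metadata=dict(metadata or {}),
    )


def predict(classifier: TrainedClassifier, table: pd.DataFrame) -> np.ndarray:
    """Predict one label per row by majority vote over the trees.

    Binding is by feature name, so column order is irrelevant; vote ties are
    broken by class order (lexicographic, as the classes are sorted).
    """
    missing = [c for c in classifier.feature_names if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    X = table[classifier.feature_names].to_numpy(dtype=float)
    return classifier.model.predict(X)


def oob_error_trace(
    classifier: TrainedClassifier, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, pd.Series]:
    """Cumulative out-of-bag error after 1..n_trees trees, plus per-class
    OOB error of the full ensemble.

    For each tree, rows outside its bootstrap sample receive that tree's
    vote; the error after t trees is measured over rows with at least one
    accumulated vote.
    """
    model = classifier.model
    n = len(y)
    classes = np.asarray(model.classes_)
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_idx[v] for v in y])
    votes = np.zeros((n, len(classes)), dtype=np.int32)
    trace = np.empty(len(model.estimators_))
    for t, (est, sampled) in enumerate(zip(model.estimators_, model.estimators_samples_)):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.asarray(sampled)] = False
        if oob_mask.any():
            pred = est.predict(X[oob_mask])
            # trees inside a fitted forest predict encoded class indices
            if pred.dtype.kind in "fiu":
                pred_idx = pred.astype(int)
            else:
                pred_idx = np.array([class_idx[v] for v in pred])
            votes[np.where(oob_mask)[0], pred_idx] += 1
        seen = votes.sum(axis=1) > 0
        if seen.any():
            committee = votes[seen].argmax(axis=1)
            trace[t] = float(np.mean(committee != y_idx[seen]))
        else:
            trace[t] = np.nan
    seen = votes.sum(axis=1) > 0
    committee = np.full(n, -1)
    committee[seen] = votes[seen].argmax(axis=1)
    per_class = {}
    for c, i in class_idx.items():
        mask = (y_idx == i) & seen
        per_class[str(c)] = float(np.mean(committee[mask] != i)) if mask.any() else np.nan
    return trace, pd.Series(per_class)


def _abs_corr(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    if np.isnan(corr).any():
        warnings.warn("constant feature(s): undefined correlations treated as 0")
        corr = np.nan_to_num(corr, nan=0.0)
    return np.abs(corr)


def correlation_prune(
    table: pd.DataFrame,
    importances: pd.Series,
    r_threshold: float = 0.70,
    features: Sequence[str] | None = None,
    corr: pd.DataFrame | None = None,
) -> tuple[list[str], list[PrunedFeature]]:
    """Drop the less-important member of every highly correlated pair.

    Pairs are processed by descending |r|; within a pair the feature with the
    lower mean Gini decrease is removed (importance ties: the lexicographically
    later name goes).  Repeats until the retained set is pairwise |r| below
    the threshold, which also makes the operation idempotent.

    Returns (retained names, removal records).  ``corr`` may supply a
    precomputed |r| matrix (e.g. an elementwise maximum across species so
    both species' models keep a common feature set).
    """
    names = list(features) if features is not None else feature_columns(table)
    for n in names:
        if n not in importances.index:
            raise KeyError(f"no importance for feature {n!r}")
    if corr is not None:
        A = corr.loc[names, names].to_numpy(dtype=float).copy()
        A = np.abs(A)
    else:
        A = _abs_corr(table[names].to_numpy(dtype=float))
    np.fill_diagonal(A, 0.0)

    removed: list[PrunedFeature] = []
    active = np.ones(len(names), dtype=bool)
    while True:
        masked = np.where(np.outer(active, active), A, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        r = masked[i, j]
        if r < r_threshold:
            break
        ni, nj = names[i], names[j]
        imp_i, imp_j = importances[ni], importances[nj]
        if imp_i < imp_j or (imp_i == imp_j and ni > nj):
            drop, keep = i, j
        else:
            drop, keep = j, i
        removed.append(PrunedFeature(removed=names[drop], kept=names[keep], r=float(r)))
        active[drop] = False
    retained = [n for n, a in zip(names, active) if a]
    return retained, removed


def default_candidate_sizes(n_features: int) -> list[int]:
    sizes = [2, 4, 8, 12, 16, 20, 25, 30, 39]
    out = sorted({s for s in sizes if s < n_features} | {n_features})
    return out


def recursive_feature_elimination(
    table: pd.DataFrame,
    candidate_sizes: Sequence[int] | None = None,
    k_folds: int = 3,
    seed: int = 0,
    n_trees: int = 100,
    label_col: str = "behaviour",
    features: Sequence[str] | None = None,
    selection_tolerance: float = 0.01,
) -> tuple[list[int], list[float], list[str]]:
    """Recursive feature elimination with cross-validated subset scoring.

    For each candidate size (descending) the lowest-importance features are
    dropped — importances recomputed from a fresh fit at each step — and the
    remaining subset is scored by stratified k-fold CV accuracy.  The
    smallest subset whose score is within ``selection_tolerance`` of the best
    is selected (exact ties therefore also go to the smaller set); the
    tolerance absorbs CV jitter that would otherwise favour redundant
    features.

    Returns (sizes ascending, CV accuracies aligned to sizes, selected names).
    """
    X, y, names = _xy(table, label_col, features)
    if candidate_sizes is None:
        candidate_sizes = default_candidate_sizes(len(names))
    sizes = sorted(set(int(s) for s in candidate_sizes))
    if sizes[0] < 1:
        raise ValueError("candidate sizes must be >= 1")
    if sizes[-1] > len(names):
        raise ValueError("candidate size exceeds number of features")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")

    def cv_score(subset: list[str]) -> float:
        cols = [names.index(c) for c in subset]
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=child_seed(seed, 2), n_jobs=1,
        )
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=child_seed(seed, 3))
        return float(np.mean(cross_val_score(clf, X[:, cols], y, cv=cv)))

    current = list(names)
    scores_by_size: dict[int, float] = {}
    subset_by_size: dict[int, list[str]] = {}
    for size in sorted(sizes, reverse=True):
        if size < len(current):
            fit = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt",
                random_state=child_seed(seed, 4), n_jobs=1,
            ).fit(X[:, [names.index(c) for c in current]], y)
            imp = pd.Series(fit.feature_importances_, index=current)
            current = list(imp.sort_values(ascending=False).index[:size])
        scores_by_size[size] = cv_score(current)
        subset_by_size[size] = list(current)

    cutoff = max(scores_by_size.values()) - selection_tolerance
    best = min(s for s in sizes if scores_by_size[s] >= cutoff)
    return sizes, [scores_by_size[s] for s in sizes], subset_by_size[best]


def refine_features(
    tables_by_species: dict[str, pd.DataFrame],
    r_threshold: float = 0.70,
    candidate_sizes: Sequence[int] | None = None,
    k_folds: int = 3,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    rfe_n_trees: int = 100,
    label_col: str = "behaviour",
    features: Sequence[str] | None = None,
) -> RefinementTrace:
    """Consistent feature refinement across species.

    Correlation pruning uses the elementwise-max |r| across species and the
    mean of the per-species Gini importances; RFE scores subsets by the mean
    of the per-species CV accuracies.  The result is one shared feature set,
    as required for cross-species prediction.
    """
    species = sorted(tables_by_species)
    any_table = tables_by_species[species[0]]
    names = list(features) if features is not None else feature_columns(any_table)
    trace = RefinementTrace(candidates=list(names))

    imps = []
    corrs = []
    for i, sp in enumerate(species):
        t = tables_by_species[sp]
        clf = train_forest(t, n_trees=n_trees, seed=child_seed(seed, 10 + i),
                           label_col=label_col, features=names)
        imps.append(clf.importances)
        corrs.append(_abs_corr(t[names].to_numpy(dtype=float)))
    mean_imp = pd.concat(imps, axis=1).mean(axis=1)
    max_corr = pd.DataFrame(np.maximum.reduce(corrs), index=names, columns=names)

    retained, removed = correlation_prune(
        any_table, mean_imp, r_threshold=r_threshold, features=names, corr=max_corr
    )
    trace.removed_by_correlation = removed

    if candidate_sizes is None:
        candidate_sizes = default_candidate_sizes(len(retained))
    sizes = sorted(set(int(s) for s in candidate_sizes if s <= len(retained)) | {len(retained)})

    per_species = {}
    for i, sp in enumerate(species):
        s, scores, _ = recursive_feature_elimination(
            tables_by_species[sp], candidate_sizes=sizes, k_folds=k_folds,
            seed=child_seed(seed, 20 + i), n_trees=rfe_n_trees,
            label_col=label_col, features=retained,
        )
        per_species[sp] = dict(zip(s, scores))
    mean_scores = {s: float(np.mean([per_species[sp][s] for sp in species])) for s in sizes}
    cutoff = max(mean_scores.values()) - 0.01
    best = min(s for s in sizes if mean_scores[s] >= cutoff)

    # materialise the shared subset at the winning size from pooled importances
    pooled = pd.concat([tables_by_species[sp] for sp in species], ignore_index=True)
    current = list(retained)
    for size in sorted(sizes, reverse=True):
        if size < best:
            break
        if size < len(current):
            fit = train_forest(pooled, n_trees=rfe_n_trees, seed=child_seed(seed, 30),
                               label_col=label_col, features=current)
            current = list(fit.importances.sort_values(ascending=False).index[:size])
    trace.rfe_sizes = sizes
    trace.rfe_scores = [mean_scores[s] for s in sizes]
    trace.selected = current
    return trace
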