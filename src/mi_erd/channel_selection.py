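"""Data-driven channel selection: ReliefF ranking + nested-subset wrapper.

The procedure mirrors the data-driven selection used for sensorimotor BCI
channels: every feature (one ERD value per channel) receives a ReliefF
weight; features are ranked by descending weight; the d ranked features
define d nested candidate groups (first 1, first 2, ..., all d); each
group is scored by stratified cross-validation accuracy with a fixed fold
assignment; and the group with the highest accuracy wins, ties going to
the smaller group (fewer channels is preferable in BCI hardware terms).

ReliefF here is the standard k-nearest-hits/misses formulation on
range-normalised features with Manhattan distance: for each sample the
weight of feature f is increased by the mean |difference| to its k nearest
misses (other class) and decreased by the mean |difference| to its k
nearest hits (same class), averaged over samples, giving weights in
[-1, 1].  A constant feature has zero range and, by convention, zero
difference and weight 0.

Because the winning accuracy is a maximum over 64 data-dependent
candidates it is optimistically biased; ``outer_cv_selection_accuracy``
re-runs the whole selection inside each outer fold and scores only
held-out trials, providing the honest companion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from mi_erd.data_io import InputError
from mi_erd.classification import ClassifierSpec, fit_spec, resolve_params, make_estimator


@dataclass
class Ranking:
    """Feature indices sorted by ReliefF weight (descending) plus the weights."""

    order: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if sorted(self.order.tolist()) != list(range(len(self.weights))):
            raise InputError("order must be a permutation of all feature indices")


@dataclass
class SelectionResult:
    """Full accuracy-vs-subset-size curve and the selected prefix."""

    ranking: Ranking
    accuracy_curve: np.ndarray
    best_size: int
    selected_features: list[Any]
    selection_accuracy: float
    tuned_params: dict[str, Any] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "subset_size": np.arange(1, len(self.accuracy_curve) + 1),
            "cv_accuracy": self.accuracy_curve,
        })

    def plot(self, ax=None):
        """Accuracy-vs-subset-size curve with the selected size marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = np.arange(1, len(self.accuracy_curve) + 1)
        ax.plot(sizes, self.accuracy_curve, marker=".")
        ax.axvline(self.best_size, ls="--", color="tab:red",
                   label=f"selected size = {self.best_size}")
        ax.set_xlabel("number of ranked features")
        ax.set_ylabel("CV accuracy")
        ax.legend()
        return ax


def relieff_weights(X: np.ndarray, y, k: int = 10) -> np.ndarray:
    """ReliefF feature weights for binary labels.

    For each of the m samples, find its k nearest hits (same class) and k
    nearest misses (other class) under Manhattan distance on
    range-normalised features; then

        w[f] = sum_miss diff(f) / (m k) - sum_hit diff(f) / (m k)

    with diff(f) = |x_f - x'_f| / range(f) and diff = 0 for zero-range
    features.  Weights lie in [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("ReliefF requires at least two classes")
    if len(classes) > 2:
        raise InputError("binary labels required")
    if counts.min() < 2:
        raise InputError("need at least 2 samples per class")
    if k < 1:
        raise InputError("k must be >= 1")
    k_eff = min(k, int(counts.min()) - 1)

    rng_f = np.ptp(X, axis=0)
    safe = np.where(rng_f > 0, rng_f, 1.0)
    Z = (X - X.min(axis=0)) / safe
    Z[:, rng_f == 0] = 0.0  # zero-range features contribute no difference

    # Pairwise Manhattan distances on the normalised features.
    diffs = np.abs(Z[:, None, :] - Z[None, :, :])  # m x m x d
    dist = diffs.sum(axis=2)
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(d)
    same = y[:, None] == y[None, :]
    for i in range(m):
        hit_idx = np.flatnonzero(same[i])
        hit_idx = hit_idx[hit_idx != i]
        miss_idx = np.flatnonzero(~same[i])
        hits = hit_idx[np.argsort(dist[i, hit_idx], kind="stable")[:k_eff]]
        misses = miss_idx[np.argsort(dist[i, miss_idx], kind="stable")[:k_eff]]
        w += diffs[i, misses].sum(axis=0) / (m * k_eff)
        w -= diffs[i, hits].sum(axis=0) / (m * k_eff)
    return w


def rank_features(X: np.ndarray, y, k: int = 10) -> Ranking:
    """ReliefF weights sorted descending (stable ties by feature index)."""
    w = relieff_weights(X, y, k=k)
    order = np.argsort(-w, kind="stable")
    return Ranking(order=order, weights=w)


def nested_groups(ranking: Ranking) -> list[list[int]]:
    """Nested prefixes of the ranking: [first], [first two], ..., [all]."""
    order = ranking.order.tolist()
    if not order:
        raise InputError("empty ranking")
    return [order[: i + 1] for i in range(len(order))]


def _fixed_fold_accuracy(X: np.ndarray, y: np.ndarray, est_template,
                         splits: list[tuple[np.ndarray, np.ndarray]]) -> float:
    correct = 0
    for train, test in splits:
        est = clone(est_template)
        est.fit(X[train], y[train])
        correct += int(np.sum(est.predict(X[test]) == y[test]))
    return correct / len(y)


def optimise_selection(X: np.ndarray, y, classifier_spec: ClassifierSpec,
                       cv_folds: int = 5, seed: int = 0, k_neighbors: int = 10,
                       descriptors: Sequence[Any] | None = None) -> SelectionResult:
    """Evaluate every nested ReliefF prefix by CV accuracy; keep the argmax.

    The fold assignment is fixed once (stratified, shuffled with ``seed``)
    and reused for every candidate group so the 64 accuracies are directly
    comparable.  Hyperparameters are resolved once on the full feature set
    and reused for all groups.  Ties at the maximum go to the smallest
    group.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError("X must be 2-D with at least one feature column")
    if descriptors is None:
        descriptors = list(range(X.shape[1]))
    if len(descriptors) != X.shape[1]:
        raise InputError("one descriptor per feature column required")

    ranking = rank_features(X, y, k=k_neighbors)
    groups = nested_groups(ranking)
    params = resolve_params(X, y, classifier_spec, folds=cv_folds)
    est_template = make_estimator(classifier_spec.kind, params)

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    curve = np.empty(len(groups))
    for i, group in enumerate(groups):
        try:
            curve[i] = _fixed_fold_accuracy(X[:, group], y, est_template, splits)
        except Exception as exc:
            raise RuntimeError(f"classifier failed on subset of size {len(group)}") from exc

    best_idx = int(np.argmax(curve))  # argmax takes the first (= smallest) at ties
    best_group = groups[best_idx]
    return SelectionResult(
        ranking=ranking,
        accuracy_curve=curve,
        best_size=best_idx + 1,
        selected_features=[descriptors[j] for j in best_group],
        selection_accuracy=float(curve[best_idx]),
        tuned_params=params,
    )


def outer_cv_selection_accuracy(X: np.ndarray, y, classifier_spec: ClassifierSpec,
                                cv_folds: int = 5, outer_folds: int = 5,
                                seed: int = 0, k_neighbors: int = 10) -> float:
    """Honest accuracy of the whole selection procedure via an outer CV.

    Ranking, subset-size choice and classifier fitting are all redone
    inside each outer training fold; only held-out trials are scored.
    The gap to ``selection_accuracy`` measures the selection optimism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in outer.split(X, y):
        res = optimise_selection(X[train], y[train], classifier_spec,
                                 cv_folds=cv_folds, seed=seed,
                                 k_neighbors=k_neighbors)
        cols = res.ranking.order[: res.best_size]
        est = make_estimator(classifier_spec.kind, res.tuned_params)
        est.fit(X[train][:, cols], y[train])
        correct += int(np.sum(est.predict(X[test][:, cols]) == y[test]))
    return correct / len(y)
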