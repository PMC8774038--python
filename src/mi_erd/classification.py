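"""Tunable SVM / KNN / decision-tree classifiers and confusion-matrix metrics.

Hyperparameters are chosen to minimise stratified 5-fold cross-validation
misclassification loss, either by seeded random search or by a seeded
Bayesian loop (Gaussian-process surrogate, expected-improvement
acquisition).  Features are standardised with train-fold statistics inside
every fold (SVM and KNN are scale sensitive), via a sklearn Pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from mi_erd.data_io import InputError

logger = logging.getLogger(__name__)

# Search spaces.  Dimensions are either ("log", lo, hi), ("int", lo, hi) or
# ("cat", (choices...)); log dimensions are sampled log-uniformly.
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "SVM": {
        "kernel": ("cat", ("linear", "rbf")),
        "C": ("log", 1e-3, 1e3),
        "gamma": ("log", 1e-4, 1e1),
    },
    "KNN": {
        "n_neighbors": ("int", 1, 30),
        "metric": ("cat", ("euclidean", "manhattan")),
    },
    "TREE": {
        "max_depth": ("int", 1, 20),
        "min_samples_leaf": ("int", 1, 20),
    },
}

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "TREE": {"max_depth": 5, "min_samples_leaf": 1},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its tuning configuration."""

    kind: str = "SVM"
    search_space: dict[str, tuple] | None = None
    tuning_budget: int = 30
    tuning_strategy: str = "bayesian"
    seed: int = 0
    tune: bool = True
    params: dict[str, Any] | None = None  # fixed params when tune is False

    def __post_init__(self) -> None:
        if self.kind not in SEARCH_SPACES:
            raise InputError(f"unknown classifier kind {self.kind!r}")
        if self.tuning_budget < 1:
            raise InputError("tuning budget must be >= 1")
        if self.tuning_strategy not in ("bayesian", "random"):
            raise InputError(f"unknown tuning strategy {self.tuning_strategy!r}")

    @property
    def space(self) -> dict[str, tuple]:
        return self.search_space or SEARCH_SPACES[self.kind]

    def with_params(self, params: dict[str, Any]) -> "ClassifierSpec":
        return replace(self, tune=False, params=dict(params))


@dataclass
class MetricsReport:
    """Binary confusion counts and the derived ratios."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}

    def rounded_percent(self) -> dict[str, str]:
        """Percentages rounded to the nearest integer, AUC to 2 decimals."""
        return {
            "accuracy": f"{round(self.accuracy * 100):d}%",
            "sensitivity": f"{round(self.sensitivity * 100):d}%",
            "specificity": f"{round(self.specificity * 100):d}%",
            "auc": f"{self.auc:.2f}",
        }


def make_estimator(kind: str, params: dict[str, Any] | None = None) -> Pipeline:
    """Standardiser + classifier pipeline for one of SVM / KNN / TREE."""
    params = dict(params or DEFAULT_PARAMS[kind])
    if kind == "SVM":
        if params.get("kernel") == "linear":
            params.pop("gamma", None)
        clf = SVC(**params)
    elif kind == "KNN":
        clf = KNeighborsClassifier(**params)
    elif kind == "TREE":
        clf = DecisionTreeClassifier(random_state=0, **params)
    else:
        raise InputError(f"unknown classifier kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _cv_loss(X: np.ndarray, y: np.ndarray, kind: str, params: dict[str, Any],
             folds: int, seed: int) -> float:
    """Mean stratified K-fold misclassification loss of one parameter set."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = []
    for train, test in cv.split(X, y):
        est = make_estimator(kind, params)
        est.fit(X[train], y[train])
        losses.append(np.mean(est.predict(X[test]) != y[test]))
    return float(np.mean(losses))


def _sample_params(space: dict[str, tuple], rng: np.random.Generator) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, dim in space.items():
        kind = dim[0]
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(dim[1]), np.log(dim[2]))))
        elif kind == "int":
            out[name] = int(rng.integers(dim[1], dim[2] + 1))
        elif kind == "cat":
            out[name] = dim[1][int(rng.integers(len(dim[1])))]
        else:
            raise InputError(f"unknown search dimension type {kind!r}")
    return out


def _encode(space: dict[str, tuple], params: dict[str, Any]) -> np.ndarray:
    """Map a parameter set to [0, 1]^d for the GP surrogate."""
    x = []
    for name, dim in space.items():
        kind = dim[0]
        v = params[name]
        if kind == "log":
            x.append((np.log(v) - np.log(dim[1])) / (np.log(dim[2]) - np.log(dim[1])))
        elif kind == "int":
            x.append((v - dim[1]) / max(dim[2] - dim[1], 1))
        else:
            x.append(dim[1].index(v) / max(len(dim[1]) - 1, 1))
    return np.asarray(x)


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm

    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def tune_hyperparameters(X: np.ndarray, y, spec: ClassifierSpec,
                         folds: int = 5) -> tuple[dict[str, Any], float]:
    """Minimise stratified K-fold CV loss within the tuning budget.

    ``bayesian``: seeded random initialisation (1/3 of the budget, at least
    5 points) followed by GP expected-improvement proposals over candidate
    draws.  ``random``: pure seeded random search.  Both return the best
    (params, loss) found; ties keep the earliest evaluation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] == 0 or np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("degenerate feature matrix (no varying columns); "
                      "returning default hyperparameters", stacklevel=2)
        defaults = dict(DEFAULT_PARAMS[spec.kind])
        return defaults, 1.0
    rng = np.random.default_rng(spec.seed)
    space = spec.space

    evaluated: list[tuple[dict[str, Any], float]] = []
    seen: set[tuple] = set()

    def evaluate(params: dict[str, Any]) -> None:
        key = tuple(params[k] for k in space)
        if key in seen:
            return
        seen.add(key)
        loss = _cv_loss(X, y, spec.kind, params, folds, spec.seed)
        evaluated.append((params, loss))

    n_init = spec.tuning_budget if spec.tuning_strategy == "random" \
        else min(spec.tuning_budget, max(5, spec.tuning_budget // 3))
    for _ in range(n_init):
        evaluate(_sample_params(space, rng))

    if spec.tuning_strategy == "bayesian":
        kernel = ConstantKernel(1.0) * RBF(length_scale=np.full(len(space), 0.3)) \
            + WhiteKernel(noise_level=1e-3)
        while len(evaluated) < spec.tuning_budget:
            Xe = np.array([_encode(space, p) for p, _ in evaluated])
            ye = np.array([l for _, l in evaluated])
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          random_state=spec.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Xe, ye)
            candidates = [_sample_params(space, rng) for _ in range(256)]
            Xc = np.array([_encode(space, p) for p in candidates])
            mu, sd = gp.predict(Xc, return_std=True)
            ei = _expected_improvement(mu, sd, float(ye.min()))
            order = np.argsort(-ei)
            before = len(evaluated)
            for idx in order:
                evaluate(candidates[idx])
                if len(evaluated) > before:
                    break
            if len(evaluated) == before:  # all candidates already seen
                break

    best_params, best_loss = min(evaluated, key=lambda pl: pl[1])
    return dict(best_params), float(best_loss)


def fit_spec(X: np.ndarray, y, spec: ClassifierSpec, folds: int = 5) -> Pipeline:
    """Resolve the spec to a concrete fitted-ready estimator (tuning if asked)."""
    if spec.tune:
        params, _ = tune_hyperparameters(X, y, spec, folds=folds)
    else:
        params = dict(spec.params or DEFAULT_PARAMS[spec.kind])
    return make_estimator(spec.kind, params)


def resolve_params(X: np.ndarray, y, spec: ClassifierSpec,
                   folds: int = 5) -> dict[str, Any]:
    """The hyperparameters the spec resolves to on (X, y)."""
    if spec.tune:
        params, _ = tune_hyperparameters(X, y, spec, folds=folds)
        return params
    return dict(spec.params or DEFAULT_PARAMS[spec.kind])


def _decision_scores(est: Pipeline, X: np.ndarray, positive_label) -> np.ndarray:
    """Real-valued scores oriented so larger means 'positive class'."""
    clf = est.named_steps["clf"]
    classes = list(clf.classes_)
    pos_idx = classes.index(positive_label)
    if hasattr(clf, "decision_function"):
        scores = est.decision_function(X)
        # sklearn orients binary decision_function toward classes_[1]
        return scores if pos_idx == 1 else -scores
    proba = est.predict_proba(X)
    return proba[:, pos_idx]


def cross_validated_predictions(X: np.ndarray, y, spec: ClassifierSpec,
                                folds: int = 5, seed: int = 0,
                                positive_label=None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified K-fold out-of-fold predictions and decision scores.

    Every trial is predicted exactly once by a model not trained on it.
    Scores are oriented toward ``positive_label`` (default: the
    lexicographically larger class) so they are usable for AUC with that
    label as positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise InputError(f"binary labels required, got {len(classes)} classes")
    if folds < 2:
        raise InputError("need at least 2 folds")
    for cls, cnt in zip(classes, counts):
        if cnt < folds:
            raise InputError(f"class {cls!r} has only {cnt} trials for {folds} folds")
    positive = sorted(classes)[-1] if positive_label is None else positive_label
    if positive not in classes:
        raise InputError(f"positive label {positive!r} not among classes")
    est_template = fit_spec(X, y, spec, folds=folds)

    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    from sklearn.base import clone

    for train, test in cv.split(X, y):
        est = clone(est_template)
        est.fit(X[train], y[train])
        y_pred[test] = est.predict(X[test])
        scores[test] = _decision_scores(est, X[test], positive)
    return y_pred, scores


def compute_metrics(y_true, y_pred, scores=None, positive_label=None) -> MetricsReport:
    """Confusion counts, accuracy, sensitivity, specificity and AUC.

    AUC is the rank statistic P(score_pos > score_neg) with ties counted
    half; when no scores are given, the hard predictions are used as
    degenerate scores.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must have equal length")
    classes = sorted(set(y_true) | set(y_pred))
    if len(classes) > 2:
        raise InputError("binary classification metrics only")
    if positive_label is None:
        positive_label = classes[-1]
    elif positive_label not in classes:
        raise InputError(f"positive label {positive_label!r} not among classes {classes}")

    pos = y_true == positive_label
    pred_pos = y_pred == positive_label
    tp = int(np.sum(pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0

    if scores is None:
        scores = pred_pos.astype(float)
    scores = np.asarray(scores, dtype=float)
    if pos.all() or (~pos).all():
        auc = 0.5
    else:
        from scipy.stats import rankdata

        ranks = rankdata(scores)  # ties get average rank -> half credit
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                         sensitivity=sensitivity, specificity=specificity, auc=auc)
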