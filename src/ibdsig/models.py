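"""The 23-algorithm classifier registry, cross-validation and test metrics.

Every algorithm sits behind one train/predict contract: build an estimator
from a :class:`ModelSpec`, fit on (samples x genes) training data, predict
hard 0/1 labels. Confusion-matrix metrics follow the usual definitions with
positive class = label 1 (IBD in the control-vs-IBD task, Crohn's disease in
the UC-vs-CD task):

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Ratios with a zero denominator are reported as NaN, never silently coerced
to 0 — a leaderboard built on coerced zeros would be corrupt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .screening import GeneSubset
from .study import SingleClassError, StudyError

__all__ = [
    "ModelSpec",
    "EvalResult",
    "registry_list",
    "get_spec",
    "registry_keys",
    "build_estimator",
    "cross_validate",
    "fit_and_evaluate",
    "ann_classifier",
    "RUSBoostClassifier",
    "confusion_counts",
    "default_search_registry",
]


def _load_registry() -> dict:
    with resources.files("ibdsig").joinpath("registry_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


_REGISTRY: dict = _load_registry()

#: Desk-scale registry used by the shipped search configuration: five
#: representative algorithm families (tree ensemble, linear margin, smoothing
#: KNN, shallow tree, subspace ensemble).
_DESK_REGISTRY = ("bagged_trees", "linear_svm", "coarse_knn", "simple_tree", "subspace_knn")


@dataclass(frozen=True)
class ModelSpec:
    """One registry entry: canonical key, display label, hyperparameters."""

    key: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def label(self) -> str:
        return self.params.get("label", self.key)


def registry_keys() -> list[str]:
    return list(_REGISTRY)


def registry_list(seed: int = 0) -> list[ModelSpec]:
    """All 23 registry entries with their frozen default hyperparameters."""
    return [ModelSpec(key=k, params=dict(v), seed=seed) for k, v in _REGISTRY.items()]


def get_spec(key: str, seed: int = 0, **overrides) -> ModelSpec:
    if key not in _REGISTRY:
        raise KeyError(f"unknown registry key {key!r}; known: {sorted(_REGISTRY)}")
    params = dict(_REGISTRY[key])
    unknown = set(overrides) - set(params) - {"label"}
    if unknown:
        raise ValueError(f"unknown hyperparameters for {key!r}: {sorted(unknown)}")
    params.update(overrides)
    return ModelSpec(key=key, params=params, seed=seed)


def default_search_registry(seed: int = 0) -> list[ModelSpec]:
    return [get_spec(k, seed=seed) for k in _DESK_REGISTRY]


class _ClampedKNN(KNeighborsClassifier):
    """KNN that clamps k to the training-set size, so the Coarse preset
    (k=100) stays usable on small folds."""

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(y))
        return super().fit(X, y)


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Boosted shallow trees with per-round random undersampling.

    SAMME-style boosting in which each round's tree is trained on a balanced
    subsample: every minority-class sample plus an equal-size weighted draw
    from the majority class. Weights are updated on the full training set.
    """

    def __init__(self, n_estimators: int = 30, max_splits: int = 20,
                 learning_rate: float = 1.0, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_splits = max_splits
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise SingleClassError("RUSBoost requires two classes")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        c0, c1 = self.classes_
        minority, majority = (c0, c1) if counts[c0] <= counts[c1] else (c1, c0)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for _ in range(self.n_estimators):
            min_idx = np.flatnonzero(y == minority)
            maj_idx = np.flatnonzero(y == majority)
            p = w[maj_idx] / w[maj_idx].sum()
            take = rng.choice(maj_idx, size=min(len(min_idx), len(maj_idx)),
                              replace=False, p=p)
            sub = np.concatenate([min_idx, take])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[sub], y[sub], sample_weight=w[sub] * len(sub))
            pred = tree.predict(X)
            err = float(np.sum(w[pred != y]))
            if err >= 0.5:  # no better than chance on the weighted set: stop
                if not self.estimators_:
                    self.estimators_.append(tree)
                    self.alphas_.append(1.0)
                break
            err = max(err, 1e-10)
            alpha = self.learning_rate * 0.5 * math.log((1 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * np.where(pred != y, 1.0, -1.0))
            w /= w.sum()
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            score += alpha * np.where(pred == self.classes_[1], 1.0, -1.0)
        return score

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def build_estimator(spec: ModelSpec, n_features: int, seed: int | None = None):
    """Instantiate the scikit-learn estimator behind a registry key.

    Scale-sensitive models (SVM, KNN, discriminants, logistic) are wrapped in
    a standardizing pipeline; tree models consume raw features. Gaussian SVM
    kernel scale s maps to gamma = 1 / s**2 with s a multiple of
    sqrt(n_features).
    """
    if spec.key not in _REGISTRY:
        raise KeyError(f"unknown registry key {spec.key!r}")
    p = spec.params
    rs = spec.seed if seed is None else seed
    key = spec.key

    def scaled(est):
        return Pipeline([("scale", StandardScaler()), ("model", est)])

    if key in ("complex_tree", "medium_tree", "simple_tree"):
        return DecisionTreeClassifier(max_leaf_nodes=p["max_splits"] + 1, random_state=rs)
    if key == "linear_discriminant":
        return scaled(LinearDiscriminantAnalysis())
    if key == "quadratic_discriminant":
        return scaled(QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.1)))
    if key == "logistic_regression":
        return scaled(LogisticRegression(max_iter=p.get("max_iter", 1000), random_state=rs))
    if key == "linear_svm":
        return scaled(SVC(kernel="linear", C=p["C"], random_state=rs))
    if key in ("quadratic_svm", "cubic_svm"):
        return scaled(SVC(kernel="poly", degree=p["degree"], C=p["C"],
                          gamma="scale", coef0=1.0, random_state=rs))
    if key.endswith("_gaussian_svm"):
        scale = p["kernel_scale_factor"] * math.sqrt(max(n_features, 1))
        return scaled(SVC(kernel="rbf", C=p["C"], gamma=1.0 / scale**2, random_state=rs))
    if key in ("fine_knn", "medium_knn", "coarse_knn"):
        return scaled(_ClampedKNN(n_neighbors=p["k"]))
    if key == "cosine_knn":
        return scaled(_ClampedKNN(n_neighbors=p["k"], metric="cosine"))
    if key == "cubic_knn":
        return scaled(_ClampedKNN(n_neighbors=p["k"], metric="minkowski",
                                  p=p["minkowski_p"]))
    if key == "weighted_knn":
        return scaled(_ClampedKNN(n_neighbors=p["k"], weights=p["weights"]))
    if key == "boosted_trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=p["max_splits"] + 1),
            n_estimators=p["n_estimators"], random_state=rs,
        )
    if key == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(),
            n_estimators=p["n_estimators"], random_state=rs,
        )
    if key == "subspace_discriminant":
        frac = 1.0 if n_features <= 1 else p["subspace_fraction"]
        return scaled(BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=p["n_estimators"], max_features=frac,
            bootstrap=False, random_state=rs,
        ))
    if key == "subspace_knn":
        frac = 1.0 if n_features <= 1 else p["subspace_fraction"]
        return scaled(BaggingClassifier(
            estimator=_ClampedKNN(n_neighbors=p["k"]),
            n_estimators=p["n_estimators"], max_features=frac,
            bootstrap=False, random_state=rs,
        ))
    if key == "rusboosted_trees":
        return RUSBoostClassifier(n_estimators=p["n_estimators"],
                                  max_splits=p["max_splits"], random_state=rs)
    raise KeyError(f"unhandled registry key {key!r}")  # pragma: no cover


def ann_classifier(n_layers: int, width: int = 30, seed: int = 0,
                   max_iter: int = 400):
    """A multilayer perceptron with ``n_layers`` hidden layers of ``width``
    neurons each, behind the same standardized train/predict contract."""
    if n_layers < 1:
        raise ValueError(f"need at least 1 hidden layer, got {n_layers}")
    mlp = MLPClassifier(hidden_layer_sizes=(width,) * n_layers,
                        max_iter=max_iter, random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("model", mlp)])


# ---------------------------------------------------------------------------
# Evaluation

def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with positive class = 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, fp, tn, fn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class EvalResult:
    """One (algorithm, gene subset) evaluation.

    Metrics are derived properties of the stored confusion counts, so the
    defining identities hold by construction. ``cv_accuracy`` is the mean
    fold accuracy when the result came from (or was preceded by)
    cross-validation.
    """

    model_key: str
    subset: GeneSubset | None
    tp: int
    fp: int
    tn: int
    fn: int
    tag: str  # "cv" | "test"
    cv_accuracy: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tag not in ("cv", "test"):
            raise ValueError("tag must be 'cv' or 'test'")

    @property
    def n_genes(self) -> int:
        return len(self.subset) if self.subset is not None else 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)


def _subset_design(X_genes_by_samples: np.ndarray, subset: GeneSubset | None) -> np.ndarray:
    X = np.asarray(X_genes_by_samples, dtype=float)
    if subset is not None:
        if len(subset) == 0:
            raise StudyError("empty gene subset")
        X = X[subset.as_array(), :]
    return X.T  # samples x genes


def cross_validate(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    subset: GeneSubset | None = None,
    stratified: bool = True,
) -> EvalResult:
    """k-fold cross-validation on training data (genes x samples layout).

    Folds are a seeded partition; ``cv_accuracy`` is the mean of per-fold
    accuracies and the confusion counts are pooled over folds. Stratified
    folds are the default so no fold is single-class at desk scale.
    """
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("cross_validate needs both classes in y_train")
    if k_folds > len(y):
        raise StudyError(f"k_folds={k_folds} exceeds n_train={len(y)}")
    D = _subset_design(X_train, subset)
    if stratified:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    fold_acc = []
    for f, (tr, te) in enumerate(splitter.split(D, y)):
        if len(np.unique(y[tr])) < 2:
            raise SingleClassError(
                f"fold {f} has a single training class; enable stratified folds"
            )
        est = build_estimator(spec, n_features=D.shape[1], seed=seed + f)
        est.fit(D[tr], y[tr])
        pred = np.asarray(est.predict(D[te]), dtype=int)
        a, b, c, d = confusion_counts(y[te], pred)
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
        fold_acc.append((a + c) / len(te))
    return EvalResult(model_key=spec.key, subset=subset, tp=tp, fp=fp, tn=tn, fn=fn,
                      tag="cv", cv_accuracy=float(np.mean(fold_acc)), seed=seed)


def fit_and_evaluate(
    spec: ModelSpec,
    subset: GeneSubset | None,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
    cv_accuracy: float | None = None,
) -> EvalResult:
    """Fit on the full training set (restricted to ``subset``) and score the
    held-out test set. Matrices are genes x samples."""
    y_tr = np.asarray(y_train, dtype=int)
    y_te = np.asarray(y_test, dtype=int)
    if len(np.unique(y_tr)) < 2:
        raise SingleClassError("fit_and_evaluate needs both classes in y_train")
    D_tr = _subset_design(X_train, subset)
    D_te = _subset_design(X_test, subset)
    est = build_estimator(spec, n_features=D_tr.shape[1], seed=seed)
    est.fit(D_tr, y_tr)
    pred = np.asarray(est.predict(D_te), dtype=int)
    tp, fp, tn, fn = confusion_counts(y_te, pred)
    return EvalResult(model_key=spec.key, subset=subset, tp=tp, fp=fp, tn=tn, fn=fn,
                      tag="test", cv_accuracy=cv_accuracy, seed=seed)
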