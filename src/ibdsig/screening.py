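"""Training-set gene screening: correlation pre-filter and lasso selection.

The pre-filter scores every gene by its point-biserial correlation (Pearson
correlation against the 0/1 task label) and keeps the top q% by absolute
value. The lasso arm fits an L1-penalized logistic regression and keeps the
genes with nonzero coefficients. Both operate on training data only; the
resulting :class:`GeneSubset` is then applied to train and test alike.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .study import SingleClassError, StudyError

__all__ = [
    "CorrelationProfile",
    "GeneSubset",
    "correlation_screen",
    "top_q_filter",
    "lasso_select",
    "lasso_path_counts",
    "LassoConvergenceError",
]


class LassoConvergenceError(RuntimeError):
    """L1 optimizer failed to converge within the iteration cap."""


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-gene correlation with a binary label vector."""

    values: np.ndarray  # length m, each in [-1, 1]; constant genes carry 0
    label_hash: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)) or np.any(np.abs(vals) > 1 + 1e-12):
            raise ValueError("correlations must be finite and within [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GeneSubset:
    """An ordered, duplicate-free set of gene row indices with provenance."""

    indices: tuple[int, ...]
    provenance: str = "correlation_filter"  # | mc_reduction | lasso
    q: float | None = None
    lam: float | None = None
    n_total: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise ValueError("gene subset contains duplicate indices")
        if any(i < 0 for i in idx):
            raise ValueError("gene indices must be non-negative")
        if self.n_total is not None and any(i >= self.n_total for i in idx):
            raise ValueError("gene index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i: int) -> bool:
        return i in set(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def _hash_labels(y: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(y, dtype=np.int64).tobytes()).hexdigest()[:16]


def correlation_screen(train_expression: np.ndarray, labels: np.ndarray) -> CorrelationProfile:
    """Point-biserial correlation of every gene row with the 0/1 labels.

    Genes with zero variance get correlation 0 by convention (no linear
    association is measurable). Raises on single-class labels or fewer than
    two samples.
    """
    X = np.asarray(train_expression, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(y):
        raise StudyError("expression columns must match label length")
    if len(y) < 2:
        raise StudyError("need at least 2 samples to correlate")
    if len(np.unique(y)) < 2:
        raise SingleClassError("labels contain a single class; correlation undefined")

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(values=r, label_hash=_hash_labels(labels))


def top_q_filter(profile: CorrelationProfile, q: float, signed: bool = False) -> GeneSubset:
    """Keep the top q% of genes by correlation magnitude.

    Subset size is ``max(1, floor(q/100 * m))``. Ranking is on |r| by default
    (both up- and down-regulated genes are informative); ``signed=True`` ranks
    the raw values instead. Ties break toward the lower gene index; the
    returned indices are in ascending order.
    """
    if not 0 < q <= 100:
        raise ValueError(f"q must be in (0, 100], got {q}")
    m = len(profile)
    size = max(1, math.floor(q / 100 * m))
    score = profile.values if signed else np.abs(profile.values)
    # stable order: descending score, ascending index on ties
    order = np.lexsort((np.arange(m), -score))
    chosen = np.sort(order[:size])
    return GeneSubset(indices=tuple(chosen), provenance="correlation_filter",
                      q=q, n_total=m)


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    # largest penalty at which every coefficient is zero, glmnet-style
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean())))) / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _standardize(X_features: np.ndarray) -> np.ndarray:
    mu = X_features.mean(axis=0)
    sd = X_features.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_features - mu) / sd


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float, max_iter: int, seed: int):
    # scikit-learn's C multiplies the loss; our lam multiplies the penalty
    clf = LogisticRegression(
        l1_ratio=1, C=1.0 / (len(y) * lam), solver="liblinear",
        max_iter=max_iter, random_state=seed,
    )
    clf.fit(Xs, y)
    if int(np.max(clf.n_iter_)) >= max_iter:
        raise LassoConvergenceError(
            f"L1 solver hit the iteration cap ({max_iter}); lambda={lam:.3g}, "
            f"n={len(y)}, m={Xs.shape[1]}"
        )
    return clf


def lasso_select(
    train_expression: np.ndarray,
    labels: np.ndarray,
    lam: float | None = None,
    lambda_strategy: str = "cv_1se",
    n_folds: int = 10,
    n_lambda: int = 30,
    max_iter: int = 2000,
    seed: int = 0,
) -> tuple[GeneSubset, np.ndarray]:
    """Select genes by L1-penalized logistic regression.

    Features (genes) are standardized internally; the penalty is chosen by
    stratified ``n_folds``-fold cross-validated log-loss (binomial deviance)
    over a log-spaced grid from the data-driven lambda_max down four decades,
    unless a fixed ``lam`` is supplied. ``lambda_strategy`` is ``"cv_1se"``
    (default: the largest penalty whose CV loss is within one standard error
    of the minimum — the usual conservative rule, so null data keeps few
    genes) or ``"cv_min"`` (the minimizer itself). Returns the subset of
    genes with nonzero coefficients and the coefficient vector on the
    standardized scale.
    """
    X = np.asarray(train_expression, dtype=float).T  # samples x genes
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("lasso_select needs both classes present")
    Xs = _standardize(X)
    n = len(y)

    if lam is None:
        if lambda_strategy not in ("cv_1se", "cv_min"):
            raise ValueError("lambda_strategy must be 'cv_1se' or 'cv_min'")
        lams = _lambda_grid(Xs, y, n_lambda)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_loss = np.zeros((n_folds, len(lams)))
        for f, (tr, te) in enumerate(cv.split(Xs, y)):
            for j, l in enumerate(lams):
                clf = _fit_l1(Xs[tr], y[tr], l, max_iter, seed)
                p = np.clip(clf.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                fold_loss[f, j] = -np.mean(
                    y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        mean = fold_loss.mean(axis=0)
        j_min = int(np.argmin(mean))
        if lambda_strategy == "cv_min":
            j_pick = j_min
        else:
            se = fold_loss[:, j_min].std(ddof=1) / math.sqrt(n_folds)
            within = np.flatnonzero(mean <= mean[j_min] + se)
            j_pick = int(within[0])  # grid is descending in lambda
        lam = float(lams[j_pick])

    clf = _fit_l1(Xs, y, lam, max_iter, seed)
    coefs = clf.coef_.ravel()
    chosen = tuple(int(i) for i in np.flatnonzero(coefs != 0.0))
    subset = GeneSubset(indices=chosen, provenance="lasso", lam=lam,
                        n_total=Xs.shape[1])
    return subset, coefs


def lasso_path_counts(
    train_expression: np.ndarray,
    labels: np.ndarray,
    lams: np.ndarray | None = None,
    n_lambda: int = 20,
    max_iter: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Number of selected genes at each penalty on a path grid (descending lambda)."""
    X = np.asarray(train_expression, dtype=float).T
    y = np.asarray(labels, dtype=int)
    Xs = _standardize(X)
    n = len(y)
    if lams is None:
        lams = _lambda_grid(Xs, y, n_lambda)
    counts = []
    for lam in lams:
        clf = _fit_l1(Xs, y, lam, max_iter, seed)
        counts.append(int(np.count_nonzero(clf.coef_)))
    return np.asarray(lams), np.asarray(counts)
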