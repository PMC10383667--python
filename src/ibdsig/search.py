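"""Monte Carlo random gene-subset search, ANN layer sweep, best-model pick.

Exhaustively evaluating every combination of the few hundred genes that
survive the correlation filter is infeasible, so the search runs ``p``
independent reduction chains: each starts from the filtered subset and
repeatedly discards a uniform random number beta of genes (1 <= beta <
current size), cross-validating the whole classifier registry on each
intermediate subset. Every per-iteration best model is a candidate; the
top ten candidates by training CV accuracy are refitted on the full
training set and reported with held-out test metrics. A multilayer
perceptron layer sweep provides the baseline the winner must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    EvalResult,
    ModelSpec,
    ann_classifier,
    confusion_counts,
    cross_validate,
    default_search_registry,
    fit_and_evaluate,
)
from .screening import GeneSubset, correlation_screen, top_q_filter
from .study import ExpressionStudy, LabelScheme, SplitIndices, encode_labels, split_train_test
from .util import child_seed

__all__ = [
    "sample_beta",
    "reduce_subset",
    "ChainRecord",
    "MCChain",
    "Leaderboard",
    "SearchResult",
    "run_chain",
    "run_search",
    "ann_layer_sweep",
    "select_best",
    "Selection",
]


def sample_beta(n_current: int, rng: np.random.Generator) -> int:
    """Uniform integer in [1, n_current - 1]: how many genes to discard."""
    if n_current < 2:
        raise ValueError(f"cannot reduce a subset of size {n_current}")
    return int(rng.integers(1, n_current))


def reduce_subset(subset: GeneSubset, beta: int, rng: np.random.Generator) -> GeneSubset:
    """Drop ``beta`` members chosen uniformly without replacement."""
    n = len(subset)
    if not 1 <= beta <= n - 1:
        raise ValueError(f"beta must be in [1, {n - 1}], got {beta}")
    keep = rng.choice(n, size=n - beta, replace=False)
    idx = tuple(subset.indices[i] for i in np.sort(keep))
    return GeneSubset(indices=idx, provenance="mc_reduction", n_total=subset.n_total)


@dataclass(frozen=True)
class ChainRecord:
    """One iteration of a reduction chain: the subset evaluated, the best
    registry model on it, and the reduction applied afterwards."""

    iteration: int
    n_genes_before: int
    beta: int | None  # None on the final record (no further reduction)
    subset: GeneSubset  # the subset evaluated at this iteration
    subset_after: GeneSubset | None
    best: EvalResult


@dataclass(frozen=True)
class MCChain:
    chain_id: int
    records: tuple[ChainRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("chain must contain at least one record")
        prev = None
        for rec in self.records:
            if rec.n_genes_before != len(rec.subset):
                raise ValueError("record size bookkeeping is inconsistent")
            if rec.beta is not None:
                if not 1 <= rec.beta <= rec.n_genes_before - 1:
                    raise ValueError("beta out of [1, n_genes_before - 1]")
                if len(rec.subset_after) != rec.n_genes_before - rec.beta:
                    raise ValueError("subset_after size does not match beta")
                if not set(rec.subset_after.indices) < set(rec.subset.indices):
                    raise ValueError("subset_after is not a strict subset")
            if prev is not None and rec.subset.indices != prev.subset_after.indices:
                raise ValueError("chain records are not nested")
            prev = rec


def _best_of_registry(
    specs: list[ModelSpec],
    X_train: np.ndarray,
    y_train: np.ndarray,
    subset: GeneSubset,
    cv_folds: int,
    seed: int,
) -> EvalResult:
    """Cross-validate every registry spec on one subset; return the winner
    (ties: higher cv accuracy, then fewer genes, then registry key)."""
    results = [
        cross_validate(spec, X_train, y_train, k_folds=cv_folds,
                       seed=seed, subset=subset)
        for spec in specs
    ]
    return min(results, key=lambda r: (-r.cv_accuracy, r.n_genes, r.model_key))


def run_chain(
    filtered_subset: GeneSubset,
    X_train: np.ndarray,
    y_train: np.ndarray,
    specs: list[ModelSpec],
    cv_folds: int = 10,
    min_size: int = 5,
    seed: int | np.random.SeedSequence = 0,
    chain_id: int = 0,
) -> MCChain:
    """One reduction trajectory from the filtered subset down to ``min_size``.

    Iteration 0 evaluates the full filtered subset; each later iteration
    evaluates the reduced subset until the next reduction would fall below
    ``min_size`` (or no reduction is possible). Deterministic given the seed.
    """
    if len(filtered_subset) < 2:
        raise ValueError("run_chain needs a filtered subset of >= 2 genes")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    cv_seed = child_seed(ss.spawn(1)[0])

    records: list[ChainRecord] = []
    current = filtered_subset
    it = 0
    while True:
        best = _best_of_registry(specs, X_train, y_train, current,
                                 cv_folds, seed=cv_seed + it)
        beta = subset_after = None
        if len(current) >= 2:
            beta = sample_beta(len(current), rng)
            subset_after = reduce_subset(current, beta, rng)
        records.append(ChainRecord(
            iteration=it, n_genes_before=len(current), beta=beta,
            subset=current, subset_after=subset_after, best=best,
        ))
        if subset_after is None or len(subset_after) < min_size:
            break
        current = subset_after
        it += 1
    return MCChain(chain_id=chain_id, records=tuple(records))


@dataclass(frozen=True)
class Leaderboard:
    """Top-k evaluations, non-increasing in the selection metric (training
    CV accuracy); ties break toward fewer genes, then the algorithm key."""

    task: str
    results: tuple[EvalResult, ...]
    k: int = 10

    def __post_init__(self) -> None:
        accs = [r.cv_accuracy for r in self.results]
        if any(a is None for a in accs):
            raise ValueError("leaderboard entries need cv_accuracy")
        if any(accs[i] < accs[i + 1] for i in range(len(accs) - 1)):
            raise ValueError("leaderboard not sorted by selection metric")

    def top(self) -> EvalResult:
        return self.results[0]


@dataclass(frozen=True)
class SearchResult:
    leaderboard: Leaderboard
    chains: tuple[MCChain, ...]
    filtered_subset: GeneSubset
    split: SplitIndices
    y_train: np.ndarray = field(repr=False)
    y_test: np.ndarray = field(repr=False)


def run_search(
    study: ExpressionStudy,
    scheme: LabelScheme,
    q: float = 1.0,
    p_chains: int = 100,
    specs: list[ModelSpec] | None = None,
    cv_folds: int = 10,
    min_size: int = 5,
    fraction: float = 0.8,
    seed: int = 0,
    top_k: int = 10,
    stratify_split: bool = True,
) -> SearchResult:
    """The full search for one task: split, screen, filter, ``p_chains``
    reduction chains, then refit the top-k CV candidates on the training set
    and report their held-out test metrics."""
    if specs is None:
        specs = default_search_registry()
    ss = np.random.SeedSequence(seed)
    ss_split, ss_chains, ss_refit = ss.spawn(3)

    y_all, kept = encode_labels(study, scheme)
    split = split_train_test(study, kept, fraction=fraction,
                             seed=child_seed(ss_split), stratify=stratify_split)
    pos = {k: i for i, k in enumerate(kept)}
    y_train = y_all[[pos[i] for i in split.train]]
    y_test = y_all[[pos[i] for i in split.test]]
    X_train = study.expression[:, split.train]
    X_test = study.expression[:, split.test]

    profile = correlation_screen(X_train, y_train)
    filtered = top_q_filter(profile, q)

    chains = tuple(
        run_chain(filtered, X_train, y_train, specs, cv_folds=cv_folds,
                  min_size=min_size, seed=css, chain_id=c)
        for c, css in enumerate(ss_chains.spawn(p_chains))
    )

    candidates = [rec.best for ch in chains for rec in ch.records]
    candidates.sort(key=lambda r: (-r.cv_accuracy, r.n_genes, r.model_key))
    top = candidates[: min(top_k, len(candidates))]

    refit_seed = child_seed(ss_refit)
    spec_by_key = {s.key: s for s in specs}
    final = tuple(
        fit_and_evaluate(spec_by_key[r.model_key], r.subset, X_train, y_train,
                         X_test, y_test, seed=refit_seed + i,
                         cv_accuracy=r.cv_accuracy)
        for i, r in enumerate(top)
    )
    board = Leaderboard(task=scheme.name, results=final, k=top_k)
    return SearchResult(leaderboard=board, chains=chains, filtered_subset=filtered,
                        split=split, y_train=y_train, y_test=y_test)


def ann_layer_sweep(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    subset: GeneSubset | None,
    layer_values: list[int],
    width: int = 30,
    seed: int = 0,
    max_iter: int = 400,
) -> tuple[int, EvalResult, list[tuple[int, float | None]]]:
    """Train one MLP per hidden-layer count and return the best test-accuracy
    configuration (ties: fewest layers), plus the full (layers, accuracy)
    table. Per-depth training failures are recorded as None and skipped."""
    if not layer_values or any(g < 1 for g in layer_values):
        raise ValueError("layer_values must be non-empty, all >= 1")
    idx = subset.as_array() if subset is not None else slice(None)
    D_tr = np.asarray(X_train, dtype=float)[idx, :].T
    D_te = np.asarray(X_test, dtype=float)[idx, :].T
    y_tr = np.asarray(y_train, dtype=int)
    y_te = np.asarray(y_test, dtype=int)

    table: list[tuple[int, float | None]] = []
    best: tuple[int, EvalResult] | None = None
    for gamma in layer_values:
        try:
            net = ann_classifier(gamma, width=width, seed=seed, max_iter=max_iter)
            net.fit(D_tr, y_tr)
            pred = np.asarray(net.predict(D_te), dtype=int)
        except Exception:
            table.append((gamma, None))
            continue
        tp, fp, tn, fn = confusion_counts(y_te, pred)
        res = EvalResult(model_key=f"ann_{gamma}_layers", subset=subset,
                         tp=tp, fp=fp, tn=tn, fn=fn, tag="test", seed=seed)
        table.append((gamma, res.accuracy))
        if best is None or res.accuracy > best[1].accuracy or (
            res.accuracy == best[1].accuracy and gamma < best[0]
        ):
            best = (gamma, res)
    if best is None:
        raise RuntimeError("every layer configuration failed to train")
    return best[0], best[1], table


@dataclass(frozen=True)
class Selection:
    """The final pick: the better of the ML leaderboard and the ANN baseline."""

    source: str  # "registry" | "ann"
    result: EvalResult
    ann_layers: int | None = None


def select_best(leaderboard: Leaderboard, ann_best: tuple[int, EvalResult]) -> Selection:
    """Pick the higher test accuracy; on a tie, the non-ANN model (and among
    registry models, the one with fewer genes, already the board order)."""
    if not leaderboard.results:
        raise ValueError("empty leaderboard")
    ml = max(leaderboard.results,
             key=lambda r: (r.accuracy, -r.n_genes, r.model_key))
    gamma, ann = ann_best
    if ann.accuracy > ml.accuracy:
        return Selection(source="ann", result=ann, ann_layers=gamma)
    return Selection(source="registry", result=ml)
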