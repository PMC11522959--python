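"""Consensus random forests for genotype→environment classification.

The protocol: a random forest is tuned in two stages on a balanced
dataset with an internal 20% validation hold-out (stage 2 refines the
stage-1 optimum with 0.75× and 1.25× multipliers), then refit across many
iterations, each on a freshly balanced and freshly split dataset.  Every
iteration records test-fold AUC, true-positive rate, per-strain
predictions, and permutation feature importance (out-of-bag per tree by
default, with test- and train-fold variants).  A KO is
*consensus-important* if it ranks in the per-iteration top-K importances
in at least a fixed fraction of iterations (default 80%).

:class:`ConsensusForestClassifier` packages the protocol as a
scikit-learn estimator; the module-level functions are the individual
steps and can be composed directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import SplitPlan, balance_downsample, make_split

__all__ = [
    "TuningConfig",
    "TuningResult",
    "IterationResult",
    "ConsensusReport",
    "auc",
    "tune_forest",
    "fit_forest",
    "permutation_importance",
    "oob_permutation_importance",
    "fit_iteration",
    "run_iterations",
    "consensus_importance",
    "misclassification_audit",
    "ConsensusForestClassifier",
]


# ---------------------------------------------------------------------- #
# AUC


def _auc_from_ranks(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Row-wise AUC of ``scores`` (2-D, one score vector per row) vs ``y``.

    Uses the rank-sum identity with midranks, so tied score pairs
    contribute 1/2 — identical to the normalised Mann–Whitney U
    statistic.
    """
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in y_true")
    ranks = rankdata(scores, axis=1)
    pos_rank_sum = ranks[:, y == 1].sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc(y_true, scores) -> float:
    """Area under the ROC curve: P(random positive outscores a random
    negative), ties counting one half."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("y_true and scores must be 1-D of equal length")
    return float(_auc_from_ranks(y, s[None, :])[0])


# ---------------------------------------------------------------------- #
# tuning


@dataclass
class TuningConfig:
    """Two-stage grid search over mtry (features tried per split) and
    min_n (minimum node size to attempt a split).

    The stage-1 grid defaults to mtry ∈ {√p, p/10, p/3} and
    min_n ∈ {2, 5, 10}; stage 2 multiplies the stage-1 optimum by the
    refinement multipliers and rounds to valid integers.
    """

    mtry_grid: tuple[int, ...] | None = None
    min_n_grid: tuple[int, ...] = (2, 5, 10)
    refine_multipliers: tuple[float, float] = (0.75, 1.25)
    n_trees: int = 500
    test_fraction: float = 0.20
    n_resamples: int = 1

    def stage1_mtry(self, n_features: int) -> tuple[int, ...]:
        if self.mtry_grid is not None:
            grid = self.mtry_grid
        else:
            grid = (
                round(sqrt(n_features)),
                round(n_features / 10),
                round(n_features / 3),
            )
        vals = sorted({min(max(1, int(m)), n_features) for m in grid})
        return tuple(vals)


@dataclass
class TuningResult:
    """Evaluated (mtry, min_n, AUC) triples for both stages and the
    selected pair (maximum validation AUC over all evaluations)."""

    stage1: list[tuple[int, int, float]]
    stage2: list[tuple[int, int, float]]
    mtry: int
    min_n: int
    auc: float

    @property
    def params(self) -> tuple[int, int]:
        return (self.mtry, self.min_n)


def refine_grid(
    best: int, multipliers: Sequence[float], lo: int = 1, hi: int | None = None
) -> tuple[int, ...]:
    """Stage-2 grid around a stage-1 optimum: {0.75·x, x, 1.25·x} rounded,
    deduplicated and clamped to ``[lo, hi]``."""
    vals = {best, *(int(round(m * best)) for m in multipliers)}
    vals = {min(max(lo, v), hi) if hi is not None else max(lo, v) for v in vals}
    return tuple(sorted(vals))


def fit_forest(
    X: np.ndarray, y: np.ndarray, mtry: int, min_n: int, n_trees: int, seed: int
) -> RandomForestClassifier:
    """One random forest with the protocol's hyperparameters.

    mtry maps to ``max_features`` and min_n (minimum number of data
    points for node splitting) to ``min_samples_split``.
    """
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(int(mtry), X.shape[1]),
        min_samples_split=max(2, int(min_n)),
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def tune_forest(
    X, y, config: TuningConfig | None = None, seed: int = 0
) -> TuningResult:
    """Two-stage hyperparameter search maximising hold-out AUC.

    Each grid point is fit on 80% of the (balanced) input and scored on
    the withheld 20%; with ``config.n_resamples > 1`` this is repeated
    over that many different splits and the validation AUCs averaged,
    which stabilises the selection on weak-signal problems.  Ties break
    toward smaller (mtry, min_n), deterministically.
    """
    config = config or TuningConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("tuning requires both classes in y")
    folds = []
    for r in range(max(1, config.n_resamples)):
        split = make_split(
            np.arange(len(y)),
            y,
            test_fraction=config.test_fraction,
            seed=int(seed) + 100_003 * r,
        )
        tr, va = list(split.train), list(split.test)
        folds.append((X[tr], y[tr], X[va], y[va]))
    p = X.shape[1]

    def evaluate(grid_mtry, grid_min_n):
        out = []
        for m in grid_mtry:
            for n in grid_min_n:
                scores = []
                for X_tr, y_tr, X_va, y_va in folds:
                    model = fit_forest(X_tr, y_tr, m, n, config.n_trees, seed)
                    scores.append(auc(y_va, model.predict_proba(X_va)[:, 1]))
                out.append((int(m), int(n), float(np.mean(scores))))
        return out

    stage1 = evaluate(config.stage1_mtry(p), config.min_n_grid)
    best_m, best_n, _ = max(stage1, key=lambda t: (t[2], -t[0], -t[1]))
    grid2_m = refine_grid(best_m, config.refine_multipliers, lo=1, hi=p)
    grid2_n = refine_grid(best_n, config.refine_multipliers, lo=2)
    seen = {(m, n) for m, n, _ in stage1}
    stage2 = evaluate(
        grid2_m, grid2_n
    )
    stage2 = [t for t in stage2 if (t[0], t[1]) not in seen]
    all_evals = stage1 + stage2
    m, n, a = max(all_evals, key=lambda t: (t[2], -t[0], -t[1]))
    return TuningResult(stage1=stage1, stage2=stage2, mtry=m, min_n=n, auc=a)


# ---------------------------------------------------------------------- #
# permutation importance


# scores are rounded before ranking so that mathematically equal
# probabilities reached by different summation orders tie identically
_SCORE_DECIMALS = 10


def _permuted_aucs_naive(model, X, y, perm: np.ndarray) -> np.ndarray:
    """Reference path: permute one column at a time, full re-predict."""
    p = X.shape[1]
    out = np.empty(p)
    for f in range(p):
        Xp = X.copy()
        Xp[:, f] = X[perm, f]
        scores = np.round(model.predict_proba(Xp)[:, 1], _SCORE_DECIMALS)
        out[f] = auc(y, scores)
    return out


def _permuted_aucs_by_tree(model, X, y, perm: np.ndarray) -> np.ndarray:
    """Fast path, numerically equivalent to :func:`_permuted_aucs_naive`.

    A forest averages per-tree class probabilities, and a tree's
    prediction only changes when a feature it actually splits on is
    permuted.  So for each feature only the trees that use it are
    re-evaluated (by swapping that one column and re-applying the tree);
    all other per-tree probabilities are reused.
    """
    n, p = X.shape
    trees = model.estimators_
    n_trees = len(trees)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    Xp32 = X32[perm]
    base_tree = np.empty((n_trees, n))
    delta = np.zeros((p, n))  # summed per-tree probability change per feature
    touched = np.zeros(p, dtype=bool)
    for t_idx, est in enumerate(trees):
        tree = est.tree_
        counts = tree.value[:, 0, :]
        prob1 = counts[:, 1] / counts.sum(axis=1)
        bt = prob1[tree.apply(X32)]
        base_tree[t_idx] = bt
        feats = tree.feature
        used = np.unique(feats[feats >= 0])
        touched[used] = True
        for f in used:
            saved = X32[:, f].copy()
            X32[:, f] = Xp32[:, f]
            delta[f] += prob1[tree.apply(X32)] - bt
            X32[:, f] = saved
    total = base_tree.sum(axis=0)
    scores = np.round((total[None, :] + delta) / n_trees, _SCORE_DECIMALS)
    out = np.full(p, auc(y, np.round(total / n_trees, _SCORE_DECIMALS)))
    if touched.any():
        out[touched] = _auc_from_ranks(y, scores[touched])
    return out


def oob_permutation_importance(
    model,
    X_train,
    y_train,
    n_repeats: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importance, ranger style.

    For every tree, its out-of-bag samples are scored with and without
    each used feature permuted (a fresh permutation per tree), and the
    per-tree AUC drops are averaged over all trees — features a tree
    never splits on contribute a drop of exactly zero for that tree.
    Averaging over trees makes this markedly less noisy than a single
    test-fold permutation.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.ascontiguousarray(np.asarray(X_train), dtype=np.float32)
    y = np.asarray(y_train)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    in_bag = list(model.estimators_samples_)
    n_trees = len(model.estimators_)
    for est, samples in zip(model.estimators_, in_bag):
        mask = np.ones(n, dtype=bool)
        mask[samples] = False
        oob = np.flatnonzero(mask)
        if oob.size < 2:
            continue
        yo = y[oob]
        if yo.min() == yo.max():
            continue
        tree = est.tree_
        counts = tree.value[:, 0, :]
        prob1 = counts[:, 1] / counts.sum(axis=1)
        Xo = np.ascontiguousarray(X[oob])
        base_scores = prob1[tree.apply(Xo)]
        base_auc = auc(yo, np.round(base_scores, _SCORE_DECIMALS))
        feats = tree.feature
        used = np.unique(feats[feats >= 0])
        if used.size == 0:
            continue
        drops = np.zeros(used.size)
        for _ in range(n_repeats):
            perm = rng.permutation(oob.size)
            scores = np.empty((used.size, oob.size))
            for j, f in enumerate(used):
                saved = Xo[:, f].copy()
                Xo[:, f] = saved[perm]
                scores[j] = prob1[tree.apply(Xo)]
                Xo[:, f] = saved
            drops += base_auc - _auc_from_ranks(
                yo, np.round(scores, _SCORE_DECIMALS)
            )
        imp[used] += drops / n_repeats
    return imp / n_trees


def permutation_importance(
    model,
    X_test,
    y_test,
    n_repeats: int = 1,
    seed: int = 0,
    method: str = "by_tree",
) -> np.ndarray:
    """Per-feature permutation importance as the drop in test AUC.

    ``importance(f) = AUC(baseline) − mean over repeats of AUC with
    column f shuffled``.  ``method='by_tree'`` re-evaluates, per feature,
    only the trees that split on it, which is numerically identical to
    the naive one-column-at-a-time loop (``method='naive'``).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X_test = np.ascontiguousarray(np.asarray(X_test))
    y_test = np.asarray(y_test)
    rng = np.random.default_rng(seed)
    n, p = X_test.shape
    base = auc(y_test, model.predict_proba(X_test)[:, 1])
    permuted = _permuted_aucs_by_tree if method == "by_tree" else _permuted_aucs_naive
    drops = np.zeros(p, dtype=float)
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        drops += permuted(model, X_test, y_test, perm)
    return base - drops / n_repeats


# ---------------------------------------------------------------------- #
# iterations


@dataclass
class IterationResult:
    """Everything recorded for one resampled model fit."""

    index: int
    seed: int
    split: SplitPlan
    auc: float
    tpr: float
    test_indices: tuple[int, ...]
    y_test: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    importances: np.ndarray
    params: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")
        if not 0.0 <= self.tpr <= 1.0:
            raise ValueError(f"TPR out of range: {self.tpr}")


def fit_iteration(
    X,
    y,
    params: tuple[int, int],
    split: SplitPlan,
    seed: int,
    n_trees: int = 500,
    n_permutation_repeats: int = 1,
    importance_data: str = "oob",
    index: int = 0,
) -> IterationResult:
    """Fit one forest on ``split.train``, evaluate on ``split.test``,
    and measure permutation importance (out-of-bag by default; test- and
    train-fold variants are available)."""
    X = np.asarray(X)
    y = np.asarray(y)
    tr, te = list(split.train), list(split.test)
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training fold contains a single class")
    mtry, min_n = params
    model = fit_forest(X[tr], y[tr], mtry, min_n, n_trees, seed)
    scores = model.predict_proba(X[te])[:, 1]
    preds = (scores >= 0.5).astype(np.int64)
    test_auc = auc(y[te], scores)
    n_pos = int(np.sum(y[te] == 1))
    tpr = float(np.sum((preds == 1) & (y[te] == 1)) / n_pos) if n_pos else 0.0
    if importance_data == "oob":
        imp = oob_permutation_importance(
            model, X[tr], y[tr], n_repeats=n_permutation_repeats, seed=seed
        )
    elif importance_data in ("test", "train"):
        Xi, yi = (X[te], y[te]) if importance_data == "test" else (X[tr], y[tr])
        imp = permutation_importance(
            model, Xi, yi, n_repeats=n_permutation_repeats, seed=seed
        )
    else:
        raise ValueError("importance_data must be 'oob', 'test' or 'train'")
    return IterationResult(
        index=index,
        seed=seed,
        split=split,
        auc=test_auc,
        tpr=tpr,
        test_indices=tuple(te),
        y_test=y[te].copy(),
        scores=scores,
        predictions=preds,
        importances=imp,
        params=(int(mtry), int(min_n)),
    )


def run_iterations(
    X,
    y,
    params: tuple[int, int],
    n_iterations: int = 100,
    test_fraction: float = 0.20,
    base_seed: int = 0,
    n_trees: int = 500,
    rebalance_per_iteration: bool = True,
    n_permutation_repeats: int = 1,
    importance_data: str = "oob",
) -> list[IterationResult]:
    """The repeated-resampling protocol: ``n_iterations`` forests, each on
    a freshly balanced dataset (seeded ``base_seed + i``) and a fresh
    stratified 80/20 split.  Fully reproducible given ``base_seed``."""
    X = np.asarray(X)
    y = np.asarray(y)
    results = []
    fixed_balance = None
    if not rebalance_per_iteration:
        fixed_balance = balance_downsample(y, base_seed)
    for i in range(n_iterations):
        seed_i = int(base_seed) + i
        balanced = (
            balance_downsample(y, seed_i)
            if rebalance_per_iteration
            else fixed_balance
        )
        split = make_split(balanced, y, test_fraction=test_fraction, seed=seed_i)
        results.append(
            fit_iteration(
                X,
                y,
                params,
                split,
                seed=seed_i,
                n_trees=n_trees,
                n_permutation_repeats=n_permutation_repeats,
                importance_data=importance_data,
                index=i,
            )
        )
    return results


# ---------------------------------------------------------------------- #
# consensus


@dataclass
class ConsensusReport:
    """Cross-iteration consensus of important features.

    ``table`` has one row per KO: top-K membership count, median
    importance across iterations, and the consensus flag
    (count ≥ ceil(min_frac · n_iterations)).
    """

    table: pd.DataFrame
    n_iterations: int
    top_k: int
    min_frac: float

    @property
    def consensus_kos(self) -> list[str]:
        flagged = self.table[self.table["consensus"]]
        return list(flagged.index)


def top_k_mask(importances: np.ndarray, ko_ids: Sequence[str], top_k: int) -> np.ndarray:
    """Boolean mask of the top-``top_k`` features of one importance
    vector; ties broken by importance descending then KO id ascending."""
    order = sorted(range(len(ko_ids)), key=lambda j: (-importances[j], ko_ids[j]))
    mask = np.zeros(len(ko_ids), dtype=bool)
    mask[order[: int(top_k)]] = True
    return mask


def consensus_importance(
    results: Sequence[IterationResult],
    ko_ids: Sequence[str],
    top_k: int = 1000,
    min_frac: float = 0.80,
) -> ConsensusReport:
    """Flag KOs ranking in the per-iteration top-K in at least
    ``min_frac`` of iterations."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not results:
        raise ValueError("need at least one iteration result")
    ko_ids = list(ko_ids)
    imp = np.vstack([r.importances for r in results])
    if imp.shape[1] != len(ko_ids):
        raise ValueError("importance vectors do not match ko_ids length")
    counts = np.zeros(len(ko_ids), dtype=np.int64)
    for row in imp:
        counts += top_k_mask(row, ko_ids, top_k)
    n_iter = len(results)
    threshold = ceil(min_frac * n_iter)
    table = pd.DataFrame(
        {
            "top_k_count": counts,
            "median_importance": np.median(imp, axis=0),
            "consensus": counts >= threshold,
        },
        index=pd.Index(ko_ids, name="ko_id"),
    )
    table = table.sort_values(
        ["consensus", "median_importance", "top_k_count"],
        ascending=[False, False, False],
        kind="mergesort",
    )
    return ConsensusReport(
        table=table, n_iterations=n_iter, top_k=int(top_k), min_frac=float(min_frac)
    )


def misclassification_audit(
    results: Sequence[IterationResult], strain_ids: Sequence[str] | None = None
) -> dict:
    """Strains consistently misclassified across iterations.

    A strain is a consistent false positive (negative) iff it was
    misclassified as positive (negative) in *every* iteration in which it
    appeared in a test fold.  Returns per-strain appearance and error
    counts as well.
    """
    appearances: dict[int, int] = {}
    errors: dict[int, int] = {}
    truth: dict[int, int] = {}
    for r in results:
        for pos, idx in enumerate(r.test_indices):
            appearances[idx] = appearances.get(idx, 0) + 1
            truth[idx] = int(r.y_test[pos])
            if r.predictions[pos] != r.y_test[pos]:
                errors[idx] = errors.get(idx, 0) + 1

    def name(idx: int):
        return strain_ids[idx] if strain_ids is not None else idx

    consistent_fp = sorted(
        name(i)
        for i, n in appearances.items()
        if errors.get(i, 0) == n and truth[i] == 0
    )
    consistent_fn = sorted(
        name(i)
        for i, n in appearances.items()
        if errors.get(i, 0) == n and truth[i] == 1
    )
    rates = {
        name(i): {
            "appearances": n,
            "errors": errors.get(i, 0),
            "error_rate": errors.get(i, 0) / n,
            "label": truth[i],
        }
        for i, n in sorted(appearances.items())
    }
    return {
        "consistent_false_pos": consistent_fp,
        "consistent_false_neg": consistent_fn,
        "per_strain": rates,
    }


# ---------------------------------------------------------------------- #
# estimator


class ConsensusForestClassifier(ClassifierMixin, BaseEstimator):
    """Balanced consensus random forest with permutation-importance
    feature selection.

    Parameters
    ----------
    n_iterations : int, default=100
        Number of resampled forest fits.
    test_fraction : float, default=0.2
        Fraction of each balanced set withheld for testing.
    n_trees : int, default=500
        Trees per forest.
    top_k : int, default=1000
        Per-iteration importance rank cutoff for consensus counting.
    min_frac : float, default=0.8
        Fraction of iterations a feature must reach the top-K to be
        consensus-flagged.
    tuning : 'auto', TuningConfig or (mtry, min_n)
        'auto' runs the two-stage grid search once before the iterations;
        a pair skips tuning.
    rebalance_per_iteration : bool, default=True
        Draw a fresh balanced set per iteration (otherwise one fixed set,
        fresh splits).
    n_permutation_repeats : int, default=1
        Shuffles per feature in the importance measurement.
    importance_data : {'oob', 'test', 'train'}, default='oob'
        Data on which permutation importance is measured: per-tree
        out-of-bag samples (as the ranger package does), the test fold,
        or the training fold.
    random_state : int, default=0

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    tuning_result_ : TuningResult or None
    best_params_ : tuple (mtry, min_n)
    iteration_results_ : list of IterationResult
    consensus_report_ : ConsensusReport
    feature_importances_ : ndarray — median permutation importance per feature
    mean_auc_ : float — mean test AUC across iterations
    mean_tpr_ : float
    estimator_ : RandomForestClassifier fit on one balanced set, used for
        predict/predict_proba
    """

    def __init__(
        self,
        n_iterations: int = 100,
        test_fraction: float = 0.20,
        n_trees: int = 500,
        top_k: int = 1000,
        min_frac: float = 0.80,
        tuning="auto",
        rebalance_per_iteration: bool = True,
        n_permutation_repeats: int = 1,
        importance_data: str = "oob",
        random_state: int = 0,
    ) -> None:
        self.n_iterations = n_iterations
        self.test_fraction = test_fraction
        self.n_trees = n_trees
        self.top_k = top_k
        self.min_frac = min_frac
        self.tuning = tuning
        self.rebalance_per_iteration = rebalance_per_iteration
        self.n_permutation_repeats = n_permutation_repeats
        self.importance_data = importance_data
        self.random_state = random_state

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame) and feature_names is None:
            feature_names = list(X.columns)
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ConsensusForestClassifier is strictly binary")
        y = (y == self.classes_[1]).astype(np.int64)
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = (
            list(feature_names)
            if feature_names is not None
            else [f"f{j}" for j in range(X.shape[1])]
        )
        seed = int(self.random_state)

        if self.tuning == "auto" or isinstance(self.tuning, TuningConfig):
            config = self.tuning if isinstance(self.tuning, TuningConfig) else None
            if config is None:
                config = TuningConfig(n_trees=self.n_trees)
            balanced = balance_downsample(y, seed)
            self.tuning_result_ = tune_forest(X[balanced], y[balanced], config, seed)
            self.best_params_ = self.tuning_result_.params
        else:
            self.tuning_result_ = None
            self.best_params_ = (int(self.tuning[0]), int(self.tuning[1]))

        self.iteration_results_ = run_iterations(
            X,
            y,
            self.best_params_,
            n_iterations=self.n_iterations,
            test_fraction=self.test_fraction,
            base_seed=seed,
            n_trees=self.n_trees,
            rebalance_per_iteration=self.rebalance_per_iteration,
            n_permutation_repeats=self.n_permutation_repeats,
            importance_data=self.importance_data,
        )
        self.consensus_report_ = consensus_importance(
            self.iteration_results_,
            self.feature_names_,
            top_k=min(self.top_k, self.n_features_in_),
            min_frac=self.min_frac,
        )
        by_feature = self.consensus_report_.table["median_importance"]
        self.feature_importances_ = by_feature.reindex(self.feature_names_).to_numpy()
        self.mean_auc_ = float(np.mean([r.auc for r in self.iteration_results_]))
        self.mean_tpr_ = float(np.mean([r.tpr for r in self.iteration_results_]))
        balanced = balance_downsample(y, seed)
        self.estimator_ = fit_forest(
            X[balanced], y[balanced], *self.best_params_, self.n_trees, seed
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X)
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba >= 0.5).astype(int)]

    @property
    def consensus_features_(self) -> list[str]:
        check_is_fitted(self, "consensus_report_")
        return self.consensus_report_.consensus_kos
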