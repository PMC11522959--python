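"""Consensus random-forest protocol: AUC, tuning, importance, consensus."""

import numpy as np
import pytest

from yeastenv.features import balance_downsample, make_split
from yeastenv.forest import (
    ConsensusForestClassifier,
    TuningConfig,
    auc,
    consensus_importance,
    fit_forest,
    fit_iteration,
    misclassification_audit,
    oob_permutation_importance,
    permutation_importance,
    refine_grid,
    run_iterations,
    top_k_mask,
    tune_forest,
)


def pairwise_auc_oracle(y, s) -> float:
    """Mann–Whitney enumeration: fraction of (pos, neg) pairs correctly
    ordered, ties counting one half."""
    pos = [si for si, yi in zip(s, y) if yi == 1]
    neg = [si for si, yi in zip(s, y) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_and_inverse_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_all_tied_scores(self):
        y = np.array([0, 1, 0, 1, 1])
        assert auc(y, np.full(5, 0.5)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(4), np.arange(4.0))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        # coarse grid of scores forces plenty of ties
        s = rng.integers(0, 6, n) / 5.0
        assert auc(y, s) == pytest.approx(pairwise_auc_oracle(y, s), abs=1e-12)


class TestTuning:
    def test_refinement_grid_arithmetic(self):
        # stage-1 optimum (mtry=40, min_n=8) refines to {30,40,50} × {6,8,10}
        assert refine_grid(40, (0.75, 1.25), lo=1, hi=1000) == (30, 40, 50)
        assert refine_grid(8, (0.75, 1.25), lo=2) == (6, 8, 10)

    def test_refinement_clamps_and_dedupes(self):
        assert refine_grid(1, (0.75, 1.25), lo=1, hi=10) == (1,)
        # 0.75·2 = 1.5 and 1.25·2 = 2.5 both round to 2: grid collapses
        assert refine_grid(2, (0.75, 1.25), lo=2) == (2,)
        assert refine_grid(100, (0.75, 1.25), lo=1, hi=110) == (75, 100, 110)

    def test_separable_data_reaches_auc_one(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X = rng.integers(0, 2, (60, 10)).astype(float)
        X[:, 0] = y  # perfectly informative feature
        result = tune_forest(X, y, TuningConfig(n_trees=50), seed=0)
        assert result.auc == 1.0
        assert (result.mtry, result.min_n) == result.params

    def test_selected_pair_attains_max_over_both_stages(self, rng):
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        X = rng.random((50, 12))
        X[:, 0] = y + rng.normal(0, 0.8, 50)
        result = tune_forest(X, y, TuningConfig(n_trees=30), seed=1)
        best = max(a for _, _, a in result.stage1 + result.stage2)
        assert result.auc == best

    def test_degenerate_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            tune_forest(rng.random((20, 4)), np.ones(20, int), seed=0)


class TestPermutationImportance:
    def _planted(self, rng, n=80, p=12):
        y = rng.integers(0, 2, n)
        y[:3], y[-3:] = 1, 0
        X = rng.integers(0, 2, (n, p)).astype(np.int8)
        X[:, 0] = y  # deterministic feature
        X[:, 1] = 1  # constant feature
        return X, y

    def test_constant_column_zero_importance(self, rng):
        X, y = self._planted(rng)
        model = fit_forest(X, y, 4, 2, 60, 0)
        imp = permutation_importance(model, X, y, seed=0)
        assert imp[1] == pytest.approx(0.0, abs=1e-12)

    def test_planted_feature_dominates(self, rng):
        X, y = self._planted(rng)
        model = fit_forest(X, y, 4, 2, 60, 0)
        imp = permutation_importance(model, X, y, seed=0)
        assert np.argmax(imp) == 0

    def test_by_tree_equals_naive_full_repredict(self, rng):
        for seed in range(5):
            X, y = self._planted(np.random.default_rng(seed), n=50, p=8)
            model = fit_forest(X, y, 3, 2, 25, seed)
            fast = permutation_importance(model, X, y, n_repeats=2, seed=7)
            naive = permutation_importance(
                model, X, y, n_repeats=2, seed=7, method="naive"
            )
            assert np.array_equal(fast, naive)

    def test_duplicated_signal_still_beats_noise(self, rng):
        n = 200
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        X = rng.integers(0, 2, (n, 10)).astype(np.int8)
        signal = (rng.random(n) < np.where(y == 1, 0.95, 0.05)).astype(np.int8)
        X[:, 0] = signal
        X[:, 1] = signal  # duplicate splits the credit
        model = fit_forest(X, y, 3, 2, 100, 0)
        imp = permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert min(imp[0], imp[1]) > max(imp[2:])

    def test_oob_planted_feature_dominates_and_constant_is_zero(self, rng):
        X, y = self._planted(rng, n=100, p=10)
        model = fit_forest(X, y, 4, 2, 80, 0)
        imp = oob_permutation_importance(model, X, y, seed=0)
        assert np.argmax(imp) == 0
        assert imp[1] == pytest.approx(0.0, abs=1e-12)  # constant column

    def test_oob_deterministic_and_unused_features_zero(self, rng):
        X, y = self._planted(rng, n=60, p=30)
        model = fit_forest(X, y, 2, 2, 20, 3)
        a = oob_permutation_importance(model, X, y, seed=5)
        b = oob_permutation_importance(model, X, y, seed=5)
        assert np.array_equal(a, b)
        used = set()
        for est in model.estimators_:
            feats = est.tree_.feature
            used |= set(feats[feats >= 0].tolist())
        unused = [j for j in range(30) if j not in used]
        assert all(a[j] == 0.0 for j in unused)

    def test_invalid_repeats(self, rng):
        X, y = self._planted(rng)
        model = fit_forest(X, y, 3, 2, 10, 0)
        with pytest.raises(ValueError):
            permutation_importance(model, X, y, n_repeats=0)


class TestFitIteration:
    def test_deterministic_feature_gives_auc_one_and_top_importance(self, rng):
        n = 60
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X = rng.integers(0, 2, (n, 8)).astype(np.int8)
        X[:, 3] = y
        split = make_split(np.arange(n), y, 0.2, 0)
        r = fit_iteration(X, y, (3, 2), split, seed=0, n_trees=50)
        assert r.auc == 1.0
        assert np.argmax(r.importances) == 3
        assert r.tpr == 1.0

    def test_label_shuffled_data_has_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.r_[np.ones(40, int), np.zeros(40, int)])
            X = rng.integers(0, 2, (80, 20)).astype(np.int8)
            split = make_split(np.arange(80), y, 0.2, seed)
            r = fit_iteration(X, y, (4, 2), split, seed=seed, n_trees=30)
            aucs.append(r.auc)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_single_class_training_fold_rejected(self, rng):
        y = np.r_[np.ones(10, int), np.zeros(40, int)]
        X = rng.integers(0, 2, (50, 5)).astype(np.int8)
        split = make_split(np.arange(50), y, 0.2, 0)
        bad = split.__class__(
            balanced=split.balanced,
            train=tuple(i for i in range(10, 50)),
            test=tuple(range(10)),
            seed=0,
            test_fraction=0.2,
        )
        with pytest.raises(ValueError, match="single class"):
            fit_iteration(X, y, (2, 2), bad, seed=0, n_trees=10)


class TestRunIterations:
    def _data(self, seed=0, n=80, p=10):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(30, int), np.zeros(50, int)]
        X = rng.integers(0, 2, (n, p)).astype(np.int8)
        X[:, 0] = (rng.random(n) < np.where(y == 1, 0.9, 0.2)).astype(np.int8)
        return X, y

    def test_returns_n_results_with_distinct_splits(self):
        X, y = self._data()
        results = run_iterations(X, y, (3, 2), n_iterations=5, base_seed=1, n_trees=20)
        assert len(results) == 5
        assert len({r.split.test for r in results}) > 1

    def test_same_base_seed_reproduces_auc_vector(self):
        X, y = self._data()
        a = run_iterations(X, y, (3, 2), n_iterations=4, base_seed=5, n_trees=20)
        b = run_iterations(X, y, (3, 2), n_iterations=4, base_seed=5, n_trees=20)
        assert [r.auc for r in a] == [r.auc for r in b]
        assert all(np.array_equal(x.importances, y_) for x, y_ in
                   zip((r for r in a), (r.importances for r in b)))

    def test_rebalancing_draws_fresh_balanced_sets(self):
        X, y = self._data()
        results = run_iterations(X, y, (3, 2), n_iterations=4, base_seed=2, n_trees=10)
        assert len({r.split.balanced for r in results}) > 1
        fixed = run_iterations(
            X, y, (3, 2), n_iterations=4, base_seed=2, n_trees=10,
            rebalance_per_iteration=False,
        )
        assert len({r.split.balanced for r in fixed}) == 1


class TestConsensus:
    def _results(self, imp_matrix):
        X = np.zeros((20, imp_matrix.shape[1]), dtype=np.int8)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        split = make_split(np.arange(20), y, 0.2, 0)
        out = []
        for i, row in enumerate(imp_matrix):
            out.append(
                type("R", (), {})()  # lightweight stand-in carrying importances
            )
            r = out[-1]
            r.importances = row
            r.index = i
        return out

    def test_always_top_feature_flagged_with_full_count(self):
        rng = np.random.default_rng(0)
        imp = rng.random((10, 50)) * 1e-3
        imp[:, 7] = 0.5  # in the top-K of every iteration
        report = consensus_importance(
            self._results(imp), [f"K{j:03d}" for j in range(50)], top_k=5, min_frac=0.8
        )
        row = report.table.loc["K007"]
        assert row["top_k_count"] == 10 and bool(row["consensus"])
        assert report.table["consensus"].sum() <= 5

    def test_never_top_feature_not_flagged(self):
        imp = np.ones((6, 10))
        imp[:, 4] = 0.0
        report = consensus_importance(
            self._results(imp), [f"K{j}" for j in range(10)], top_k=3, min_frac=0.8
        )
        assert report.table.loc["K4", "top_k_count"] == 0
        assert not bool(report.table.loc["K4", "consensus"])

    def test_recount_oracle_and_order_invariance(self):
        rng = np.random.default_rng(3)
        imp = rng.random((25, 40))
        kos = [f"K{j:03d}" for j in range(40)]
        results = self._results(imp)
        report = consensus_importance(results, kos, top_k=8, min_frac=0.8)
        # brute-force recount from the stored importance matrix
        counts = np.zeros(40, dtype=int)
        for row in imp:
            order = sorted(range(40), key=lambda j: (-row[j], kos[j]))
            for j in order[:8]:
                counts[j] += 1
        for j, ko in enumerate(kos):
            assert report.table.loc[ko, "top_k_count"] == counts[j]
            assert report.table.loc[ko, "consensus"] == (counts[j] >= 20)
            assert report.table.loc[ko, "median_importance"] == np.median(imp[:, j])
        shuffled = consensus_importance(results[::-1], kos, top_k=8, min_frac=0.8)
        assert shuffled.table.sort_index().equals(report.table.sort_index())

    def test_tie_break_is_lexicographic(self):
        mask = top_k_mask(np.array([0.5, 0.5, 0.5, 0.1]), ["Kb", "Ka", "Kc", "Kd"], 2)
        # ties at 0.5 resolved by id: Ka then Kb
        assert list(mask) == [True, True, False, False]


class TestMisclassificationAudit:
    def test_perfect_classifier_has_empty_sets(self, rng):
        n = 60
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X = rng.integers(0, 2, (n, 6)).astype(np.int8)
        X[:, 0] = y
        results = run_iterations(X, y, (6, 2), n_iterations=5, base_seed=0, n_trees=50)
        audit = misclassification_audit(results)
        assert audit["consistent_false_pos"] == []
        assert audit["consistent_false_neg"] == []

    def test_adversarial_strain_lands_in_false_negatives(self, rng):
        n = 61
        y = np.r_[np.ones(31, int), np.zeros(30, int)]
        X = rng.integers(0, 2, (n, 6)).astype(np.int8)
        X[:, :] = y[:, None]  # all features track the label...
        X[0, :] = 0  # ...except strain 0: positive label, negative profile
        results = run_iterations(X, y, (3, 2), n_iterations=8, base_seed=0, n_trees=30)
        audit = misclassification_audit(results, [f"s{i}" for i in range(n)])
        appeared = any(
            0 in r.test_indices for r in results
        )
        if appeared:
            assert "s0" in audit["consistent_false_neg"]
        assert audit["consistent_false_pos"] == []

    def test_recount_from_stored_predictions(self, rng):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = rng.integers(0, 2, (40, 5)).astype(np.int8)
        results = run_iterations(X, y, (2, 2), n_iterations=6, base_seed=1, n_trees=10)
        audit = misclassification_audit(results)
        # independent recount
        app, err = {}, {}
        for r in results:
            for pos, idx in enumerate(r.test_indices):
                app[idx] = app.get(idx, 0) + 1
                if r.predictions[pos] != r.y_test[pos]:
                    err[idx] = err.get(idx, 0) + 1
        for idx, stats in audit["per_strain"].items():
            assert stats["appearances"] == app[idx]
            assert stats["errors"] == err.get(idx, 0)


class TestEstimator:
    def test_sklearn_contract_and_fitted_attributes(self, rng):
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        X = rng.integers(0, 2, (80, 12)).astype(np.int8)
        X[:, 2] = (rng.random(80) < np.where(y == 1, 0.95, 0.1)).astype(np.int8)
        clf = ConsensusForestClassifier(
            n_iterations=6, n_trees=25, top_k=3, tuning=(4, 2), random_state=0
        )
        params = clf.get_params()
        assert params["n_iterations"] == 6
        clf.set_params(n_iterations=5)
        clf.fit(X, y)
        assert clf.classes_.tolist() == [0, 1]
        assert len(clf.iteration_results_) == 5
        assert clf.feature_importances_.shape == (12,)
        assert 0.5 < clf.mean_auc_ <= 1.0
        assert "f2" in clf.consensus_features_
        preds = clf.predict(X)
        assert set(preds) <= {0, 1}
        assert clf.predict_proba(X).shape == (80, 2)

    def test_refit_with_same_seed_is_identical(self, rng):
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        X = rng.integers(0, 2, (50, 8)).astype(np.int8)
        a = ConsensusForestClassifier(
            n_iterations=3, n_trees=15, top_k=2, tuning=(3, 2), random_state=4
        ).fit(X, y)
        b = ConsensusForestClassifier(
            n_iterations=3, n_trees=15, top_k=2, tuning=(3, 2), random_state=4
        ).fit(X, y)
        assert [r.auc for r in a.iteration_results_] == [r.auc for r in b.iteration_results_]
        assert a.consensus_report_.table.equals(b.consensus_report_.table)

    def test_multiclass_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            ConsensusForestClassifier(n_iterations=2, n_trees=5).fit(
                rng.random((30, 4)), np.arange(30) % 3
            )
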