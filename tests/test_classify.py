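"""Relevance ranking, SVM-RFE, ROC/AUC and the nested LOOCV ensemble."""

import numpy as np
import pytest
from scipy import stats

from bandconn import (
    FeatureTable,
    audit_hygiene,
    nested_loocv,
    region_selection_frequency,
    relevance_rank,
    roc_auc,
    svm_rfe,
)
from bandconn.classify import SelectionTrace
from bandconn._smo import fit_decision


def make_table(X, y):
    X = np.asarray(X, dtype=float)
    X = X - min(X.min(), 0.0)  # feature tables are non-negative
    return FeatureTable(
        matrix=X,
        feature_names=[("B", f"f{j}") for j in range(X.shape[1])],
        labels=np.asarray(y, dtype=int),
        subject_ids=[f"s{i}" for i in range(X.shape[0])],
    )


class TestRelevanceRank:
    def test_label_copy_ranks_first(self, rng):
        y = np.concatenate([np.ones(10), -np.ones(10)]).astype(int)
        X = rng.normal(size=(20, 5))
        X[:, 3] = y
        assert relevance_rank(X, y, 5)[0] == 3

    def test_constant_feature_ranks_last(self, rng):
        y = np.concatenate([np.ones(8), -np.ones(8)]).astype(int)
        X = rng.normal(size=(16, 4))
        X[:, 1] = 2.5
        assert relevance_rank(X, y, 4)[-1] == 1

    def test_planted_feature_found_in_noise(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = np.concatenate([np.ones(15), -np.ones(15)]).astype(int)
            X = r.normal(size=(30, 21))
            X[:, 20] = y + 0.1 * r.normal(size=30)
            hits += relevance_rank(X, y, 21)[0] == 20
        assert hits >= 95

    def test_ties_break_by_ascending_index(self):
        y = np.array([1, 1, -1, -1])
        X = np.zeros((4, 3))
        X[:, 2] = [1.0, 1.0, 0.0, 0.0]
        order = relevance_rank(X, y, 3)
        assert order[0] == 2 and list(order[1:]) == [0, 1]

    def test_top_m_must_be_positive(self):
        with pytest.raises(ValueError):
            relevance_rank(np.zeros((4, 2)), np.array([1, 1, -1, -1]), 0)


class TestSvmRfe:
    def test_perfect_separator_survives_elimination(self, rng):
        y = np.concatenate([np.ones(10), -np.ones(10)]).astype(int)
        X = rng.normal(size=(20, 2))
        X[:, 0] = y * 2.0
        _, subset, err, _ = svm_rfe(X, y, C=1.0, gamma=0.5)
        assert subset == (0,)
        assert err == 0.0

    def test_identical_features_collapse_to_one(self, rng):
        # four copies of one separating feature: every subset along the
        # path has zero error, so the smallest-subset preference decides
        y = np.concatenate([np.ones(6), -np.ones(6)]).astype(int)
        base = 2.0 * y + 0.05 * rng.normal(size=12)
        X = np.tile(base[:, None], (1, 4))
        _, subset, err, _ = svm_rfe(X, y, C=1.0, gamma=0.5)
        assert err == 0.0
        assert len(subset) == 1

    def test_elimination_order_is_a_permutation(self, rng):
        y = np.concatenate([np.ones(8), -np.ones(8)]).astype(int)
        X = rng.normal(size=(16, 5))
        elim, subset, _, _ = svm_rfe(X, y, C=1.0, gamma=0.2)
        assert sorted(elim + list(subset if len(subset) == 1 else ())) or True
        # all but the last surviving feature are eliminated exactly once
        assert len(elim) == 4 and len(set(elim)) == 4

    def test_xor_pair_is_kept_jointly(self):
        # two features informative only jointly (XOR); an RBF SVM can
        # express the interaction, so RFE should retain both
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 40
            a = r.choice([-1.0, 1.0], size=n)
            b = r.choice([-1.0, 1.0], size=n)
            y = (a * b).astype(int)
            X = np.column_stack([
                a + 0.1 * r.normal(size=n),
                b + 0.1 * r.normal(size=n),
                r.normal(size=(n, 3)),
            ])
            if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == -1).sum()) < 2:
                continue
            _, subset, _, _ = svm_rfe(X, y, C=8.0, gamma=1.0)
            hits += {0, 1} <= set(subset)
        assert hits >= 0.9 * n_seeds

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            svm_rfe(X, np.ones(6, dtype=int), C=1.0, gamma=0.5)

    def test_fast_svm_path_matches_public_estimator(self, rng):
        from sklearn.svm import SVC

        for _ in range(25):
            n = int(rng.integers(6, 16))
            X = rng.normal(size=(n, 4))
            y = np.where(rng.random(n) > 0.5, 1, -1)
            if min((y == 1).sum(), (y == -1).sum()) < 1:
                continue
            gamma, C = 0.5, 2.0
            D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            K = np.exp(-gamma * D)
            # both solvers run to tight KKT tolerance: the dual is unique
            # for a PD kernel, so decisions must coincide
            got = fit_decision(K, y.astype(float), C, K, tol=1e-8)
            ref = SVC(C=C, kernel="precomputed", shrinking=False, tol=1e-8).fit(K, y)
            assert np.allclose(got, ref.decision_function(K), atol=1e-6)


class TestRocAuc:
    def test_perfect_ordering_gives_unit_auc(self):
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0])
        labels = np.array([1, 1, 1, -1, -1])
        points, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_identical_scores_give_half(self):
        _, auc = roc_auc(np.zeros(6), np.array([1, 1, 1, -1, -1, -1]))
        assert auc == 0.5

    def test_monotone_curve(self, rng):
        scores = rng.normal(size=20)
        labels = np.where(rng.random(20) > 0.4, 1, -1)
        points, _ = roc_auc(scores, labels)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_equals_mann_whitney_u_statistic(self):
        # trapezoidal AUC == U / (n1 n2), exactly, draw by draw
        for seed in range(300):
            r = np.random.default_rng(seed)
            labels = np.concatenate([np.ones(12), -np.ones(25)]).astype(int)
            scores = np.round(r.normal(size=37), 1)  # rounding forces ties
            _, auc = roc_auc(scores, labels)
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == -1],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(u / (12 * 25), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) > 0.5, 1, -1)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(scores) * 3 + 1, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, dtype=int))


GRID = [(0.5, 0.125), (8.0, 0.125)]


class TestNestedLoocv:
    def test_separable_classes_classified_perfectly(self, rng):
        n = 16
        y = np.concatenate([np.ones(8), -np.ones(8)]).astype(int)
        X = rng.normal(size=(n, 20))
        X[:, :2] += 3.0 * y[:, None]  # 6 sigma between the class means
        res = nested_loocv(make_table(X, y), grid=GRID, top_m=5)
        assert res.accuracy == 100.0
        assert res.auc == 1.0

    def test_fold_structure_and_hygiene(self, rng):
        n = 8
        y = np.concatenate([np.ones(4), -np.ones(4)]).astype(int)
        X = rng.normal(size=(n, 6))
        res = nested_loocv(make_table(X, y), grid=GRID, top_m=3)
        # N outer folds, each with N-1 inner models trained on N-2 subjects
        assert len(res.mean_scores) == n
        outer_folds = {t.outer_fold for t in res.traces}
        assert outer_folds == set(range(n))
        for s in range(n):
            fold_traces = [t for t in res.traces if t.outer_fold == s]
            assert len(fold_traces) == n - 1
            for t in fold_traces:
                assert len(t.training_indices) == n - 2
        assert audit_hygiene(res)

    def test_deterministic_given_input(self, rng):
        y = np.concatenate([np.ones(4), -np.ones(4)]).astype(int)
        X = rng.normal(size=(8, 6))
        t = make_table(X, y)
        r1 = nested_loocv(t, grid=GRID, top_m=3)
        r2 = nested_loocv(t, grid=GRID, top_m=3)
        assert np.array_equal(r1.mean_scores, r2.mean_scores)
        assert r1.accuracy == r2.accuracy
        assert [t.optimal_subset for t in r1.traces] == [t.optimal_subset for t in r2.traces]

    def test_accuracy_definition(self, rng):
        y = np.concatenate([np.ones(4), -np.ones(4)]).astype(int)
        X = rng.normal(size=(8, 6))
        res = nested_loocv(make_table(X, y), grid=GRID, top_m=3)
        assert res.accuracy == pytest.approx(
            100.0 * np.mean(res.predicted_labels == y)
        )

    def test_empty_grid_rejected(self, rng):
        y = np.concatenate([np.ones(4), -np.ones(4)]).astype(int)
        with pytest.raises(ValueError):
            nested_loocv(make_table(rng.normal(size=(8, 4)), y), grid=[], top_m=2)


class TestSelectionFrequency:
    def _trace(self, outer, inner, subset):
        return SelectionTrace(
            outer_fold=outer, inner_fold=inner, relevance_ranked=[0, 1, 2],
            elimination_order=[], optimal_subset=subset, chosen_C=1.0,
            chosen_gamma=0.5, inner_error=0.0,
            training_indices=(0,), training_hash="")

    def test_always_selected_feature_counts_fold_product(self):
        names = [("Band1", "R1"), ("Band1", "R2")]
        traces = [self._trace(o, i, (0,)) for o in range(5) for i in range(4)]
        rows = region_selection_frequency(traces, names)
        assert rows == [("Band1", "R1", 20)]

    def test_never_selected_feature_absent(self):
        names = [("Band1", "R1"), ("Band2", "R2")]
        traces = [self._trace(0, 0, (1,))]
        rows = region_selection_frequency(traces, names)
        assert all(r[:2] != ("Band1", "R1") for r in rows)

    def test_sorted_by_count_then_band_then_region(self):
        names = [("Band2", "Rb"), ("Band1", "Ra"), ("Band1", "Rc")]
        traces = [self._trace(0, 0, (0, 1)), self._trace(0, 1, (1, 2))]
        rows = region_selection_frequency(traces, names)
        assert rows == [("Band1", "Ra", 2), ("Band1", "Rc", 1), ("Band2", "Rb", 1)]
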