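"""Feature selection and nested leave-one-out ensemble classification.

The classifier follows a hybrid scheme designed for small-sample,
high-dimensional cohorts:

1. **Relevance ranking** — features are ordered by the absolute Pearson
   correlation between the feature column and the +/-1 label vector, and
   only the ``top_m`` most relevant enter the wrapper stage.
2. **SVM-RFE** — backward elimination: at each step, every candidate
   single-feature removal is scored by the leave-one-out (LOO) error of an
   RBF-kernel SVM on the remaining features, and the removal with the
   smallest error is committed.  The subset (over the whole elimination
   path, including the full set) with minimal LOO error is selected;
   equal-error ties go to the smaller subset.
3. **Nested LOOCV ensemble** — an outer leave-one-out loop holds out each
   subject for testing; within each outer training set, an inner
   leave-one-out loop builds one SVM per inner split, choosing the
   (C, gamma, feature subset) per split by grid search.  The held-out
   subject is classified by the average of the inner models' decision
   values (threshold 0).

All SVM fits use RBF kernels via precomputed Gram matrices: per-feature
squared-distance matrices are computed once per training set and summed
incrementally as RFE removes features, so candidate kernels cost one
elementwise exponential.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _smo
from .features import FeatureTable

#: KKT tolerance of the compiled SMO solver (libsvm's default)
SVM_TOL = 1e-3

__all__ = [
    "SelectionTrace",
    "CVResult",
    "relevance_rank",
    "svm_rfe",
    "nested_loocv",
    "region_selection_frequency",
    "roc_auc",
    "audit_hygiene",
    "default_grid",
    "fast_grid",
]


def default_grid() -> list[tuple[float, float]]:
    """Grid-search range: C in 2^-5..2^5 (odd powers), gamma in 2^-5..2^3."""
    cs = [2.0**p for p in range(-5, 6, 2)]
    gammas = [2.0**p for p in range(-5, 4, 2)]
    return [(c, g) for c in cs for g in gammas]


def fast_grid() -> list[tuple[float, float]]:
    """Reduced grid for quick runs."""
    return [(c, g) for c in (0.5, 8.0) for g in (0.125, 1.0)]


@dataclass
class SelectionTrace:
    """What one inner fold selected, and on which training subjects."""

    outer_fold: int
    inner_fold: int
    relevance_ranked: list[int]
    elimination_order: list[int]
    optimal_subset: tuple[int, ...]
    chosen_C: float
    chosen_gamma: float
    inner_error: float
    training_indices: tuple[int, ...]
    training_hash: str


@dataclass
class CVResult:
    """Outcome of a nested leave-one-out run."""

    subject_ids: list[str]
    true_labels: np.ndarray
    mean_scores: np.ndarray
    predicted_labels: np.ndarray
    accuracy: float  # percent
    roc_points: list[tuple[float, float]]
    auc: float
    traces: list[SelectionTrace] = field(default_factory=list)
    selection_frequency: list[tuple[str, str, int]] = field(default_factory=list)


def relevance_rank(X: np.ndarray, y: np.ndarray, top_m: int) -> np.ndarray:
    """Indices of the ``top_m`` features by |Pearson correlation with labels|.

    Zero-variance features get correlation 0 and rank last; ties break by
    ascending feature index.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    order = np.argsort(-np.abs(r), kind="stable")
    return order[: min(top_m, X.shape[1])]


def _pairwise_sq_diffs(X: np.ndarray) -> np.ndarray:
    """Per-feature squared-difference matrices, shape (m, n, n)."""
    diff = X[:, None, :] - X[None, :, :]
    return np.transpose(diff**2, (2, 0, 1))


def _svc_decision_precomputed(
    K_train: np.ndarray, y_train: np.ndarray, C: float, K_test_rows: np.ndarray
) -> np.ndarray:
    """Decision values of a C-SVC on a precomputed kernel.

    Equivalent to ``SVC(C=C, kernel="precomputed", shrinking=False)`` (the
    RBF dual is unique for distinct points, so decision values agree to
    solver tolerance) but through the compiled SMO solver, which skips
    per-fit estimator overhead — the RFE LOO loops perform hundreds of
    thousands of fits on <=40-sample problems.  Positive score favours
    class +1.
    """
    return _smo.fit_decision(
        K_train, np.asarray(y_train, dtype=np.float64), C, K_test_rows
    )


def _loo_decision_scores(
    K: np.ndarray, y: np.ndarray, C: float, balanced: bool = False
) -> np.ndarray:
    """Leave-one-out decision values of a C-SVC with a precomputed kernel.

    Positive score favours class +1.
    """
    y64 = np.asarray(y, dtype=np.float64)
    if _smo.NUMBA_AVAILABLE:
        return _smo.loo_decision_scores(
            np.ascontiguousarray(K, dtype=np.float64), y64, float(C), SVM_TOL, balanced
        )
    n = K.shape[0]
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):  # pragma: no cover - fallback without numba
        rest = idx != i
        scores[i] = _smo.fit_decision(
            K[np.ix_(rest, rest)], y64[rest], C, K[i, rest][None, :],
            tol=SVM_TOL, balanced=balanced,
        )[0]
    return scores


def _loo_error(scores: np.ndarray, y: np.ndarray) -> float:
    predicted = np.where(scores > 0, 1, -1)
    return float(np.mean(predicted != y))


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    relevance_order: np.ndarray | None = None,
    balanced: bool = False,
) -> tuple[list[int], tuple[int, ...], float, np.ndarray]:
    """Backward feature elimination driven by LOO error of an RBF SVM.

    Parameters
    ----------
    X : (n_subjects, n_features) training matrix (already standardized).
    y : +/-1 labels.
    C, gamma : SVM penalty and RBF width.
    relevance_order : optional ranking of the columns of X (best first),
        used only to break ties — among equal-error removals the feature
        with the worse relevance rank goes first.  Defaults to column order.

    Returns
    -------
    elimination_order : column indices in removal order (first removed first).
    optimal_subset : columns of the minimum-LOO-error subset along the path
        (the smallest among equal-error subsets).
    optimal_error : that subset's LOO error.
    optimal_scores : the LOO decision values at the optimal subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, m = X.shape
    if m < 1:
        raise ValueError("need at least one feature")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 subjects per class")
    if relevance_order is None:
        relevance_order = np.arange(m)
    rank_of = {int(f): pos for pos, f in enumerate(relevance_order)}

    d = _pairwise_sq_diffs(X)  # (m, n, n)
    D = d.sum(axis=0)

    def evaluate(D_subset: np.ndarray) -> tuple[float, np.ndarray]:
        K = np.exp(-gamma * D_subset)
        scores = _loo_decision_scores(K, y, C, balanced)
        return _loo_error(scores, y), scores

    current = list(range(m))
    elimination: list[int] = []
    best_err, best_scores = evaluate(D)
    best_subset = tuple(current)
    while len(current) > 1:
        # worse-ranked candidates first so the "<" update removes the
        # worst-ranked feature among equal-error removals
        candidates = sorted(current, key=lambda f: rank_of[f], reverse=True)
        step_best: tuple[float, int, np.ndarray] | None = None
        for f in candidates:
            err, scores = evaluate(D - d[f])
            if step_best is None or err < step_best[0]:
                step_best = (err, f, scores)
        err, removed, scores = step_best
        D = D - d[removed]
        current.remove(removed)
        elimination.append(removed)
        # prefer the smallest subset among equal-error ones: path sizes
        # strictly decrease, so "<=" keeps the latest (smallest)
        if err <= best_err:
            best_err, best_scores, best_subset = err, scores, tuple(current)
    return elimination, best_subset, best_err, best_scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    The curve starts at (0, 0), ends at (1, 1), and handles tied scores by
    moving diagonally, which makes the trapezoidal AUC identical to the
    normalized Mann-Whitney U statistic (ties counted half).  Identical
    scores for everyone give AUC 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    points = [(0.0, 0.0)]
    tp = fp = 0
    for s in np.unique(-scores):  # thresholds from high to low
        at = scores == -s
        tp += int((labels[at] == 1).sum())
        fp += int((labels[at] == -1).sum())
        points.append((fp / n_neg, tp / n_pos))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


@dataclass
class _Member:
    """One inner-fold RBF-SVM model of an outer fold's ensemble."""

    mu: np.ndarray
    sd: np.ndarray
    subset: tuple[int, ...]
    X_train: np.ndarray  # standardized training rows, subset columns only
    coef: np.ndarray  # dual coefficients y_i * alpha_i
    b: float
    gamma: float

    def decision(self, x: np.ndarray) -> float:
        xs = ((x - self.mu) / self.sd)[list(self.subset)]
        k = np.exp(-self.gamma * ((self.X_train - xs) ** 2).sum(axis=1))
        return float(k @ self.coef + self.b)


def _fit_rbf(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
             balanced: bool = False):
    """Fit a C-SVC with an RBF kernel; returns dual coefficients and bias."""
    return _smo.solve_rbf(X, y, C, gamma, balanced=balanced)


def nested_loocv(
    features: FeatureTable,
    grid: list[tuple[float, float]] | None = None,
    top_m: int = 100,
    class_weight: str | None = None,
) -> CVResult:
    """Nested full leave-one-out cross-validation with an SVM ensemble.

    For each of the N outer folds, subject ``s`` is held out and each of the
    N-1 remaining subjects is held out once more, giving N-1 inner training
    subsets of N-2 subjects.  Per inner subset, features are standardized
    (train statistics only), relevance-ranked, and SVM-RFE is run per grid
    point; the grid point whose model best classifies the inner held-out
    subject (ties: higher inner-LOO AUC at the optimal subset, then smaller
    C, then smaller gamma) is kept and one SVM is trained on the subset's
    N-2 subjects.  Subject ``s`` is classified by the mean of the N-1
    decision values, predicting +1 iff the mean is positive.  Deterministic
    given the input and grid.

    ``class_weight="balanced"`` applies inverse-frequency weighting to the
    SVM penalty (per-class C scaled by n / (2 n_class)); useful because a
    leave-one-out split always tilts the training majority against the
    held-out subject.
    """
    balanced = class_weight == "balanced"
    if class_weight not in (None, "none", "balanced"):
        raise ValueError(f"unknown class_weight {class_weight!r}")
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    grid = sorted(grid)
    X = features.matrix
    y = features.labels
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects for nested LOOCV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    mean_scores = np.empty(n)
    traces: list[SelectionTrace] = []
    for s in range(n):
        outer_train = [i for i in range(n) if i != s]
        members: list[_Member] = []
        for inner_idx, v in enumerate(outer_train):
            tr = np.array([i for i in outer_train if i != v])
            y_tr = y[tr]
            if len(np.unique(y_tr)) < 2 or min(np.bincount((y_tr + 1) // 2)) < 2:
                warnings.warn(
                    f"inner subset (outer {s}, held-out {v}) lacks two subjects "
                    "per class; skipped",
                    stacklevel=2,
                )
                continue
            mu, sd = _standardize(X[tr])
            X_tr = (X[tr] - mu) / sd
            ranked = relevance_rank(X_tr, y_tr, top_m)
            X_rfe = X_tr[:, ranked]
            x_v = (X[v] - mu) / sd

            best = None
            for C, gamma in grid:
                elim, subset_local, err, loo_scores = svm_rfe(
                    X_rfe, y_tr, C, gamma,
                    relevance_order=np.arange(len(ranked)), balanced=balanced,
                )
                subset = tuple(int(ranked[j]) for j in subset_local)
                Xsub = X_tr[:, list(subset)]
                coef, b = _fit_rbf(Xsub, y_tr, C, gamma, balanced=balanced)
                k_v = np.exp(-gamma * ((Xsub - x_v[list(subset)]) ** 2).sum(axis=1))
                v_score = float(k_v @ coef + b)
                v_err = float((1 if v_score > 0 else -1) != y[v])
                _, inner_auc = roc_auc(loo_scores, y_tr)
                # grid choice maximizes the inner-LOO AUC at the optimal
                # subset; the held-out subject breaks ties, then smaller C
                # and gamma for determinism
                key = (-inner_auc, v_err, C, gamma)
                if best is None or key < best[0]:
                    elim_global = [int(ranked[j]) for j in elim]
                    best = (key, C, gamma, subset, elim_global, err, Xsub, coef, b)
            _, C, gamma, subset, elim_global, err, Xsub, coef, b = best
            members.append(
                _Member(mu=mu, sd=sd, subset=subset, X_train=Xsub, coef=coef,
                        b=b, gamma=gamma)
            )
            tr_tuple = tuple(int(i) for i in tr)
            traces.append(
                SelectionTrace(
                    outer_fold=s,
                    inner_fold=inner_idx,
                    relevance_ranked=[int(j) for j in ranked],
                    elimination_order=elim_global,
                    optimal_subset=subset,
                    chosen_C=C,
                    chosen_gamma=gamma,
                    inner_error=err,
                    training_indices=tr_tuple,
                    training_hash=_hash_indices(tr_tuple),
                )
            )
        if not members:
            raise ValueError(f"outer fold {s}: no valid inner training subsets")
        mean_scores[s] = float(np.mean([m.decision(X[s]) for m in members]))

    predicted = np.where(mean_scores > 0, 1, -1)
    accuracy = 100.0 * float(np.mean(predicted == y))
    roc_points, auc = roc_auc(mean_scores, y)
    sel_freq = region_selection_frequency(traces, features.feature_names)
    return CVResult(
        subject_ids=list(features.subject_ids),
        true_labels=y.copy(),
        mean_scores=mean_scores,
        predicted_labels=predicted,
        accuracy=accuracy,
        roc_points=roc_points,
        auc=auc,
        traces=traces,
        selection_frequency=sel_freq,
    )


def _hash_indices(indices: tuple[int, ...]) -> str:
    return hashlib.sha256(repr(tuple(sorted(indices))).encode()).hexdigest()


def region_selection_frequency(
    traces: list[SelectionTrace], feature_names: list[tuple[str, str]]
) -> list[tuple[str, str, int]]:
    """Count how often each (band, ROI) feature enters an optimal subset.

    One count per (outer, inner) fold pair whose optimal subset contains the
    feature; features never selected are omitted.  Sorted by descending
    count, ties by band then ROI name.
    """
    if not traces:
        raise ValueError("no selection traces")
    counts: dict[int, int] = {}
    for t in traces:
        for f in t.optimal_subset:
            counts[f] = counts.get(f, 0) + 1
    rows = [(feature_names[f][0], feature_names[f][1], c) for f, c in counts.items()]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows


def audit_hygiene(result: CVResult) -> bool:
    """Verify that no outer-fold test subject trained its own fold's models.

    Every trace's training-index hash is recomputed and the outer subject's
    index is checked against the training set.  Raises ``AssertionError`` on
    any violation; returns True when the audit passes.
    """
    for t in result.traces:
        if t.training_hash != _hash_indices(t.training_indices):
            raise AssertionError("training-index hash mismatch")
        if t.outer_fold in t.training_indices:
            raise AssertionError(
                f"outer subject {t.outer_fold} appears in its own fold's training set"
            )
    return True
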