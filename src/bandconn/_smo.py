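"""Compiled SMO solver for the tiny kernel-SVM fits inside RFE loops.

SVM-RFE scores every candidate feature removal by a full leave-one-out
error, which means hundreds of thousands of C-SVC fits on problems of a few
dozen samples.  This module solves the C-SVC dual directly with the
maximal-violating-pair working-set strategy (the same algorithm libsvm
uses), compiled with numba so an entire leave-one-out pass over a
precomputed kernel is one native call.  For a positive-definite kernel the
dual solution is unique, so decision values agree with scikit-learn's SVC
to solver tolerance; a test asserts that equivalence.

Only what the pipeline needs is implemented: binary C-SVC, precomputed
kernel, per-sample box constraints (for inverse-frequency class weights),
no shrinking.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_TAU = 1e-12
_MAX_ITER = 20_000


@njit(cache=False)
def _solve_svc_warm(K: np.ndarray, y: np.ndarray, Cb: np.ndarray, tol: float,
                    alpha: np.ndarray):
    """Solve min 1/2 a'Qa - e'a, 0 <= a_t <= Cb_t, y'a = 0 with Q = yy' * K.

    ``Cb`` holds the per-sample box bound (a constant vector for the plain
    C-SVC; class-dependent for inverse-frequency weighting).  ``alpha`` is a
    feasible starting point (modified in place).  Returns (coef, b) with
    coef_i = y_i * alpha_i so that the decision value for a test point x is
    k(x, .) @ coef + b  (positive favours class +1).
    """
    n = K.shape[0]
    # G = Q alpha - e
    grad = np.empty(n)
    for t in range(n):
        s = -1.0
        for u in range(n):
            if alpha[u] != 0.0:
                s += y[t] * y[u] * K[t, u] * alpha[u]
        grad[t] = s
    it = 0
    while it < _MAX_ITER:
        # maximal violating pair over I_up / I_low
        i = -1
        j = -1
        m_val = -1e300
        M_val = 1e300
        for t in range(n):
            yg = -y[t] * grad[t]
            if (y[t] > 0 and alpha[t] < Cb[t]) or (y[t] < 0 and alpha[t] > 0):
                if yg > m_val:
                    m_val = yg
                    i = t
            if (y[t] < 0 and alpha[t] < Cb[t]) or (y[t] > 0 and alpha[t] > 0):
                if yg < M_val:
                    M_val = yg
                    j = t
        if i < 0 or j < 0 or m_val - M_val < tol:
            break
        a = K[i, i] + K[j, j] - 2.0 * y[i] * y[j] * K[i, j]
        if a < _TAU:
            a = _TAU
        delta = (m_val - M_val) / a
        # feasible interval for delta from both box constraints
        if y[i] > 0:
            lo, hi = -alpha[i], Cb[i] - alpha[i]
        else:
            lo, hi = alpha[i] - Cb[i], alpha[i]
        if y[j] > 0:
            lo2, hi2 = alpha[j] - Cb[j], alpha[j]
        else:
            lo2, hi2 = -alpha[j], Cb[j] - alpha[j]
        if lo2 > lo:
            lo = lo2
        if hi2 < hi:
            hi = hi2
        if delta > hi:
            delta = hi
        elif delta < lo:
            delta = lo
        d_ai = y[i] * delta
        d_aj = -y[j] * delta
        alpha[i] += d_ai
        alpha[j] += d_aj
        for t in range(n):
            grad[t] += y[t] * (K[t, i] * y[i] * d_ai + K[t, j] * y[j] * d_aj)
        it += 1
    # bias: mean of -yG over free SVs; with no free SV the KKT conditions
    # only bound b, so take the midpoint of the feasible interval
    # (epsilon-tolerant bound classification, as warm starts can leave
    # alpha exactly on the box boundary)
    sum_free = 0.0
    n_free = 0
    ub = 1e300
    lb = -1e300
    for t in range(n):
        eps = 1e-10 * (1.0 + Cb[t])
        yg = -y[t] * grad[t]
        if eps < alpha[t] < Cb[t] - eps:
            sum_free += yg
            n_free += 1
        elif (y[t] > 0 and alpha[t] <= eps) or (y[t] < 0 and alpha[t] >= Cb[t] - eps):
            # y_t alpha_t can only increase: lower-bound side for b
            if yg > lb:
                lb = yg
        else:
            if yg < ub:
                ub = yg
    if n_free > 0:
        b = sum_free / n_free
    else:
        b = 0.5 * (lb + ub)
    coef = alpha * y
    return coef, b


@njit(cache=False)
def _class_bounds(y: np.ndarray, C: float, balanced: bool) -> np.ndarray:
    """Per-sample box bounds; inverse-frequency weighted when balanced."""
    n = y.shape[0]
    Cb = np.full(n, C)
    if balanced:
        n_pos = 0
        for t in range(n):
            if y[t] > 0:
                n_pos += 1
        n_neg = n - n_pos
        if n_pos > 0 and n_neg > 0:
            for t in range(n):
                if y[t] > 0:
                    Cb[t] = C * n / (2.0 * n_pos)
                else:
                    Cb[t] = C * n / (2.0 * n_neg)
    return Cb


@njit(cache=False)
def loo_decision_scores(K: np.ndarray, y: np.ndarray, C: float, tol: float,
                        balanced: bool) -> np.ndarray:
    """Leave-one-out decision values over a precomputed kernel matrix.

    Each subproblem is warm-started from the full-data solution (with the
    left-out point's dual weight redistributed within its class to stay
    feasible); the dual optimum is unique for a PD kernel, so warm starting
    changes only the iteration count.
    """
    n = K.shape[0]
    scores = np.empty(n)
    Ksub = np.empty((n - 1, n - 1))
    ysub = np.empty(n - 1)
    krow = np.empty(n - 1)
    asub = np.empty(n - 1)
    alpha_full = np.zeros(n)
    Cb_full = _class_bounds(y, C, balanced)
    _solve_svc_warm(K, y, Cb_full, tol, alpha_full)
    for i in range(n):
        r = 0
        for a_ in range(n):
            if a_ == i:
                continue
            c = 0
            for b_ in range(n):
                if b_ == i:
                    continue
                Ksub[r, c] = K[a_, b_]
                c += 1
            ysub[r] = y[a_]
            krow[r] = K[i, a_]
            asub[r] = alpha_full[a_]
            r += 1
        Cb = _class_bounds(ysub, C, balanced)
        # clip the start into the subproblem's box (weighted bounds shift
        # when the class counts change), then restore feasibility: move the
        # removed point's weight onto same-class points with box room, else
        # shrink the other class
        deficit = alpha_full[i]
        for t in range(n - 1):
            if asub[t] > Cb[t]:
                excess = asub[t] - Cb[t]
                asub[t] = Cb[t]
                if ysub[t] == y[i]:
                    deficit += excess
                else:
                    deficit -= excess
        if deficit < 0.0:
            # too much same-class weight was clipped away: rebuild cold
            for t in range(n - 1):
                asub[t] = 0.0
            deficit = 0.0
        if deficit > 0.0:
            for t in range(n - 1):
                if deficit <= 0.0:
                    break
                if ysub[t] == y[i] and asub[t] < Cb[t]:
                    room = Cb[t] - asub[t]
                    step = room if room < deficit else deficit
                    asub[t] += step
                    deficit -= step
            if deficit > 0.0:
                for t in range(n - 1):
                    if deficit <= 0.0:
                        break
                    if ysub[t] != y[i] and asub[t] > 0.0:
                        step = asub[t] if asub[t] < deficit else deficit
                        asub[t] -= step
                        deficit -= step
            if deficit > 1e-12:  # no feasible redistribution: cold start
                for t in range(n - 1):
                    asub[t] = 0.0
        coef, b = _solve_svc_warm(Ksub, ysub, Cb, tol, asub)
        s = b
        for t in range(n - 1):
            s += krow[t] * coef[t]
        scores[i] = s
    return scores


def fit_decision(
    K_train: np.ndarray, y_train: np.ndarray, C: float, K_test_rows: np.ndarray,
    tol: float = 1e-6, balanced: bool = False,
) -> np.ndarray:
    """Fit once on a precomputed kernel and return test decision values."""
    y64 = np.ascontiguousarray(y_train, dtype=np.float64)
    coef, b = _solve_svc_warm(
        np.ascontiguousarray(K_train, dtype=np.float64),
        y64,
        _class_bounds(y64, float(C), balanced),
        float(tol),
        np.zeros(len(y64)),
    )
    return K_test_rows @ coef + b


def solve_rbf(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
              tol: float = 1e-6, balanced: bool = False):
    """Fit a C-SVC with an RBF kernel; returns dual coefficients and bias."""
    X = np.asarray(X, dtype=np.float64)
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    K = np.ascontiguousarray(np.exp(-gamma * D))
    y64 = np.ascontiguousarray(y, dtype=np.float64)
    return _solve_svc_warm(
        K, y64, _class_bounds(y64, float(C), balanced), float(tol), np.zeros(len(y64))
    )
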