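"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the mathematical
definitions, not by calling the code under test: bisection instead of
the sort-based projection, long-run projected gradient instead of the
primal-dual scheme, exhaustive pair counting instead of rank-based AUC.
"""

from __future__ import annotations

import numpy as np


def huber_scalar(t: float, delta: float) -> float:
    if abs(t) <= delta:
        return t * t / (2.0 * delta)
    return abs(t) - delta / 2.0


def objective_reference(W, mu, X, Y, delta, rho, loss="huber") -> float:
    """Straight-line recomputation of the training criterion."""
    R = Y @ mu - X @ W
    if loss == "huber":
        fit = sum(huber_scalar(t, delta) for t in R.ravel())
    else:
        fit = 0.5 * sum(t * t for t in R.ravel())
    k = mu.shape[0]
    pen = 0.5 * rho * sum(t * t for t in (np.eye(k) - mu).ravel())
    return fit + pen


def project_l1_ball_bisect(V, eta: float, tol: float = 1e-12) -> np.ndarray:
    """KKT soft-threshold projection via bisection on the threshold."""
    V = np.asarray(V, dtype=float)
    a = np.abs(V)
    if a.sum() <= eta:
        return V.copy()
    if eta == 0:
        return np.zeros_like(V)
    lo, hi = 0.0, a.max()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = np.maximum(a - mid, 0.0).sum()
        if s > eta:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    theta = 0.5 * (lo + hi)
    return np.sign(V) * np.maximum(a - theta, 0.0)


def solve_reference(
    X, Y, eta, delta, rho, loss="huber", iters=60000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Long-run projected-gradient minimizer of the training criterion.

    The Huber loss is smooth (gradient Lipschitz with constant
    ||A||^2/delta + rho), so projected gradient with a 1/L step
    converges to the constrained optimum; we track the best objective
    seen on the feasible path.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    m, d = X.shape
    k = Y.shape[1]
    # dense operator norm via SVD of the stacked linear map
    A = operator_matrix(X, Y)
    op = np.linalg.svd(A, compute_uv=False)[0]
    L = op**2 / (delta if loss == "huber" else 1.0) + rho
    W = np.zeros((d, k))
    mu = np.eye(k)
    I = np.eye(k)
    best = objective_reference(W, mu, X, Y, delta, rho, loss)
    bestWmu = (W.copy(), mu.copy())
    for _ in range(iters):
        R = Y @ mu - X @ W
        G = np.clip(R / delta, -1.0, 1.0) if loss == "huber" else R
        gW = -X.T @ G
        gmu = Y.T @ G + rho * (mu - I)
        W = project_l1_ball_bisect(W - gW / L, eta)
        mu = mu - gmu / L
        obj = objective_reference(W, mu, X, Y, delta, rho, loss)
        if obj < best:
            best = obj
            bestWmu = (W.copy(), mu.copy())
    return bestWmu[0], bestWmu[1], best


def operator_matrix(X, Y) -> np.ndarray:
    """Dense matrix of the linear map (W, mu) -> Y mu - X W (row-major vec)."""
    m, d = X.shape
    k = Y.shape[1]
    n_in = d * k + k * k
    A = np.zeros((m * k, n_in))
    for j in range(n_in):
        v = np.zeros(n_in)
        v[j] = 1.0
        W = v[: d * k].reshape(d, k)
        mu = v[d * k :].reshape(k, k)
        A[:, j] = (Y @ mu - X @ W).ravel()
    return A


def auc_pair_counting(scores, truth) -> float:
    """Exhaustive Mann-Whitney AUC: every positive-negative pair, ties 1/2."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_tiny_instance(rng, m_max=10, d_max=6):
    """Small random scaled two-class instance for solver comparisons."""
    m = int(rng.integers(4, m_max + 1))
    d = int(rng.integers(2, d_max + 1))
    X = rng.standard_normal((m, d))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = np.zeros(m, dtype=int)
    y[rng.permutation(m)[: m // 2]] = 1
    Y = np.eye(2)[y]
    return X, Y
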