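"""Primal-dual solver for sparse centroid learning.

The training criterion couples a d x k projection matrix W and a k x k
centroid matrix mu through a robust data-fit term::

    min_{W, mu}  h_delta(Y mu - X W) + (rho/2) ||I_k - mu||_F^2
    subject to   ||W||_1 <= eta

where h_delta is the Huber function applied entrywise and summed,
||W||_1 is the entrywise sum of absolute values (the vectorized l1
norm, which induces feature sparsity in the rows of W), and the
centroids are regularized toward the identity so the trivial solution
(W, mu) = (0, 0) is excluded.

The problem is "loss o linear map + separable penalties", the canonical
setting for the Chambolle-Pock primal-dual splitting: the dual variable
Z lives in the residual space, the Huber conjugate prox is an entrywise
clipped shrinkage, the W-prox is Euclidean projection onto the l1 ball,
and the mu-prox is a closed-form quadratic step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolverConfig",
    "SolverResult",
    "huber_value",
    "huber_dual_prox",
    "project_l1_ball",
    "estimate_operator_norm",
    "objective",
    "pd_solve",
]


@dataclass
class SolverConfig:
    """Parameters of the primal-dual solver.

    sigma / tau are the dual and primal step sizes; when ``auto_steps``
    is true they are set to 0.99 / ||A|| where A(W, mu) = Y mu - X W,
    which satisfies the convergence condition sigma * tau * ||A||^2 <= 1.
    ``delta`` is the Huber knee (quadratic for |t| <= delta, linear
    beyond), ``rho_penalty`` the weight pulling mu toward the identity,
    and ``eta`` the radius of the l1 ball constraining W.
    """

    sigma: float | None = None
    tau: float | None = None
    delta: float = 0.3
    rho_penalty: float = 1.0
    eta: float = 5.0
    loss: str = "huber"
    max_iter: int = 2000
    tol: float = 1e-6
    auto_steps: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.rho_penalty <= 0:
            raise ValueError("rho_penalty must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.loss not in ("huber", "squared_l2"):
            raise ValueError("loss must be 'huber' or 'squared_l2'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not self.auto_steps:
            if self.sigma is None or self.tau is None:
                raise ValueError("sigma and tau required when auto_steps is off")
            if self.sigma <= 0 or self.tau <= 0:
                raise ValueError("sigma and tau must be positive")


@dataclass
class SolverResult:
    """Solver output: the learned (W, mu) pair plus diagnostics."""

    W: np.ndarray
    mu: np.ndarray
    objective_trace: list[float]
    iterations_run: int
    converged: bool
    w_l1_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "objective_trace": self.objective_trace,
            "w_l1_trace": self.w_l1_trace,
        }


def huber_value(t, delta: float) -> float:
    """Huber function h_delta, summed over all entries of ``t``.

    h_delta(t) = t^2 / (2 delta) for |t| <= delta, |t| - delta/2 beyond:
    quadratic near zero, linear in the tails, continuous at the knee.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    vals = np.where(a <= delta, t * t / (2.0 * delta), a - delta / 2.0)
    return float(np.sum(vals))


def huber_dual_prox(Z, sigma: float, delta: float) -> np.ndarray:
    """Resolvent of sigma * h_delta^* : entrywise z -> clip(z/(1+sigma*delta), -1, 1).

    The Huber conjugate is h_delta^*(z) = delta z^2 / 2 on [-1, 1] and
    +inf outside, so its prox is a shrinkage followed by clipping.
    """
    if sigma <= 0 or delta <= 0:
        raise ValueError("sigma and delta must be positive")
    Z = np.asarray(Z, dtype=float)
    return np.clip(Z / (1.0 + sigma * delta), -1.0, 1.0)


def _squared_l2_dual_prox(Z, sigma: float) -> np.ndarray:
    # conjugate of (1/2)||.||^2 is itself; prox of sigma*f* is z/(1+sigma)
    return np.asarray(Z, dtype=float) / (1.0 + sigma)


def project_l1_ball(V, eta: float) -> np.ndarray:
    """Euclidean projection of ``V`` onto {M : sum |M_ij| <= eta}.

    Sort-based exact algorithm: the projection is entrywise
    soft-thresholding at the level where the thresholded magnitudes sum
    to eta, found from the cumulative sums of the sorted magnitudes.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    V = np.asarray(V, dtype=float)
    mags = np.abs(V)
    if mags.sum() <= eta:
        return V.copy()
    if eta == 0:
        return np.zeros_like(V)
    u = np.sort(mags.ravel())[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, u.size + 1)
    rho = np.nonzero(u * idx > (css - eta))[0][-1]
    theta = (css[rho] - eta) / (rho + 1.0)
    return np.sign(V) * np.maximum(mags - theta, 0.0)


def estimate_operator_norm(
    X: np.ndarray, Y: np.ndarray, iters: int = 100, seed: int = 0
) -> float:
    """Operator norm of A(W, mu) = Y mu - X W by power iteration on A^T A.

    Deterministic given ``seed``; accuracy improves geometrically with
    ``iters`` (ratio of the top two squared singular values).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0 or Y.size == 0:
        raise ValueError("matrices must be nonempty")
    d = X.shape[1]
    k = Y.shape[1]
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((d, k))
    mu = rng.standard_normal((k, k))
    norm = float(np.sqrt(np.sum(W**2) + np.sum(mu**2)))
    W /= norm
    mu /= norm
    est = 0.0
    for _ in range(iters):
        Z = Y @ mu - X @ W
        W_next = -X.T @ Z
        mu_next = Y.T @ Z
        norm = float(np.sqrt(np.sum(W_next**2) + np.sum(mu_next**2)))
        if norm == 0.0:
            return 0.0
        W = W_next / norm
        mu = mu_next / norm
        est = np.sqrt(norm)  # ||A^T A v|| for unit v -> sigma_max^2
    return float(est)


def objective(
    W: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    config: SolverConfig,
) -> float:
    """Training criterion value at (W, mu)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    mu = np.asarray(mu, dtype=float)
    m, d = X.shape
    k = Y.shape[1]
    if Y.shape[0] != m or W.shape != (d, k) or mu.shape != (k, k):
        raise ValueError(
            f"inconsistent shapes: X {X.shape}, Y {Y.shape}, W {W.shape}, mu {mu.shape}"
        )
    R = Y @ mu - X @ W
    if config.loss == "huber":
        fit = huber_value(R, config.delta)
    else:
        fit = 0.5 * float(np.sum(R**2))
    penalty = 0.5 * config.rho_penalty * float(np.sum((np.eye(k) - mu) ** 2))
    return fit + penalty


def pd_solve(X: np.ndarray, Y: np.ndarray, config: SolverConfig) -> SolverResult:
    """Chambolle-Pock iteration for the constrained training criterion.

    Updates, with extrapolated points (W_bar, mu_bar)::

        Z    <- prox_{sigma f*}(Z + sigma (Y mu_bar - X W_bar))
        W+   <- project_l1_ball(W + tau X^T Z, eta)
        mu+  <- (mu - tau Y^T Z + tau rho I_k) / (1 + tau rho)
        bar  <- 2 (W+, mu+) - (W, mu)

    Initialization is deterministic: W = 0, mu = I_k, Z = 0. Every
    iterate is primal-feasible by construction. Convergence is declared
    on the relative change of (W, mu); the objective trace is recorded
    for diagnostics only (primal-dual objectives are not monotone).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m, d = X.shape
    k = Y.shape[1]
    if Y.shape[0] != m:
        raise ValueError("X and Y must have the same number of rows")

    if config.auto_steps:
        L = estimate_operator_norm(X, Y, iters=100, seed=0)
        L = max(L, 1e-12)
        sigma = tau = 0.99 / L
    else:
        sigma, tau = config.sigma, config.tau

    W = np.zeros((d, k))
    mu = np.eye(k)
    Z = np.zeros((m, k))
    W_bar = W.copy()
    mu_bar = mu.copy()

    obj_trace: list[float] = []
    l1_trace: list[float] = []
    converged = False
    it = 0
    I_k = np.eye(k)
    for it in range(1, config.max_iter + 1):
        Z_in = Z + sigma * (Y @ mu_bar - X @ W_bar)
        if config.loss == "huber":
            Z = huber_dual_prox(Z_in, sigma, config.delta)
        else:
            Z = _squared_l2_dual_prox(Z_in, sigma)

        W_new = project_l1_ball(W + tau * (X.T @ Z), config.eta)
        mu_new = (mu - tau * (Y.T @ Z) + tau * config.rho_penalty * I_k) / (
            1.0 + tau * config.rho_penalty
        )

        if not (np.all(np.isfinite(W_new)) and np.all(np.isfinite(mu_new))):
            raise FloatingPointError(f"non-finite iterate at iteration {it}")

        obj_trace.append(objective(W_new, mu_new, X, Y, config))
        l1_trace.append(float(np.abs(W_new).sum()))

        change = np.sqrt(np.sum((W_new - W) ** 2) + np.sum((mu_new - mu) ** 2))
        scale = max(1.0, np.sqrt(np.sum(W**2) + np.sum(mu**2)))

        W_bar = 2.0 * W_new - W
        mu_bar = 2.0 * mu_new - mu
        W, mu = W_new, mu_new

        if change / scale < config.tol:
            converged = True
            break

    return SolverResult(
        W=W,
        mu=mu,
        objective_trace=obj_trace,
        iterations_run=it,
        converged=converged,
        w_l1_trace=l1_trace,
    )
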