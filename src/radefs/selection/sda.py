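"""Sparse discriminant analysis by elastic-net penalized optimal scoring.

The discriminant directions solve, per direction k,

    min_{beta, theta_k}  || Y theta_k - X beta ||^2
                         + lambda ||beta||_1 + gamma2 ||beta||_2^2

where ``Y`` is the n x K class-indicator matrix and the score vectors
``theta_k`` are orthonormal in the class-proportion inner product (and
orthogonal to the constant score).  Alternating minimization: an elastic-net
coordinate-descent solve for beta, a closed-form projection + normalization
for theta.  The selected support is the union of nonzero coefficient rows
across the K-1 directions; the L1 weight is chosen by bisection so the
support size hits the requested subset size as closely as achievable.

A single-direction mode (``q=1``) matching the scalar-response formulation is
available for the two-class case and for oracle tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..cohort import Cohort
from .base import SelectionRequest, SelectionResult, candidate_pool


def elastic_net_cd(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    gamma2: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Cyclic coordinate descent for  ||y - X beta||^2 + lam |beta|_1
    + gamma2 ||beta||_2^2  (no intercept; covariance updates)."""
    n, p = X.shape
    G = X.T @ X
    c = X.T @ y
    diag = np.diag(G).copy()
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    Gb = G @ beta
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            rho = c[j] - Gb[j] + diag[j] * beta[j]
            bj = np.sign(rho) * max(abs(rho) - lam / 2.0, 0.0) / (diag[j] + gamma2)
            delta = bj - beta[j]
            if delta != 0.0:
                Gb += G[:, j] * delta
                beta[j] = bj
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


@dataclass
class SDAResultDetail:
    """Fitted directions at the chosen penalty: beta (d x q), theta (K x q),
    the penalty used, and the support before truncation to p."""

    beta: np.ndarray
    theta: np.ndarray
    lam: float
    gamma2: float
    support: list[str]


def _fit_sda(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    gamma2: float,
    q: int,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential optimal-scoring SDA; returns (beta d x q, theta K x q)."""
    n, d = X.shape
    K = Y.shape[1]
    D = (Y.T @ Y) / n  # class proportions on the diagonal
    Dinv = np.linalg.pinv(D)
    ones = np.ones(K)

    thetas: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    rng = np.random.default_rng(0)
    for k in range(q):
        theta = np.zeros(K)
        theta[k + 1 if k + 1 < K else 0] = 1.0
        theta = _project_scores(theta, thetas, D, ones)
        beta = np.zeros(d)
        for _ in range(max_iter):
            target = Y @ theta
            beta_new = elastic_net_cd(X, target, lam, gamma2, beta0=beta)
            s = Dinv @ (Y.T @ (X @ beta_new)) / n
            theta_new = _project_scores(s, thetas, D, ones)
            if np.linalg.norm(theta_new) == 0:  # degenerate: no signal left
                theta_new = _project_scores(rng.standard_normal(K), thetas, D, ones)
            change = np.max(np.abs(beta_new - beta)) if beta_new.size else 0.0
            beta, theta = beta_new, theta_new
            if change < tol:
                break
        thetas.append(theta)
        betas.append(beta)
    return np.column_stack(betas), np.column_stack(thetas)


def _project_scores(
    s: np.ndarray, prev: list[np.ndarray], D: np.ndarray, ones: np.ndarray
) -> np.ndarray:
    """Project out the constant score and earlier directions (D-inner
    product), then D-normalize."""
    v = s.astype(float).copy()
    for u in [ones] + prev:
        denom = u @ D @ u
        if denom > 0:
            v -= (v @ D @ u) / denom * u
    norm = np.sqrt(v @ D @ v)
    return v / norm if norm > 1e-12 else np.zeros_like(v)


def sda_select(
    cohort: Cohort,
    request: SelectionRequest,
    lambda_grid: tuple[float, float] | None = None,
    gamma2: float = 1e-2,
    q: int | None = None,
    task: str = "three_class",
) -> SelectionResult:
    """Select ``request.p`` features by SDA support, tuning lambda by bisection.

    ``lambda_grid`` optionally bounds the bisection bracket (low, high).
    """
    pool = candidate_pool(cohort, request)
    idx = cohort.feature_index(pool)
    X = cohort.X[:, idx]
    # standardize: SDA expects centered, unit-variance columns
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd

    from ..evaluation import task_labels

    y, _ = task_labels(cohort.labels, task)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("SDA needs at least two classes")
    Y = np.zeros((len(y), len(classes)))
    for i, v in enumerate(y):
        Y[i, classes.index(v)] = 1.0
    q = q if q is not None else len(classes) - 1

    def support_at(lam: float) -> tuple[np.ndarray, np.ndarray]:
        beta, theta = _fit_sda(X, Y, lam, gamma2, q)
        return beta, theta

    lam_max = 2.0 * float(np.abs(X.T @ Y).max())
    lo, hi = (lambda_grid if lambda_grid is not None
              else (lam_max * 1e-5, lam_max))
    best: tuple[int, float, np.ndarray, np.ndarray] | None = None

    def consider(lam: float) -> int:
        nonlocal best
        beta, theta = support_at(lam)
        size = int((np.abs(beta).max(axis=1) > 1e-8).sum())
        if size > 0:
            score = (abs(size - request.p), lam)
            if best is None or score < (abs(best[0] - request.p), best[1]):
                best = (size, lam, beta, theta)
        return size

    size_lo = consider(lo)
    size_hi = consider(hi)
    if size_lo < request.p:
        warnings.warn(
            f"support at the smallest penalty is {size_lo} < p={request.p}; "
            "padding by coefficient magnitude", stacklevel=2,
        )
    a, b = lo, hi
    for _ in range(30):
        if best is not None and best[0] == request.p:
            break
        mid = float(np.sqrt(a * b))  # bisection on the log scale
        size_mid = consider(mid)
        if size_mid >= request.p:
            a = mid
        else:
            b = mid
    if best is None:  # even the smallest penalty shrank everything to zero
        warnings.warn("no penalty achieved a nonempty support; using the "
                      "least-penalized solution", stacklevel=2)
        beta, theta = support_at(lo)
        best = (0, lo, beta, theta)

    size, lam, beta, theta = best
    row_norm = np.sqrt((beta**2).sum(axis=1))
    support_order = sorted(
        range(len(pool)),
        key=lambda j: (-int(row_norm[j] > 1e-8), -float(row_norm[j]), pool[j]),
    )
    selected = [pool[j] for j in support_order[: request.p]]
    support = [pool[j] for j in np.flatnonzero(row_norm > 1e-8)]
    freq = {n: 1.0 for n in selected}
    detail = SDAResultDetail(beta, theta, lam, gamma2, support)
    return SelectionResult(request, selected, freq, trace=[detail])
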