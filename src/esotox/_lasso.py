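"""L1-penalized logistic regression via IRLS + cyclic coordinate descent.

Solves, for a decreasing penalty sequence with warm starts,

    min_{b0, beta}  (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i]
                    + lambda * ||beta||_1,        eta_i = b0 + x_i . beta

with an unpenalized intercept. The outer loop forms the iteratively
reweighted least-squares quadratic approximation (weights w = mu(1-mu),
working residual (y - mu)/w); the inner loop is cyclic coordinate descent
with soft-thresholding, run in covariance form: the weighted Gram matrix and
gradient are maintained so each coordinate update costs O(p) rather than
O(n). Full sweeps alternate with active-set iteration. Convergence is
measured on the quadratic objective change per coordinate,
``max_j den_j * delta_j^2 < tol``, the customary criterion for penalized
GLM coordinate descent. Weights are floored at 1e-6 and the linear predictor
is clipped at +/-30 before exponentiation.

Predictors are assumed standardized by the caller (the packaged pipeline
always z-scores on the training rows first).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lasso_logistic_path", "lambda_grid", "binomial_deviance"]


@njit(cache=True)
def _cd_sweep(G, W1, wsum, grad, beta, b0, lam, n, p, active_only, active):
    """One coordinate-descent sweep in covariance form; returns (b0, max obj delta)."""
    max_delta = 0.0
    # intercept (unpenalized); grad0 = wsum * (weighted mean residual)
    d0 = grad[p] / wsum
    if d0 != 0.0:
        b0 += d0
        for k in range(p):
            grad[k] -= W1[k] * d0
        grad[p] = 0.0
        obj = (wsum / n) * d0 * d0
        if obj > max_delta:
            max_delta = obj
    for j in range(p):
        if active_only and not active[j]:
            continue
        den = G[j, j] / n
        if den <= 0.0:
            continue
        num = grad[j] / n + den * beta[j]
        if num > lam:
            new_bj = (num - lam) / den
        elif num < -lam:
            new_bj = (num + lam) / den
        else:
            new_bj = 0.0
        d = new_bj - beta[j]
        if d != 0.0:
            beta[j] = new_bj
            for k in range(p):
                grad[k] -= G[k, j] * d
            grad[p] -= W1[j] * d
            obj = den * d * d
            if obj > max_delta:
                max_delta = obj
    return b0, max_delta


@njit(cache=True)
def _cd_solve(G, W1, wsum, grad, beta, b0, lam, n, p, tol, max_inner):
    """Solve the penalized weighted least-squares subproblem by CD.

    Alternates full sweeps with active-set iteration; mutates ``beta`` and
    ``grad`` in place and returns the updated intercept.
    """
    active = np.zeros(p, dtype=np.bool_)
    for _round in range(max_inner):
        b0, delta_full = _cd_sweep(G, W1, wsum, grad, beta, b0, lam, n, p, False, active)
        if delta_full < tol:
            break
        for j in range(p):
            active[j] = beta[j] != 0.0
        for _sweep in range(max_inner):
            b0, delta = _cd_sweep(G, W1, wsum, grad, beta, b0, lam, n, p, True, active)
            if delta < tol:
                break
    return b0


@njit(cache=True)
def _path(X, XT, y, lambdas, tol, max_outer, max_inner):
    n, p = X.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)

    beta = np.zeros(p)
    pbar = y.mean()
    b0 = np.log(pbar / (1.0 - pbar))

    w = np.empty(n)
    r = np.empty(n)
    XwT = np.empty((p, n))
    grad = np.empty(p + 1)
    beta_old = np.empty(p)

    for l in range(n_lam):
        lam = lambdas[l]
        for _outer in range(max_outer):
            b0_old = b0
            for j in range(p):
                beta_old[j] = beta[j]

            # IRLS quadratic approximation at the current (b0, beta)
            eta = np.dot(X, beta)
            wsum = 0.0
            g0 = 0.0
            for i in range(n):
                e = eta[i] + b0
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                m = 1.0 / (1.0 + np.exp(-e))
                wi = m * (1.0 - m)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                wsum += wi
                r[i] = (y[i] - m) / wi
                g0 += wi * r[i]

            # weighted Gram matrix, column sums and gradient (BLAS matmuls
            # on contiguous operands)
            for j in range(p):
                for i in range(n):
                    XwT[j, i] = XT[j, i] * w[i]
            G = np.dot(XwT, X)
            grad[:p] = np.dot(XwT, r)
            grad[p] = g0
            W1 = np.sum(XwT, axis=1)

            b0 = _cd_solve(G, W1, wsum, grad, beta, b0, lam, n, p, tol, max_inner)

            # IRLS step convergence on the same objective scale
            step = (wsum / n) * (b0 - b0_old) ** 2
            for j in range(p):
                obj = (G[j, j] / n) * (beta[j] - beta_old[j]) ** 2
                if obj > step:
                    step = obj
            if step < tol:
                break
        coefs[l] = beta
        intercepts[l] = b0
    return coefs, intercepts


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 50,
    max_inner: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path over a (typically decreasing) penalty sequence.

    Returns ``(coefs, intercepts)`` with ``coefs[k]`` the slope vector at
    ``lambdas[k]``. ``tol`` is on the per-coordinate quadratic objective
    change (glmnet-style), not on raw parameter deltas.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be (n, p) with y of length n")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))) or uniq.size < 2:
        raise ValueError("y must be binary with both classes present")
    if np.any(lambdas < 0):
        raise ValueError("penalties must be non-negative")
    XT = np.ascontiguousarray(X.T)
    return _path(X, XT, y, lambdas, tol, max_outer, max_inner)


def lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambda: int = 100, min_ratio: float = 1e-2
) -> np.ndarray:
    """Decreasing log-spaced penalty grid from the data-driven lambda_max.

    ``lambda_max = max_j |x_j^T (y - ybar)| / n`` is the smallest penalty at
    which every slope is zero (for standardized predictors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / X.shape[0]
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def binomial_deviance(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood, probability-clipped."""
    p = np.clip(np.asarray(probs, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
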