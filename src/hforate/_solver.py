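"""L1-penalized logistic regression solved along a penalty path.

Cyclical coordinate descent on an iteratively reweighted quadratic
approximation of the binomial log-likelihood (the glmnet algorithm), with
warm starts down a descending lambda grid.  The objective per lambda is

    (1/n) * sum_i log(1 + exp(-yt_i * eta_i)) + lambda * ||beta||_1

with an unpenalized intercept; features are expected standardized.  Written
in-package because the simulation studies need thousands of cross-validated
path fits per run, which must complete in milliseconds each.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lambda_max", "lambda_grid", "lasso_logistic_path", "deviance"]


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero."""
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def lambda_grid(lmax: float, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Descending logarithmic grid from lambda_max over ``decades`` decades."""
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)


@njit(cache=False)
def _sweep(X, xsq, w, z, eta, beta, b0, lam, n, p, active_only):
    """One cyclical coordinate-descent sweep; returns (max change, b0)."""
    maxd = 0.0
    for j in range(p):
        if active_only and beta[j] == 0.0:
            continue
        num = 0.0
        denom = 0.0
        for i in range(n):
            num += w[i] * X[i, j] * (z[i] - eta[i] + X[i, j] * beta[j])
            denom += w[i] * xsq[i, j]
        num /= n
        denom /= n
        if denom <= 0.0:
            continue
        if num > lam:
            bj = (num - lam) / denom
        elif num < -lam:
            bj = (num + lam) / denom
        else:
            bj = 0.0
        d = bj - beta[j]
        if d != 0.0:
            for i in range(n):
                eta[i] += X[i, j] * d
            beta[j] = bj
            if abs(d) > maxd:
                maxd = abs(d)
    # unpenalized intercept
    num0 = 0.0
    den0 = 0.0
    for i in range(n):
        num0 += w[i] * (z[i] - eta[i])
        den0 += w[i]
    d0 = num0 / den0
    b0 += d0
    for i in range(n):
        eta[i] += d0
    if abs(d0) > maxd:
        maxd = abs(d0)
    return maxd, b0


@njit(cache=False)
def _path(X, y, lambdas, tol, max_outer, max_sweeps):  # pragma: no cover
    n, p = X.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    xsq = X * X
    # null deviance, for early path termination on (near-)saturated fits
    dev0 = -2.0 * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    saturated_at = -1
    dev_prev = dev0
    stagnant = 0
    for li in range(nl):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # quadratic (IRLS) approximation at the current linear predictor
            pr = np.empty(n)
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                pr[i] = 1.0 / (1.0 + np.exp(-e))
            w = pr * (1.0 - pr)
            for i in range(n):
                if w[i] < 1e-3:
                    w[i] = 1e-3
            z = eta + (y - pr) / w
            # full sweep to update the active set, then cheap active-set
            # sweeps to convergence, repeated until a full sweep is quiet
            outer_delta = 0.0
            for _cycle in range(max_outer):
                maxd_full, b0 = _sweep(X, xsq, w, z, eta, beta, b0, lam,
                                       n, p, False)
                if maxd_full > outer_delta:
                    outer_delta = maxd_full
                if maxd_full < tol:
                    break
                for _s in range(max_sweeps):
                    maxd, b0 = _sweep(X, xsq, w, z, eta, beta, b0, lam,
                                      n, p, True)
                    if maxd < tol:
                        break
            if outer_delta < 100.0 * tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
        # training deviance; once the fit is essentially saturated, further
        # relaxation only inflates coefficients (glmnet-style stop)
        dev = 0.0
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            pi = 1.0 / (1.0 + np.exp(-e))
            if pi < 1e-12:
                pi = 1e-12
            elif pi > 1.0 - 1e-12:
                pi = 1.0 - 1e-12
            dev -= 2.0 * (y[i] * np.log(pi) + (1.0 - y[i]) * np.log(1.0 - pi))
        dev /= n
        # degenerate overfit: odds ratios beyond e^8 per SD can never win
        # cross-validation; stop descending the path
        bmax = 0.0
        for j in range(p):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
        if bmax > 8.0:
            saturated_at = li
            break
        # saturated, or no longer improving: smaller penalties only inflate
        # coefficients without changing the fit (glmnet-style stop)
        if dev < 0.9 * dev0 and dev_prev - dev < 1e-4 * dev0:
            stagnant += 1
        else:
            stagnant = 0
        dev_prev = dev
        if dev < 0.001 * dev0 or stagnant >= 2:
            saturated_at = li
            break
    if saturated_at >= 0:
        for li in range(saturated_at + 1, nl):
            coefs[li] = coefs[saturated_at]
            intercepts[li] = intercepts[saturated_at]
    return intercepts, coefs


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-6,
    max_outer: int = 8,
    max_sweeps: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the whole penalty path; returns (intercepts, coefs[nl, p])."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return _path(X, y, np.asarray(lambdas, dtype=np.float64), tol,
                 max_outer, max_sweeps)


def deviance(intercept: float | np.ndarray, coef: np.ndarray,
             X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean binomial deviance, vectorized over a path.

    ``coef`` may be (p,) or (nl, p); returns scalar array or (nl,).
    """
    coef = np.atleast_2d(coef)
    eta = np.clip(np.atleast_1d(intercept)[:, None] + coef @ X.T, -30, 30)
    pr = 1.0 / (1.0 + np.exp(-eta))
    pr = np.clip(pr, 1e-12, 1 - 1e-12)
    ll = y[None, :] * np.log(pr) + (1 - y[None, :]) * np.log(1 - pr)
    return -2.0 * ll.mean(axis=1)
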