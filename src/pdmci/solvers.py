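"""Elastic-net penalized logistic and multinomial regression with penalty factors.

Solves, for binary outcomes,

    min_{b0, b}  (1/n) Σ_i [log(1 + exp(η_i)) − y_i η_i]
                 + λ Σ_j pf_j ( α |b_j| + (1−α)/2 b_j² ),   η = b0 + X b,

and the analogous symmetric softmax objective for K-class outcomes. ``pf`` is a
per-feature penalty factor: covariates with ``pf=0`` (age, gender in the risk
models) are never penalized and therefore never shrunk out of the model. The
intercept(s) are unpenalized.

The binomial solver is IRLS with cyclic coordinate descent on the weighted
least-squares subproblem (the glmnet algorithm), compiled with numba and
warm-started along a geometric lambda path. The multinomial solver is FISTA
(accelerated proximal gradient) with a fixed step from the spectral norm of the
design. Both are deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import softmax

_EPS = 1e-12


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance (−2 × mean log-likelihood) on the logit scale."""
    y = np.asarray(y, dtype=float)
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * np.mean(ll))


def multinomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean multinomial deviance; ``y`` integer classes, ``eta`` (n, K) liabilities."""
    from scipy.special import logsumexp

    eta = np.asarray(eta, dtype=float)
    ll = eta[np.arange(len(y)), y] - logsumexp(eta, axis=1)
    return float(-2.0 * np.mean(ll))


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    penalty_factor: np.ndarray | None = None,
    n_lambda: int = 30,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    """Geometric lambda path from the smallest lambda zeroing all penalized terms."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    Xc = X - X.mean(axis=0)
    if y.ndim == 1:
        resid = y - y.mean()
        score = np.abs(Xc.T @ resid) / n  # (p,)
    else:  # indicator matrix for multinomial
        resid = y - y.mean(axis=0)
        score = np.max(np.abs(Xc.T @ resid), axis=1) / n
    alpha_eff = max(alpha, 1e-3)
    with np.errstate(divide="ignore"):
        lam_max = np.max(np.where(pf > 0, score / (alpha_eff * np.maximum(pf, _EPS)),
                                  0.0))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


@dataclass
class LogisticFit:
    intercept: float
    coef: np.ndarray
    lambda_: float
    alpha: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coef


@njit(cache=False)
def _cd_binomial_path(X, y, lambdas, alpha, pf, tol, max_outer, max_sweeps):
    """IRLS + cyclic coordinate descent along a decreasing lambda path."""
    n, p = X.shape
    n_lam = lambdas.shape[0]
    b0s = np.zeros(n_lam)
    coefs = np.zeros((n_lam, p))

    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        # degenerate outcome: intercept-only fit is undefined; leave at +-35
        base = 35.0 if ybar >= 1.0 else -35.0
    else:
        base = np.log(ybar / (1.0 - ybar))
    b0 = base
    b = np.zeros(p)
    xsq = np.empty(p)
    for li in range(n_lam):
        lam = lambdas[li]
        for _outer in range(max_outer):
            eta = b0 + X @ b
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = prob * (1.0 - prob)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            z = eta + (y - prob) / w
            r = z - eta  # residual of working response
            wsum = w.sum()
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                xsq[j] = s / n
            old_b0 = b0
            max_coef_change = 0.0
            for _sweep in range(max_sweeps):
                delta = 0.0
                # intercept (unpenalized)
                num = 0.0
                for i in range(n):
                    num += w[i] * (r[i] + b0)
                new_b0 = num / wsum
                d0 = new_b0 - b0
                if d0 != 0.0:
                    for i in range(n):
                        r[i] -= d0
                    b0 = new_b0
                    if abs(d0) > delta:
                        delta = abs(d0)
                for j in range(p):
                    bj = b[j]
                    num = 0.0
                    for i in range(n):
                        num += w[i] * X[i, j] * r[i]
                    num = num / n + xsq[j] * bj
                    th = lam * alpha * pf[j]
                    if num > th:
                        new_bj = (num - th) / (xsq[j] + lam * (1.0 - alpha) * pf[j])
                    elif num < -th:
                        new_bj = (num + th) / (xsq[j] + lam * (1.0 - alpha) * pf[j])
                    else:
                        new_bj = 0.0
                    dj = new_bj - bj
                    if dj != 0.0:
                        for i in range(n):
                            r[i] -= dj * X[i, j]
                        b[j] = new_bj
                        if abs(dj) > delta:
                            delta = abs(dj)
                if delta > max_coef_change:
                    max_coef_change = delta
                if delta < tol:
                    break
            # outer convergence: quadratic approximation stabilized
            if max_coef_change < tol and abs(b0 - old_b0) < tol:
                break
        b0s[li] = b0
        coefs[li] = b
    return b0s, coefs


def logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    penalty_factor: np.ndarray | None = None,
    tol: float = 1e-7,
    max_outer: int = 30,
    max_sweeps: int = 200,
) -> list[LogisticFit]:
    """Fit a decreasing lambda path with warm starts; returns one fit per lambda."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    # center columns for conditioning; the free intercept absorbs the shift
    mu = X.mean(axis=0)
    Xc = np.ascontiguousarray(X - mu)
    b0s, coefs = _cd_binomial_path(
        Xc, y, lambdas, float(alpha), np.asarray(pf, np.float64),
        tol, max_outer, max_sweeps,
    )
    return [
        LogisticFit(float(b0s[i] - mu @ coefs[i]), coefs[i].copy(),
                    float(lambdas[i]), float(alpha))
        for i in range(len(lambdas))
    ]


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    alpha: float,
    penalty_factor: np.ndarray | None = None,
    tol: float = 1e-7,
) -> LogisticFit:
    """Fit one elastic-net logistic regression."""
    return logistic_path(X, y, np.array([lambda_]), alpha, penalty_factor, tol=tol)[0]


@dataclass
class MultinomialFit:
    intercepts: np.ndarray  # (K,)
    coef: np.ndarray  # (p, K)
    classes: np.ndarray
    lambda_: float
    alpha: float

    def liabilities(self, X: np.ndarray) -> np.ndarray:
        return self.intercepts + np.asarray(X, float) @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.liabilities(X), axis=1)


@njit(cache=False)
def _cd_multinomial_path(X, Y, lambdas, alpha, pf, tol, max_cycles, max_sweeps):
    """Partial-Newton coordinate descent over classes along a lambda path."""
    n, p = X.shape
    K = Y.shape[1]
    n_lam = lambdas.shape[0]
    b0s = np.zeros((n_lam, K))
    coefs = np.zeros((n_lam, p, K))

    B0 = np.zeros(K)
    B = np.zeros((p, K))
    Eta = np.zeros((n, K))
    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    xsq = np.empty(p)
    for li in range(n_lam):
        lam = lambdas[li]
        for _cycle in range(max_cycles):
            cycle_change = 0.0
            for k in range(K):
                # quadratic approximation in class k with the others fixed
                for i in range(n):
                    m = Eta[i, 0]
                    for c in range(1, K):
                        if Eta[i, c] > m:
                            m = Eta[i, c]
                    denom = 0.0
                    for c in range(K):
                        denom += np.exp(Eta[i, c] - m)
                    pik = np.exp(Eta[i, k] - m) / denom
                    wi = pik * (1.0 - pik)
                    if wi < 1e-5:
                        wi = 1e-5
                    w[i] = wi
                    z[i] = Eta[i, k] + (Y[i, k] - pik) / wi
                    r[i] = z[i] - Eta[i, k]
                wsum = w.sum()
                for j in range(p):
                    s = 0.0
                    for i in range(n):
                        s += w[i] * X[i, j] * X[i, j]
                    xsq[j] = s / n
                b0 = B0[k]
                for _sweep in range(max_sweeps):
                    delta = 0.0
                    num = 0.0
                    for i in range(n):
                        num += w[i] * (r[i] + b0)
                    new_b0 = num / wsum
                    d0 = new_b0 - b0
                    if d0 != 0.0:
                        for i in range(n):
                            r[i] -= d0
                        b0 = new_b0
                        if abs(d0) > delta:
                            delta = abs(d0)
                    for j in range(p):
                        bj = B[j, k]
                        num = 0.0
                        for i in range(n):
                            num += w[i] * X[i, j] * r[i]
                        num = num / n + xsq[j] * bj
                        th = lam * alpha * pf[j]
                        if num > th:
                            new_bj = (num - th) / (xsq[j] + lam * (1.0 - alpha) * pf[j])
                        elif num < -th:
                            new_bj = (num + th) / (xsq[j] + lam * (1.0 - alpha) * pf[j])
                        else:
                            new_bj = 0.0
                        dj = new_bj - bj
                        if dj != 0.0:
                            for i in range(n):
                                r[i] -= dj * X[i, j]
                            B[j, k] = new_bj
                            if abs(dj) > delta:
                                delta = abs(dj)
                    if delta > cycle_change:
                        cycle_change = delta
                    if delta < tol:
                        break
                B0[k] = b0
                for i in range(n):
                    Eta[i, k] = z[i] - r[i]
            if cycle_change < tol:
                break
        b0s[li] = B0
        coefs[li] = B
    return b0s, coefs


def multinomial_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    penalty_factor: np.ndarray | None = None,
    tol: float = 1e-7,
    max_cycles: int = 30,
    max_sweeps: int = 200,
) -> list[MultinomialFit]:
    """Elastic-net multinomial (symmetric softmax) regression along a lambda path."""
    X = np.asarray(X, dtype=np.float64)
    classes, y_idx = np.unique(y, return_inverse=True)
    K = len(classes)
    n, p = X.shape
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    mu = X.mean(axis=0)
    Xc = np.ascontiguousarray(X - mu)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    b0s, coefs = _cd_multinomial_path(
        Xc, Y, lambdas, float(alpha), np.asarray(pf, np.float64),
        tol, max_cycles, max_sweeps,
    )
    return [
        MultinomialFit(b0s[i] - mu @ coefs[i], coefs[i].copy(), classes,
                       float(lambdas[i]), float(alpha))
        for i in range(len(lambdas))
    ]
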