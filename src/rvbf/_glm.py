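"""Small logistic-regression engine shared by the association modules.

Newton/IRLS with step-halving on the log-likelihood.  The designs fitted
here are tiny (intercept + a handful of covariates + one burden or dosage
column), so a dedicated dense solver is faster and easier to control than
going through a full GLM framework for every one of the thousands of
per-gene and per-permutation fits the pipeline performs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "fit_logistic", "score_test_components"]


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    Attributes
    ----------
    beta : coefficient vector, same order as the design columns.
    mu : fitted probabilities.
    loglik : maximized binomial log-likelihood.
    converged : True when the gradient norm dropped below tolerance.
    n_iter : Newton iterations used.
    """

    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogisticFit:
    """Fit a binary logistic regression by damped Newton iterations.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary response.
    ridge : tiny diagonal added to the information matrix for numerical
        safety on nearly collinear designs; 0 disables it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    # start the intercept at the empirical logit for faster convergence
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    if np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1 - ybar))
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol * n:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        if ridge:
            info = info + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving on the log-likelihood
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(y, eta_new)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta, ll = beta_new, eta_new, ll_new
    mu = expit(eta)
    return LogisticFit(beta=beta, mu=mu, loglik=ll, converged=converged, n_iter=it)


def score_test_components(
    G: np.ndarray, y: np.ndarray, mu: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Efficient-score numerator and variance for each column of ``G``.

    Given the null fit (``mu`` from ``X`` only), returns ``U = G'(y-mu)``
    and the efficient information ``V = diag(G'WG) - diag(G'WX (X'WX)^-1
    X'WG)`` so that ``U**2/V`` is the Rao score chi-square with 1 df per
    column.  Fully vectorized across columns.
    """
    w = mu * (1.0 - mu)
    U = G.T @ (y - mu)
    WG = G * w[:, None]
    V_full = np.einsum("ij,ij->j", G, WG)
    XtWX = (X * w[:, None]).T @ X
    A = X.T @ WG  # (p, m)
    B = np.linalg.solve(XtWX, A)
    V = V_full - np.einsum("pj,pj->j", A, B)
    return U, V
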