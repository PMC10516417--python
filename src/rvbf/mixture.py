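"""Tail probabilities of positive linear combinations of chi-square(1) variables.

This is the numerical engine behind the SKAT variance-component p-value:
the score statistic is distributed, under the null, as ``Q ~ sum_k
lambda_k * chi2_1`` where the lambdas are eigenvalues of the projected
kernel matrix.  The survival function is evaluated by Imhof's
characteristic-function inversion

    P(Q > q) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du,

with ``theta(u) = 1/2 sum arctan(lambda_k u) - q u / 2`` and ``rho(u) =
prod (1 + lambda_k^2 u^2)^(1/4)``.  When the oscillatory integral cannot
be evaluated to the requested absolute accuracy, a Liu-type four-moment
chi-square approximation is used instead and flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

__all__ = ["chisq_mixture_pvalue", "liu_pvalue"]


def _imhof_integrand(u, lam, q):
    theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
    rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
    return np.sin(theta) / (u * rho)


def liu_pvalue(eigenvalues: np.ndarray, q: float) -> float:
    """Moment-matching (Liu et al. style) chi-square approximation."""
    lam = np.asarray(eigenvalues, dtype=float)
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
        a = np.sqrt(df)
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta))


def chisq_mixture_pvalue(
    eigenvalues,
    q: float,
    atol: float = 1e-6,
    full_output: bool = False,
):
    """P(sum_k lambda_k chi2_1 > q) for non-negative eigenvalues.

    Parameters
    ----------
    eigenvalues : non-negative weights, not all zero.
    q : evaluation point, must be >= 0.
    atol : target absolute accuracy of the inversion integral.
    full_output : when True return ``(p, used_fallback)``.

    Raises
    ------
    ValueError for q < 0, negative eigenvalues, or an all-zero spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if q < 0:
        raise ValueError("q must be non-negative")
    if lam.size == 0 or np.all(lam == 0):
        raise ValueError("eigenvalue spectrum is empty or all zero")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    lam = lam[lam > 0]
    if q == 0.0:
        return (1.0, False) if full_output else 1.0

    # truncate the inversion integral where the analytic tail bounds drop
    # below the accuracy target; the envelope decays like u^-(1+k/2) and
    # the oscillation (frequency q/2) gains another factor 2/(q u)
    k = lam.size
    prod_sqrt = float(np.exp(0.5 * np.sum(np.log(lam))))
    target = atol / 4.0

    def tail_bound(u):
        env = (2.0 / k) * u ** (-k / 2.0) / (prod_sqrt * np.pi)
        osc = 2.0 / (q * np.pi) * u ** (-1.0 - k / 2.0) / prod_sqrt
        return min(env, osc)

    upper = 16.0
    while tail_bound(upper) > target and upper < 1e8:
        upper *= 2.0

    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            val, err = integrate.quad(
                _imhof_integrand,
                0.0,
                upper,
                args=(lam, q),
                epsabs=target * np.pi,
                epsrel=1e-10,
                limit=int(max(200, min(20000, 20 * upper * q / np.pi))),
            )
            p = 0.5 + val / np.pi
            if err / np.pi + tail_bound(upper) > atol or not np.isfinite(p):
                fallback = True
        except (integrate.IntegrationWarning, Exception):
            fallback = True

    if fallback:
        p = liu_pvalue(lam, q)
    # inversion of an oscillatory integral can land epsilon outside [0,1]
    p = float(min(max(p, 0.0), 1.0))
    if p == 0.0:
        p = liu_pvalue(lam, q)
        fallback = True
    if full_output:
        return p, fallback
    return p
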