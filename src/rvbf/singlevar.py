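"""Per-variant association machinery.

Provides the Rao score test used both on its own and as the source of the
within-gene p-values feeding the KS prior, Benjamini-Hochberg q-values,
and the covariate-adjusted Firth scan over rare variants with FDR-based
selection (default gate q <= 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import fit_logistic, score_test_components
from .firth import firth_logistic

__all__ = [
    "score_test_pvalue",
    "score_test_pvalues",
    "bh_qvalues",
    "storey_qvalues",
    "single_variant_scan",
    "SingleVariantResult",
]


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if X is None or (hasattr(X, "size") and np.asarray(X).size == 0):
        return ones
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(np.all(X == 1.0, axis=0)):
        return X
    return np.hstack([ones, X])


def mean_impute(G: np.ndarray) -> np.ndarray:
    """Replace missing dosages (coded negative or NaN) by the column mean."""
    G = np.asarray(G, dtype=float)
    G = np.where(G < 0, np.nan, G)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = col_mean[idx[1]]
    return G


def score_test_pvalues(
    G: np.ndarray, y: np.ndarray, X_null: np.ndarray | None = None
) -> np.ndarray:
    """Rao score-test p-values for each dosage column added to the null model.

    The null logistic model (covariates only, intercept always included) is
    fitted once; each column's score ``U = g'(y - mu)`` is referred to the
    efficient information, giving a chi-square(1) p-value.  Constant
    columns (zero score variance) get p = 1.
    """
    y = np.asarray(y, dtype=float)
    G = mean_impute(np.atleast_2d(np.asarray(G, dtype=float).T).T)
    X = _with_intercept(X_null, len(y))
    null = fit_logistic(X, y)
    U, V = score_test_components(G, y, null.mu, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 1e-12, U**2 / np.maximum(V, 1e-300), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p[V <= 1e-12] = 1.0
    return p


def score_test_pvalue(g, y, X_null=None) -> float:
    """Scalar convenience wrapper around :func:`score_test_pvalues`."""
    return float(score_test_pvalues(np.asarray(g, dtype=float)[:, None], y, X_null)[0])


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(pvalues, lambdas=None) -> np.ndarray:
    """Storey-style q-values with smoother pi0 estimation.

    pi0 is estimated on a lambda grid, smoothed with a cubic spline and
    read off at the largest lambda; q-values are BH values scaled by pi0.
    """
    from scipy.interpolate import CubicSpline

    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_grid = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    spline = CubicSpline(lambdas, pi0_grid)
    pi0 = float(np.clip(spline(lambdas[-1]), 0.0, 1.0))
    if pi0 == 0.0:
        pi0 = 1.0 / len(p)
    return np.minimum(bh_qvalues(p) * pi0, 1.0)


@dataclass
class SingleVariantResult:
    """One row of the single-variant scan table."""

    variant_id: str
    carriers_cases: int
    carriers_controls: int
    maf_cases: float
    maf_controls: float
    maf_overall: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    qvalue: float = np.nan
    selected: bool = False
    error: str | None = None


def single_variant_scan(
    G: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    variant_ids=None,
    q_threshold: float = 0.01,
    qvalue_method: str = "bh",
    ci: bool = True,
) -> pd.DataFrame:
    """Firth-regression scan over rare variants with FDR selection.

    One Firth fit per variant with the supplied covariates; p-values are
    penalized likelihood-ratio, the odds ratio and CI come from the
    genotype coefficient.  Per-variant failures are recorded in the
    ``error`` column and the scan continues.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    Xc = _with_intercept(X, n)
    Gi = mean_impute(G)
    cases = y == 1

    rows = []
    for j in range(m):
        g = Gi[:, j]
        raw = G[:, j]
        obs = (raw >= 0) & ~np.isnan(raw)
        carrier = obs & (raw > 0)
        n_case_alt = float(raw[obs & cases].sum())
        n_ctrl_alt = float(raw[obs & ~cases].sum())
        maf_case = n_case_alt / max(2 * np.sum(obs & cases), 1)
        maf_ctrl = n_ctrl_alt / max(2 * np.sum(obs & ~cases), 1)
        maf_all = (n_case_alt + n_ctrl_alt) / max(2 * obs.sum(), 1)
        res = SingleVariantResult(
            variant_id=str(variant_ids[j]),
            carriers_cases=int(np.sum(carrier & cases)),
            carriers_controls=int(np.sum(carrier & ~cases)),
            maf_cases=min(maf_case, 1 - maf_case),
            maf_controls=min(maf_ctrl, 1 - maf_ctrl),
            maf_overall=min(maf_all, 1 - maf_all),
            odds_ratio=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            pvalue=np.nan,
        )
        try:
            design = np.hstack([Xc, g[:, None]])
            fit = firth_logistic(y, design, compute_ci=ci, inference_indices=[-1])
            res.odds_ratio = float(np.exp(fit.beta[-1]))
            res.ci_low = float(np.exp(fit.ci_low[-1]))
            res.ci_high = float(np.exp(fit.ci_high[-1]))
            res.pvalue = float(fit.pvalues[-1])
        except (ValueError, np.linalg.LinAlgError) as exc:
            res.error = str(exc)
        rows.append(res)

    columns = list(SingleVariantResult.__dataclass_fields__)
    table = pd.DataFrame([r.__dict__ for r in rows], columns=columns)
    ok = table["pvalue"].notna()
    if ok.any():
        qfun = storey_qvalues if qvalue_method == "storey" else bh_qvalues
        table.loc[ok, "qvalue"] = qfun(table.loc[ok, "pvalue"].to_numpy())
        table["selected"] = table["qvalue"] <= q_threshold
    return table
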