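"""QQ diagnostics and table rendering.

QQ data pairs observed order statistics with theoretical quantiles of
the null reference (chi-square(3) for the gene statistic 2·logBF, or
Uniform(0,1) for p-values) and reports the genomic inflation factor —
the ratio of the observed to theoretical median, ≈1 for a calibrated
scan.  Table renderers emit the standard report layouts: the MAF-bin
histogram, ranked gene tables (prior P, BF P, combined P) and the
single-variant association table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .qc import MAF_BINS

__all__ = [
    "qq_data",
    "render_maf_histogram",
    "render_gene_table",
    "render_single_variant_table",
]


def qq_data(
    values,
    null_df: int = 3,
    pvalues: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(expected, observed) quantile pairs and the inflation factor.

    ``values`` are test statistics referred to chi-square(null_df), or
    p-values when ``pvalues`` is True (reference Uniform(0,1); raw
    quantile pairs are returned).  Theoretical quantiles are taken at
    (i - 0.5)/n; the inflation factor is the observed/theoretical
    median ratio.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a QQ curve")
    if not np.all(np.isfinite(v)):
        bad = np.flatnonzero(~np.isfinite(v))
        raise ValueError(f"non-finite values at positions {bad.tolist()[:10]}")
    if v.std() == 0:
        raise ValueError("degenerate (constant) input")
    n = v.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    observed = np.sort(v)
    if pvalues:
        expected = probs
        inflation = float(np.median(observed) / 0.5)
    else:
        dist = stats.chi2(null_df)
        expected = dist.ppf(probs)
        inflation = float(np.median(observed) / dist.median())
    return expected, observed, inflation


def _sci(x) -> str:
    if pd.isna(x):
        return "NA"
    return f"{x:.2E}"


def render_maf_histogram(hist: dict) -> pd.DataFrame:
    """Table-style MAF histogram over the standard bins, with proportions."""
    missing = [b for b in MAF_BINS if b not in hist]
    if missing:
        raise ValueError(f"missing MAF bins: {missing}")
    counts = [int(hist[b]) for b in MAF_BINS]
    total = sum(counts)
    return pd.DataFrame(
        {
            "MAF": list(MAF_BINS) + ["Total"],
            "n_variants": counts + [total],
            "proportion_pct": [
                round(100.0 * c / total, 2) if total else 0.0 for c in counts
            ]
            + [100.0 if total else 0.0],
        }
    )


def render_gene_table(results: pd.DataFrame) -> pd.DataFrame:
    """Ranked gene table: rank, gene, #(sites), prior P, BF P (+combined).

    Rows are ranked by the gene BF p-value ascending; numbers are
    rendered in scientific notation with 3 significant digits.
    """
    required = {"gene", "n_sites", "prior_p", "pvalue"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df = results.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(df) + 1),
            "gene": df["gene"],
            "n_sites": df["n_sites"].astype(int) if len(df) else df["n_sites"],
            "prior_P": df["prior_p"].map(_sci),
            "BF_P": df["pvalue"].map(_sci),
        }
    )
    if "p_combined" in df.columns:
        out["combined_P"] = df["p_combined"].map(_sci)
    return out


def render_single_variant_table(results: pd.DataFrame) -> pd.DataFrame:
    """Single-RV table: MAF and carriers by group, P, q, OR (95% CI)."""
    required = {
        "variant_id", "maf_overall", "carriers_cases", "carriers_controls",
        "pvalue", "qvalue", "odds_ratio", "ci_low", "ci_high",
    }
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"single-variant table missing columns: {sorted(missing)}")
    df = results.reset_index(drop=True)
    return pd.DataFrame(
        {
            "variant": df["variant_id"],
            "MAF": df["maf_overall"].map(_sci),
            "carriers_cases": df["carriers_cases"],
            "carriers_controls": df["carriers_controls"],
            "P": df["pvalue"].map(_sci),
            "q": df["qvalue"].map(_sci),
            "OR_95CI": [
                f"{o:.1f} ({lo:.1f}-{hi:.1f})" if np.isfinite(o) else "NA"
                for o, lo, hi in zip(df["odds_ratio"], df["ci_low"], df["ci_high"])
            ],
        }
    )
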