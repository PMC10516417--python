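"""Published summary statistics bundled as worked-example inputs.

Gene-level results of a lung-cancer whole-exome rare-variant analysis
(discovery: ILCCO consortium, 1042 cases / 881 controls; replication:
UK Biobank, 630 cases / 172,864 controls), as reported in its summary
tables.  These are *inputs* for the two-stage selection and Fisher
combination machinery — a ready-made example of a discovery/replication
gene screen — not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "lung_bf_ks_tables",
    "lung_bf_skat_tables",
    "lung_sex_by_status",
    "lung_maf_bin_counts",
    "GAMMA",
    "LAMBDA",
]

#: two-stage thresholds used in the published screen
GAMMA = 5e-4
LAMBDA = 0.05

# gene, chrom, n_sites, KS prior P (discovery), BF_KS P (discovery),
# KS prior P (replication), BF_KS P (replication); NA = not testable
_BF_KS = [
    ("CTSL", 9, 25, 1.32e-03, 4.87e-05, 8.43e-01, 2.75e-03),
    ("TBX4", 17, 37, 1.48e-03, 6.49e-05, 9.67e-01, 9.96e-01),
    ("RASL10B", 17, 53, 4.05e-04, 6.75e-05, 1.00e00, 9.81e-01),
    ("MUC3A", 7, 94, 1.30e-04, 7.33e-05, 5.95e-01, 6.42e-01),
    ("AMN", 14, 22, 1.68e-04, 8.08e-05, 9.07e-01, 9.71e-01),
    ("KRTAP19-4", 21, 21, 3.38e-05, 1.27e-04, 8.74e-02, 8.76e-02),
    ("KRTAP19-5", 21, 20, 3.38e-05, 1.28e-04, None, None),
    ("CPB2", 13, 25, 1.74e-03, 1.46e-04, 1.00e00, 6.71e-01),
    ("C8orf44", 8, 38, 1.11e-02, 2.17e-04, 6.74e-01, 1.82e-01),
    ("ZW10", 11, 48, 6.49e-04, 2.23e-04, 8.79e-01, 7.19e-01),
    ("INHA", 2, 68, 1.05e-04, 2.51e-04, 1.00e00, 9.04e-01),
    ("DGKB", 7, 79, 3.33e-02, 3.27e-04, 9.73e-01, 9.34e-01),
    ("FBXO6", 1, 55, 2.09e-03, 3.34e-04, 3.47e-01, 3.51e-01),
    ("PHF12", 17, 82, 2.00e-03, 3.57e-04, 1.00e00, 8.35e-01),
    ("LEMD3", 12, 46, 8.70e-04, 3.58e-04, 1.00e00, 9.98e-01),
    ("OR5AC2", 3, 70, 1.09e-04, 3.85e-04, 1.00e00, 1.00e00),
    ("FGF8", 10, 38, 9.89e-02, 4.52e-04, 9.93e-01, 7.29e-01),
]

_BF_SKAT = [
    ("VAV2", 9, 121, 3.09e-04, 1.95e-05, 6.72e-01, 5.72e-01),
    ("DENND4B", 1, 69, 2.21e-05, 4.31e-05, 9.96e-01, 6.35e-01),
    ("TBX4", 17, 37, 1.95e-03, 8.41e-05, 8.21e-01, 9.41e-01),
    ("RHBDL3", 17, 27, 9.09e-03, 1.06e-04, 1.63e-01, 2.91e-01),
    ("C8orf44", 8, 38, 5.89e-03, 1.19e-04, 9.97e-01, 2.52e-01),
    ("CCT8", 21, 46, 2.43e-02, 2.41e-04, 9.87e-01, 9.99e-01),
    ("SIGLEC11", 19, 24, 3.10e-03, 2.46e-04, 7.23e-01, 5.81e-01),
    ("APOE", 19, 25, 2.65e-04, 2.56e-04, 6.10e-03, 4.01e-03),
    ("POMK", 8, 33, 3.00e-02, 3.27e-04, 9.54e-01, 7.50e-01),
    ("DGKB", 7, 79, 4.34e-02, 4.20e-04, 3.79e-01, 5.10e-01),
    ("CTSL", 9, 25, 1.29e-02, 4.30e-04, 3.08e-03, 1.31e-05),
    ("CPB2", 13, 25, 5.55e-03, 4.42e-04, 2.98e-01, 2.65e-01),
    ("ITGB6", 2, 61, 3.23e-02, 4.93e-04, 9.83e-01, 9.40e-01),
    ("VCPIP1", 8, 39, 1.73e-02, 4.94e-04, 8.73e-01, 7.00e-01),
]


def _tables(rows):
    df = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "n_sites", "prior_p_d", "pvalue_d",
                 "prior_p_r", "pvalue_r"],
    )
    discovery = df[["gene", "pvalue_d"]].rename(columns={"pvalue_d": "pvalue"})
    replication = df[["gene", "pvalue_r"]].rename(columns={"pvalue_r": "pvalue"})
    replication["pvalue"] = replication["pvalue"].astype(float)
    return df, discovery, replication


def lung_bf_ks_tables():
    """(full, discovery, replication) gene tables of the KS-prior screen."""
    return _tables(_BF_KS)


def lung_bf_skat_tables():
    """(full, discovery, replication) gene tables of the SKAT-prior screen."""
    return _tables(_BF_SKAT)


def lung_sex_by_status() -> pd.DataFrame:
    """Replication-cohort sex-by-status counts (males/females in cases
    and controls) from the demographic table."""
    return pd.DataFrame(
        {"cases": [332, 298], "controls": [78163, 94701]},
        index=["male", "female"],
    )


def lung_maf_bin_counts() -> dict:
    """Discovery-study MAF-bin variant counts."""
    return {
        "0": 136485,
        "(0,0.01)": 1022101,
        "[0.01,0.05)": 60288,
        "[0.05,0.5]": 129789,
    }
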