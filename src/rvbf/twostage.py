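"""Two-stage discovery-replication significance control.

A gene is declared replicated when its discovery p-value Pd and
replication p-value Pr satisfy Pd <= gamma and Pr <= lambda.  The pair
(gamma, lambda) is calibrated by phenotype permutation so that the
family-wise error rate FWER = Pr(V >= 1) stays below a target alpha,
where V counts genes passing both thresholds in a fully null pair of
cohorts.  Evidence across the two stages is summarized by Fisher's
method: X = -2(ln Pd + ln Pr) ~ chi-square(4), whose survival function
has the closed form exp(-X/2) * (1 + X/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CohortData, permute_phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "TwoStageConfig",
    "ReplicationResult",
    "fisher_combine",
    "calibrate_thresholds",
    "two_stage_select",
]


@dataclass(frozen=True)
class TwoStageConfig:
    """Calibration settings.

    ``count_mode`` decides what "number of identified significant genes
    over B replicates" counts: "any_hit" (default) counts permutation
    replicates in which at least one gene passes both thresholds — the
    empirical version of Pr(V >= 1); "total_hits" counts every passing
    gene across replicates.
    """

    alpha: float = 0.05
    B: int = 100
    gamma_grid: tuple = (1e-3, 5e-4, 1e-4, 5e-5)
    lambda_grid: tuple = (0.05, 0.01)
    seed: int = 0
    count_mode: str = "any_hit"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.B < 1:
            raise ValueError("need at least one permutation replicate")
        for grid in (self.gamma_grid, self.lambda_grid):
            if len(grid) == 0 or any(not 0.0 < g < 1.0 for g in grid):
                raise ValueError("threshold grids must be non-empty with values in (0,1)")
        if self.count_mode not in ("any_hit", "total_hits"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class ReplicationResult:
    """Per-gene two-stage outcome."""

    gene: str
    p_discovery: float
    p_replication: float
    replicated: bool
    p_combined: float
    testable_in_replication: bool = True


def fisher_combine(pd_: float, pr: float) -> float:
    """Fisher's-method combination of two p-values.

    X = -2(ln pd + ln pr) referred to chi-square(4); closed form
    p = exp(-X/2) * (1 + X/2).  Inputs must lie in (0, 1].
    """
    pd_, pr = float(pd_), float(pr)
    if not (0.0 < pd_ <= 1.0 and 0.0 < pr <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * (np.log(pd_) + np.log(pr))
    return float(np.exp(-x / 2.0) * (1.0 + x / 2.0))


def _align(tables: list) -> pd.DataFrame:
    frames = []
    for i, t in enumerate(tables):
        if isinstance(t, pd.DataFrame):
            s = t.set_index("gene")["pvalue"]
        elif isinstance(t, pd.Series):
            s = t
        else:
            s = pd.Series(np.asarray(t, dtype=float))
        frames.append(s.rename(i))
    return pd.concat(frames, axis=1, join="outer")


def calibrate_thresholds(
    discovery_test,
    replication_test,
    cohorts: tuple,
    config: TwoStageConfig,
) -> tuple[float, float, pd.DataFrame]:
    """Permutation calibration of (gamma, lambda).

    ``discovery_test`` and ``replication_test`` map a cohort (with its
    phenotype permuted) to gene p-values over a shared gene universe
    (pd.Series keyed by gene, or aligned arrays).  For each of B
    replicates both phenotypes are permuted and all gene p-values
    recomputed; for each grid pair the event {>= 1 gene with Pd <= gamma
    and Pr <= lambda} is recorded.  Returns the least-stringent pair
    whose count over B replicates is <= B * alpha (ties broken toward
    larger gamma, then larger lambda) plus the full event-count grid.

    Raises RuntimeError when no grid pair is admissible, reporting the
    best achieved count.
    """
    cohort_d, cohort_r = cohorts
    pairs = sorted(
        ((g, l) for g in config.gamma_grid for l in config.lambda_grid),
        key=lambda p: (-p[0], -p[1]),
    )
    counts = {p: 0 for p in pairs}
    rng = np.random.default_rng(config.seed)
    for b in range(config.B):
        sd, sr = rng.integers(0, 2**31 - 1, size=2)
        pd_vals = discovery_test(permute_phenotype(cohort_d, int(sd)))
        pr_vals = replication_test(permute_phenotype(cohort_r, int(sr)))
        aligned = _align([pd_vals, pr_vals]).dropna()
        d = aligned[0].to_numpy()
        r = aligned[1].to_numpy()
        for g, l in pairs:
            hits = int(np.sum((d <= g) & (r <= l)))
            if config.count_mode == "any_hit":
                counts[(g, l)] += int(hits >= 1)
            else:
                counts[(g, l)] += hits
        if (b + 1) % 20 == 0:
            logger.info("calibration permutation %d/%d", b + 1, config.B)

    grid = pd.DataFrame(
        [
            {"gamma": g, "lambda": l, "count": counts[(g, l)], "B": config.B}
            for g, l in pairs
        ]
    )
    cutoff = config.B * config.alpha
    for g, l in pairs:
        if counts[(g, l)] <= cutoff:
            return g, l, grid
    best = min(counts.values())
    raise RuntimeError(
        f"no (gamma, lambda) grid pair admissible at alpha={config.alpha}: "
        f"best achieved count {best} > {cutoff}"
    )


def two_stage_select(
    discovery_table,
    replication_table,
    gamma: float,
    lam: float,
) -> pd.DataFrame:
    """Select and combine genes across the two stages.

    Genes with Pd <= gamma form the replication set; those additionally
    with Pr <= lambda are flagged replicated.  Fisher-combined p-values
    are computed for every gene in the replication set; genes untestable
    in replication carry NA and ``testable_in_replication = False``.
    """
    if not (0.0 < gamma < 1.0 and 0.0 <= lam < 1.0):
        raise ValueError("thresholds must lie in (0, 1) (lambda may be 0)")
    aligned = _align([discovery_table, replication_table])
    rows = []
    for gene, (p_d, p_r) in aligned.iterrows():
        if not np.isfinite(p_d) or p_d > gamma:
            continue
        testable = np.isfinite(p_r)
        rows.append(
            ReplicationResult(
                gene=str(gene),
                p_discovery=float(p_d),
                p_replication=float(p_r) if testable else np.nan,
                replicated=bool(testable and p_r <= lam),
                p_combined=fisher_combine(p_d, p_r) if testable else np.nan,
                testable_in_replication=testable,
            )
        )
    out = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=[
            "gene", "p_discovery", "p_replication", "replicated",
            "p_combined", "testable_in_replication",
        ],
    )
    return out.sort_values("p_discovery", kind="mergesort").reset_index(drop=True)
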