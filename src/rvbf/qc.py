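"""Exome QC: genotype masking, site filter cascades, sample QC, gene regions.

Two preset cascades are provided, matching the discovery ("ilcco") and
replication ("ukbiobank") pipelines:

ilcco
    QUAL<100 or mean GQ<50 excluded; singletons whose minor allele has
    GQ<50 or DP<20 excluded; non-biallelic and sex-chromosome variants
    excluded; Hardy-Weinberg exact p < 1e-7 in controls excluded;
    genotypes masked when GQ<30 or DP<10; MAF>1% excluded.
ukbiobank
    non-biallelic or QUAL<10 excluded; mean GQ<30 excluded; singletons
    with DP<20 or GQ<40 excluded; genotypes masked when DP<10 or GQ<20;
    missing rate >10% excluded; MAF>1% excluded.

All thresholds are strict inequalities; boundary values survive.
Genotype masking is applied BEFORE missing-rate, HWE and MAF
computation; the mean-GQ rule uses pre-mask GQ values.  Within the
cascade, rules are applied in a fixed order (site quality → structure →
singleton → HWE → missing rate → MAF) and each failing site is
attributed to its first failing rule, so the per-rule exclusion counts
partition the excluded sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "GeneRegion",
    "RULE_ORDER",
    "mask_genotypes",
    "compute_maf",
    "site_mafs",
    "hwe_exact_test",
    "tstv_ratio",
    "apply_site_filters",
    "sample_qc",
    "build_gene_regions",
    "assign_variants_to_genes",
    "MAF_BINS",
]

RULE_ORDER = (
    "qual",
    "mean_gq",
    "not_biallelic",
    "sex_chromosome",
    "singleton_quality",
    "hwe",
    "missing_rate",
    "maf",
)

#: MAF histogram bin edges/labels: 0, (0,0.01), [0.01,0.05), [0.05,0.5]
MAF_BINS = ("0", "(0,0.01)", "[0.01,0.05)", "[0.05,0.5]")

_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of one QC cascade.  ``None`` disables a rule."""

    name: str = "custom"
    min_qual: float | None = None
    min_mean_gq: float | None = None
    singleton_min_gq: float | None = None
    singleton_min_dp: float | None = None
    biallelic_only: bool = True
    exclude_sex_chromosomes: bool = False
    hwe_floor: float | None = None
    max_missing_rate: float | None = None
    max_maf: float | None = 0.01
    mask_min_gq: float | None = None
    mask_min_dp: float | None = None
    sample_max_missing: float = 0.10
    het_sd_multiplier: float = 6.0

    @classmethod
    def preset(cls, name: str) -> "QCConfig":
        if name == "ilcco":
            return cls(
                name="ilcco", min_qual=100.0, min_mean_gq=50.0,
                singleton_min_gq=50.0, singleton_min_dp=20.0,
                biallelic_only=True, exclude_sex_chromosomes=True,
                hwe_floor=1e-7, max_missing_rate=None, max_maf=0.01,
                mask_min_gq=30.0, mask_min_dp=10.0,
            )
        if name == "ukbiobank":
            return cls(
                name="ukbiobank", min_qual=10.0, min_mean_gq=30.0,
                singleton_min_gq=40.0, singleton_min_dp=20.0,
                biallelic_only=True, exclude_sex_chromosomes=False,
                hwe_floor=None, max_missing_rate=0.10, max_maf=0.01,
                mask_min_gq=20.0, mask_min_dp=10.0,
            )
        raise ValueError(f"unknown QC preset {name!r}")


@dataclass
class QCReport:
    """Accounting of one cascade run.

    ``exclusions`` maps each rule to the number of sites whose FIRST
    failing rule it was, so sites_in = sites_out + sum(exclusions).
    """

    sites_in: int = 0
    sites_out: int = 0
    exclusions: dict = field(default_factory=dict)
    genotypes_masked: int = 0
    samples_removed: list = field(default_factory=list)
    tstv_before: float | None = None
    tstv_after: float | None = None
    maf_hist_pre_maf_rule: dict = field(default_factory=dict)
    maf_hist_pass: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sites_in": self.sites_in,
            "sites_out": self.sites_out,
            "exclusions": dict(self.exclusions),
            "genotypes_masked": self.genotypes_masked,
            "samples_removed": list(self.samples_removed),
            "tstv_before": self.tstv_before,
            "tstv_after": self.tstv_after,
            "maf_hist_pre_maf_rule": dict(self.maf_hist_pre_maf_rule),
            "maf_hist_pass": dict(self.maf_hist_pass),
        }


# --------------------------------------------------------------------------
# elementary computations
# --------------------------------------------------------------------------

def compute_maf(dosages) -> float:
    """Folded minor-allele frequency over non-missing genotypes.

    Dosages count alt alleles in {0,1,2}; negative or NaN means missing.
    """
    d = np.asarray(dosages, dtype=float)
    obs = (d >= 0) & ~np.isnan(d)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all genotypes missing: MAF undefined")
    f_alt = d[obs].sum() / (2.0 * n)
    return float(min(f_alt, 1.0 - f_alt))


def site_mafs(genotypes: np.ndarray) -> np.ndarray:
    """Vectorized folded MAF per column; columns with no data give NaN."""
    G = np.asarray(genotypes, dtype=float)
    obs = G >= 0
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(obs, G, 0.0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, np.minimum(f_alt, 1.0 - f_alt), np.nan)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed minor-allele count and sums, over all
    compatible heterozygote counts, the probabilities no greater than
    that of the observed configuration.  Monomorphic input gives p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one individual")
    m = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor-allele count
    if m == 0:
        return 1.0
    hets = np.arange(m % 2, min(m, 2 * n - m) + 1, 2)
    hom_minor = (m - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


def tstv_ratio(ref, alt) -> tuple[float, bool]:
    """Transition/transversion ratio over SNVs; returns (ratio, flagged).

    ``flagged`` is True when there are no transversions (ratio +inf).
    Raises on zero SNVs.
    """
    ts = tv = 0
    for r, a in zip(ref, alt):
        r, a = str(r).upper(), str(a).upper()
        if r in _BASES and a in _BASES and r != a:
            if (r, a) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if ts + tv == 0:
        raise ValueError("no SNVs: Ts/Tv undefined")
    if tv == 0:
        logger.warning("no transversions among %d SNVs: Ts/Tv is +inf", ts)
        return float("inf"), True
    return ts / tv, False


# --------------------------------------------------------------------------
# cascade
# --------------------------------------------------------------------------

def mask_genotypes(
    genotypes: np.ndarray,
    gq: np.ndarray | None,
    dp: np.ndarray | None,
    qc: QCConfig,
) -> tuple[np.ndarray, int]:
    """Set low-confidence genotypes missing; returns (masked matrix, count).

    A genotype fails the mask when GQ < mask_min_gq or DP < mask_min_dp;
    an absent GQ/DP value (negative) is treated as failing — conservative.
    Masking happens before missing-rate and MAF computation.
    """
    G = np.asarray(genotypes)
    if qc.mask_min_gq is None and qc.mask_min_dp is None:
        return G.copy(), 0
    bad = np.zeros(G.shape, dtype=bool)
    if qc.mask_min_gq is not None:
        bad |= (gq < qc.mask_min_gq) if gq is not None else True
    if qc.mask_min_dp is not None:
        bad |= (dp < qc.mask_min_dp) if dp is not None else True
    bad &= G >= 0
    out = G.copy()
    out[bad] = -1
    return out, int(bad.sum())


def _maf_bin(maf: float) -> str:
    if maf == 0:
        return MAF_BINS[0]
    if maf < 0.01:
        return MAF_BINS[1]
    if maf < 0.05:
        return MAF_BINS[2]
    return MAF_BINS[3]


def apply_site_filters(
    genotypes: np.ndarray,
    qc: QCConfig,
    control_mask: np.ndarray | None = None,
    qual: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    dp: np.ndarray | None = None,
    chrom=None,
    ref=None,
    alt=None,
    n_alt_alleles: np.ndarray | None = None,
) -> tuple[np.ndarray, QCReport]:
    """Run the site-filter cascade; returns (passing column indices, report).

    ``genotypes`` must already be genotype-masked (see
    :func:`mask_genotypes`); ``gq`` carries the pre-mask values used by
    the mean-GQ and singleton rules.  ``n_alt_alleles`` (per-site count
    of ALT alleles beyond the first) marks non-biallelic records kept in
    bi-allelic storage.  ``control_mask`` selects the control rows for
    the HWE rule; without it the HWE rule uses all samples.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    report = QCReport(sites_in=m, exclusions={r: 0 for r in RULE_ORDER})
    if m == 0:
        report.sites_out = 0
        return np.array([], dtype=int), report

    fail_rule = np.array([""] * m, dtype=object)

    def mark(mask, rule):
        mask = np.asarray(mask, dtype=bool) & (fail_rule == "")
        fail_rule[mask] = rule

    # 1. site quality
    if qc.min_qual is not None and qual is not None:
        mark(np.asarray(qual) < qc.min_qual, "qual")
    if qc.min_mean_gq is not None and gq is not None:
        with np.errstate(invalid="ignore"):
            mean_gq = np.where(gq >= 0, gq, np.nan).mean(axis=0)
        mean_gq = np.nan_to_num(mean_gq, nan=-1.0)
        mark(mean_gq < qc.min_mean_gq, "mean_gq")

    # 2. structure
    if qc.biallelic_only and n_alt_alleles is not None:
        mark(np.asarray(n_alt_alleles) > 1, "not_biallelic")
    if qc.exclude_sex_chromosomes and chrom is not None:
        mark(np.isin(np.asarray(chrom, dtype=object), list(_SEX_CHROMS)),
             "sex_chromosome")

    obs = G >= 0
    n_obs = obs.sum(axis=0)
    alt_count = np.where(obs, G, 0).sum(axis=0)
    minor_count = np.minimum(alt_count, 2 * n_obs - alt_count)

    # 3. singleton quality
    if qc.singleton_min_gq is not None or qc.singleton_min_dp is not None:
        singleton = minor_count == 1
        for j in np.flatnonzero(singleton & (fail_rule == "")):
            minor_is_alt = alt_count[j] <= n_obs[j]
            col = G[:, j]
            carriers = np.flatnonzero(
                obs[:, j] & ((col > 0) if minor_is_alt else (col < 2))
            )
            if carriers.size == 0:
                continue
            i = carriers[0]
            bad = False
            if qc.singleton_min_gq is not None and gq is not None:
                bad |= gq[i, j] < qc.singleton_min_gq
            if qc.singleton_min_dp is not None and dp is not None:
                bad |= dp[i, j] < qc.singleton_min_dp
            if bad:
                fail_rule[j] = "singleton_quality"

    # 4. HWE in controls
    if qc.hwe_floor is not None:
        rows = np.flatnonzero(control_mask) if control_mask is not None else \
            np.arange(n)
        Gc = G[rows]
        for j in np.flatnonzero(fail_rule == ""):
            col = Gc[:, j]
            col = col[col >= 0]
            if col.size == 0:
                continue
            counts = np.bincount(col, minlength=3)
            if hwe_exact_test(counts[0], counts[1], counts[2]) < qc.hwe_floor:
                fail_rule[j] = "hwe"

    # 5. missing rate
    if qc.max_missing_rate is not None:
        miss = 1.0 - n_obs / n
        mark(miss > qc.max_missing_rate, "missing_rate")

    # pre-MAF-rule histogram (sites surviving every other rule)
    mafs = site_mafs(G)
    pre = np.flatnonzero(fail_rule == "")
    hist = {b: 0 for b in MAF_BINS}
    for j in pre:
        if np.isfinite(mafs[j]):
            hist[_maf_bin(mafs[j])] += 1
    report.maf_hist_pre_maf_rule = hist

    # 6. MAF
    if qc.max_maf is not None:
        mark(mafs > qc.max_maf, "maf")

    passing = np.flatnonzero(fail_rule == "")
    for rule in RULE_ORDER:
        report.exclusions[rule] = int(np.sum(fail_rule == rule))
    report.sites_out = int(passing.size)
    hist_pass = {b: 0 for b in MAF_BINS}
    for j in passing:
        if np.isfinite(mafs[j]):
            hist_pass[_maf_bin(mafs[j])] += 1
    report.maf_hist_pass = hist_pass

    if ref is not None and alt is not None and m > 0:
        try:
            report.tstv_before = tstv_ratio(ref, alt)[0]
            if passing.size:
                report.tstv_after = tstv_ratio(
                    np.asarray(ref, dtype=object)[passing],
                    np.asarray(alt, dtype=object)[passing],
                )[0]
        except ValueError:
            pass
    return passing, report


def sample_qc(
    genotypes: np.ndarray,
    sample_ids=None,
    max_missing: float = 0.10,
    het_sd_multiplier: float = 6.0,
) -> tuple[np.ndarray, list]:
    """Drop samples with high genotype missingness or outlying low
    heterozygosity.

    Heterozygosity = fraction of non-missing genotypes that are
    heterozygous; samples more than ``het_sd_multiplier`` sample standard
    deviations (n-1 denominator) BELOW the mean are dropped.  A zero SD
    (all samples identical) yields no heterozygosity outliers.  Fails if
    fewer than 2 samples survive.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    if sample_ids is None:
        sample_ids = list(range(n))
    obs = G >= 0
    miss_rate = 1.0 - obs.sum(axis=1) / m
    removals = [
        (sample_ids[i], "missing_rate") for i in np.flatnonzero(miss_rate > max_missing)
    ]
    keep = miss_rate <= max_missing

    with np.errstate(invalid="ignore"):
        het = np.where(obs, G == 1, False).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    het_kept = het[keep]
    sd = het_kept.std(ddof=1) if keep.sum() > 1 else 0.0
    if sd > 0:
        floor = het_kept.mean() - het_sd_multiplier * sd
        low = keep & (het < floor)
        removals += [(sample_ids[i], "low_heterozygosity") for i in np.flatnonzero(low)]
        keep &= ~low
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size < 2:
        raise ValueError("fewer than 2 samples remain after sample QC")
    return kept_idx, removals


# --------------------------------------------------------------------------
# gene regions
# --------------------------------------------------------------------------

@dataclass
class GeneRegion:
    """A gene's analysis interval: annotated span ± flank, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int
    members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_sites(self) -> int:
        return int(self.members.size)


def build_gene_regions(annotations: pd.DataFrame, flank: int = 1000) -> list:
    """Flank annotated gene spans (default ±1000 bp, floored at position 1).

    Malformed rows (missing fields, non-numeric or inverted coordinates)
    are skipped with a logged count.
    """
    regions, skipped = [], 0
    for row in annotations.itertuples():
        try:
            start, end = int(row.start), int(row.end)
            if start < 1 or end < start:
                raise ValueError
            regions.append(
                GeneRegion(
                    gene=str(row.gene),
                    chrom=str(row.chrom),
                    start=max(1, start - flank),
                    end=end + flank,
                )
            )
        except (ValueError, TypeError, AttributeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed annotation rows", skipped)
    return regions


def assign_variants_to_genes(
    chrom,
    pos,
    regions: list,
    min_sites: int = 20,
) -> dict:
    """Map analyzable genes to their member variant indices.

    Containment is inclusive on both interval ends; a variant may belong
    to several overlapping genes.  Genes with fewer than ``min_sites``
    member variants are excluded from the returned map (and logged).
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=int)
    gene_map = {}
    for region in regions:
        members = np.flatnonzero(
            (chrom == region.chrom) & (pos >= region.start) & (pos <= region.end)
        )
        region.members = members
        if members.size >= min_sites:
            gene_map[region.gene] = members
        else:
            logger.info(
                "gene %s excluded: %d < %d sites", region.gene, members.size, min_sites
            )
    return gene_map
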