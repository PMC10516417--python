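"""Synthetic case-control exome cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: bi-allelic sites with a rare-dominated MAF spectrum, Hardy-
Weinberg genotypes, a logistic disease model with covariate effects
(age, sex, smoking, principal components) and optional causal genes,
retrospective case-control sampling, and VCF-style quality fields (site
QUAL, per-genotype GQ/DP) with configurable corruption so the QC rules
have something to reject.

Design notes
------------
* Retrospective sampling: a super-population is drawn, disease status is
  assigned by the logistic model, and individuals are kept until the
  requested case and control quotas are filled.  When a quota cannot be
  met within the population cap, generation fails loudly naming the cap.
* Smoking is generated with a direct effect on disease (strongly
  imbalanced between cases and controls), so covariate-adjusted and
  unadjusted analyses differ measurably.
* One master seed fans out into named substreams (site frequencies,
  population, quality fields) so each stage is independently
  reproducible; identical config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MafSpectrum",
    "CausalGene",
    "CovariateModel",
    "QualityModel",
    "SimulationConfig",
    "CohortData",
    "simulate_cohort",
    "inject_quality_fields",
    "write_cohort",
    "read_cohort",
    "permute_phenotype",
]

#: MAF-bin proportions of the exome spectrum the generator targets by
#: default: monomorphic, (0, 0.01), [0.01, 0.05), [0.05, 0.5).
DEFAULT_BIN_WEIGHTS = (0.1012, 0.7579, 0.0447, 0.0962)


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture distribution over per-site minor-allele frequencies.

    A site first draws a bin (monomorphic / rare / low-frequency /
    common) with the given weights, then a frequency log-uniformly within
    the bin's interior.  Interior ranges sit away from the bin edges so
    that the *observed* sample MAF lands in the intended bin with high
    probability at realistic cohort sizes.
    """

    bin_weights: tuple = DEFAULT_BIN_WEIGHTS
    rare_range: tuple = (5e-4, 8e-3)
    lowfreq_range: tuple = (1.2e-2, 4.5e-2)
    common_range: tuple = (5.5e-2, 4.5e-1)

    @classmethod
    def rare_only(cls, rare_range=(5e-4, 8e-3)) -> "MafSpectrum":
        """Spectrum concentrated entirely in the rare bin — the post-QC
        world the gene tests operate in."""
        return cls(bin_weights=(0.0, 1.0, 0.0, 0.0), rare_range=rare_range)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        w = np.asarray(self.bin_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("bin weights must be non-negative and sum > 0")
        w = w / w.sum()
        bins = rng.choice(4, size=size, p=w)
        f = np.zeros(size)
        for b, (lo, hi) in zip(
            (1, 2, 3), (self.rare_range, self.lowfreq_range, self.common_range)
        ):
            mask = bins == b
            if mask.any():
                f[mask] = np.exp(
                    rng.uniform(np.log(lo), np.log(hi), size=int(mask.sum()))
                )
        return f


@dataclass(frozen=True)
class CausalGene:
    """Causal architecture of one gene.

    ``architecture`` is "sparse" (a fraction of the gene's sites carry a
    large per-allele log-odds-ratio — the few-large-effects regime the KS
    prior targets) or "uniform" (every site carries the same, typically
    small, shift — the regime SKAT targets).
    """

    gene_index: int
    architecture: str = "sparse"
    log_or: float = np.log(2.0)
    fraction_causal: float = 0.2

    def __post_init__(self):
        if self.architecture not in ("sparse", "uniform"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not np.isfinite(self.log_or):
            raise ValueError("log odds ratio must be finite")


@dataclass(frozen=True)
class CovariateModel:
    """Generating distributions and disease-model effects of covariates.

    Ages in years; smoking is a 3-level never/former/current factor with
    a derived ever/never binary; effects are log-odds per unit.
    """

    age_mean: float = 60.0
    age_sd: float = 10.0
    p_male: float = 0.5
    smoking_probs: tuple = (0.35, 0.40, 0.25)  # never, former, current
    n_pcs: int = 5
    beta_age: float = 0.02  # per year, centered at age_mean
    beta_sex: float = 0.2
    beta_former: float = 0.9
    beta_current: float = 1.6
    beta_pcs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class QualityModel:
    """Distributions for QUAL/GQ/DP plus engineered-violation rates.

    Baseline draws comfortably clear every threshold of the target
    preset; ``corruption`` maps rule names to the fraction of sites (or
    genotypes, for "genotype_mask") engineered to violate that rule:
    "site_qual", "site_mean_gq", "singleton", "genotype_mask".
    """

    qual_mean: float = 1000.0
    qual_sd: float = 200.0
    gq_mean: float = 80.0
    gq_sd: float = 10.0
    dp_mean: float = 50.0
    preset: str = "ilcco"
    corruption: dict = field(default_factory=dict)

    def __post_init__(self):
        for rule, rate in self.corruption.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"corruption rate for {rule!r} outside [0, 1]")


#: thresholds the corruption engineering targets, by preset
_PRESET_THRESHOLDS = {
    "ilcco": dict(qual=100.0, mean_gq=50.0, singleton_gq=50, singleton_dp=20,
                  mask_gq=30, mask_dp=10),
    "ukbiobank": dict(qual=10.0, mean_gq=30.0, singleton_gq=40, singleton_dp=20,
                      mask_gq=20, mask_dp=10),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic cohort."""

    n_cases: int = 1000
    n_controls: int = 1000
    n_genes: int = 10
    sites_per_gene: int | tuple = 25
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum.rare_only)
    causal_genes: tuple = ()
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    prevalence_intercept: float = -2.0
    quality_model: QualityModel | None = field(default_factory=QualityModel)
    seed: int = 0
    population_cap: int | None = None  # default: 200 * (n_cases + n_controls)

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        spg = self.sites_per_gene
        if (spg if isinstance(spg, int) else min(spg)) < 1:
            raise ValueError("sites_per_gene must be >= 1")
        for cg in self.causal_genes:
            if not 0 <= cg.gene_index < self.n_genes:
                raise ValueError(
                    f"causal gene index {cg.gene_index} out of range [0, {self.n_genes})"
                )

    @property
    def cap(self) -> int:
        return self.population_cap or 200 * (self.n_cases + self.n_controls)


@dataclass
class CohortData:
    """A case-control cohort with genotypes, covariates and quality fields.

    Dosages are minor... alt-allele counts in {0, 1, 2} with -1 for
    missing; covariate rows align 1:1 with genotype rows.
    """

    sample_ids: list
    phenotype: np.ndarray  # 1 = case
    age: np.ndarray
    sex: np.ndarray  # 1 = male
    smoking: np.ndarray  # 0 never / 1 former / 2 current
    pcs: np.ndarray  # (n, k)
    genotypes: np.ndarray  # (n, m) int8, -1 missing
    variants: pd.DataFrame  # chrom, pos, ref, alt, gene, id
    gene_table: pd.DataFrame  # gene, chrom, start, end (1-based inclusive)
    qual: np.ndarray | None = None  # (m,)
    gq: np.ndarray | None = None  # (n, m)
    dp: np.ndarray | None = None  # (n, m)
    quality_ledger: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def smoking_ever(self) -> np.ndarray:
        return (self.smoking > 0).astype(np.int8)

    def covariate_matrix(self) -> np.ndarray:
        """Standard adjustment set: age, sex, smoking ever/never, PCs."""
        return np.column_stack(
            [self.age, self.sex, self.smoking_ever, self.pcs]
        ).astype(float)

    def covariates(self) -> pd.DataFrame:
        cols = {"age": self.age, "sex": self.sex, "smoking": self.smoking,
                "smoking_ever": self.smoking_ever}
        for k in range(self.pcs.shape[1]):
            cols[f"PC{k + 1}"] = self.pcs[:, k]
        return pd.DataFrame(cols, index=self.sample_ids)

    def gene_map(self) -> dict:
        """gene id -> column indices into the genotype matrix."""
        return {
            g: idx.to_numpy()
            for g, idx in self.variants.groupby("gene", sort=False).groups.items()
        }


def _substreams(seed: int) -> dict:
    """Named, order-stable RNG substreams derived from the master seed."""
    names = ("frequencies", "population", "quality", "layout")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Assign genes to autosomes and sites to positions within each span."""
    spg = config.sites_per_gene
    n_sites = np.full(config.n_genes, spg, dtype=int) if isinstance(spg, int) else \
        rng.integers(spg[0], spg[1] + 1, size=config.n_genes)
    span = 50_000
    gap = 10_000
    chroms, starts, ends, genes = [], [], [], []
    pos_all, gene_of_site = [], []
    per_chrom_offset = {}
    for g in range(config.n_genes):
        chrom = str(g % 22 + 1)
        off = per_chrom_offset.get(chrom, 0)
        start, end = off + gap + 1, off + gap + span
        per_chrom_offset[chrom] = end
        genes.append(f"G{g:04d}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=n_sites[g],
                                 replace=False))
        pos_all.append(pos)
        gene_of_site.extend([f"G{g:04d}"] * n_sites[g])
    gene_table = pd.DataFrame(
        {"gene": genes, "chrom": chroms, "start": starts, "end": ends}
    )
    bases = np.array(["A", "C", "G", "T"])
    m = sum(len(p) for p in pos_all)
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])
    variants = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, n_sites),
            "pos": np.concatenate(pos_all),
            "ref": ref,
            "alt": alt,
            "gene": gene_of_site,
        }
    )
    variants["id"] = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(variants.chrom, variants.pos, variants.ref, variants.alt)
    ]
    return gene_table, variants


def _hwe_genotypes(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """Binomial(2, f) dosages as the sum of two Bernoulli allele draws,
    chunked over variants to bound memory."""
    m = freqs.size
    out = np.empty((n, m), dtype=np.int8)
    f32 = freqs.astype(np.float32)
    chunk = max(1, int(4e7) // max(n, 1))
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        f = f32[None, j0:j1]
        block = (rng.random((n, j1 - j0), dtype=np.float32) < f).astype(np.int8)
        block += rng.random((n, j1 - j0), dtype=np.float32) < f
        out[:, j0:j1] = block
    return out


def _draw_covariates(cm: CovariateModel, rng, size):
    age = rng.normal(cm.age_mean, cm.age_sd, size)
    sex = (rng.random(size) < cm.p_male).astype(np.int8)
    smoking = rng.choice(3, size=size, p=np.asarray(cm.smoking_probs) /
                         np.sum(cm.smoking_probs)).astype(np.int8)
    pcs = rng.normal(0.0, 1.0, size=(size, cm.n_pcs))
    return age, sex, smoking, pcs


def _covariate_logit(cm: CovariateModel, age, sex, smoking, pcs):
    eta = cm.beta_age * (age - cm.age_mean) + cm.beta_sex * sex
    eta = eta + np.where(smoking == 1, cm.beta_former, 0.0)
    eta = eta + np.where(smoking == 2, cm.beta_current, 0.0)
    beta_pcs = np.asarray(cm.beta_pcs[: pcs.shape[1]], dtype=float)
    return eta + pcs @ beta_pcs


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Draw a case-control cohort under the configured disease model.

    Raises RuntimeError when the case or control quota cannot be filled
    within the population cap (the message names the cap).
    """
    rngs = _substreams(config.seed)
    gene_table, variants = _gene_layout(config, rngs["layout"])
    m = len(variants)
    freqs = config.maf_spectrum.sample(rngs["frequencies"], m)

    # per-variant log-odds-ratios from the causal architecture
    beta_v = np.zeros(m)
    gene_codes = variants["gene"].to_numpy()
    for cg in config.causal_genes:
        gid = f"G{cg.gene_index:04d}"
        cols = np.flatnonzero(gene_codes == gid)
        if cg.architecture == "uniform":
            beta_v[cols] = cg.log_or
        else:
            k = max(1, int(round(cg.fraction_causal * len(cols))))
            chosen = rngs["layout"].choice(cols, size=k, replace=False)
            beta_v[chosen] = cg.log_or

    causal_cols = np.flatnonzero(beta_v != 0.0)
    rng = rngs["population"]
    cm = config.covariate_model

    need_cases, need_controls = config.n_cases, config.n_controls
    acc = {k: [] for k in ("age", "sex", "smoking", "pcs", "geno_causal", "y")}
    drawn = 0
    batch = max(1024, min(8192, 4 * (need_cases + need_controls)))
    while need_cases > 0 or need_controls > 0:
        if drawn >= config.cap:
            raise RuntimeError(
                f"population cap of {config.cap} individuals exceeded with "
                f"{need_cases} cases and {need_controls} controls still needed"
            )
        b = min(batch, config.cap - drawn)
        drawn += b
        age, sex, smoking, pcs = _draw_covariates(cm, rng, b)
        eta = config.prevalence_intercept + _covariate_logit(cm, age, sex, smoking, pcs)
        if causal_cols.size:
            gc = rng.binomial(2, freqs[causal_cols][None, :], size=(b, causal_cols.size))
            eta = eta + gc @ beta_v[causal_cols]
        else:
            gc = np.zeros((b, 0), dtype=np.int64)
        y = (rng.random(b) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
        take = np.zeros(b, dtype=bool)
        case_idx = np.flatnonzero(y == 1)[:need_cases]
        ctrl_idx = np.flatnonzero(y == 0)[:need_controls]
        take[case_idx] = True
        take[ctrl_idx] = True
        need_cases -= len(case_idx)
        need_controls -= len(ctrl_idx)
        acc["age"].append(age[take])
        acc["sex"].append(sex[take])
        acc["smoking"].append(smoking[take])
        acc["pcs"].append(pcs[take])
        acc["geno_causal"].append(gc[take])
        acc["y"].append(y[take])

    age = np.concatenate(acc["age"])
    sex = np.concatenate(acc["sex"])
    smoking = np.concatenate(acc["smoking"])
    pcs = np.vstack(acc["pcs"])
    y = np.concatenate(acc["y"])
    gc = np.vstack(acc["geno_causal"])
    n = len(y)

    # non-causal genotypes are independent of the phenotype: draw them
    # only for the retained individuals (exact under retrospective sampling)
    geno = np.empty((n, m), dtype=np.int8)
    noncausal = np.setdiff1d(np.arange(m), causal_cols)
    if noncausal.size:
        geno[:, noncausal] = _hwe_genotypes(rng, freqs[noncausal], n)
    if causal_cols.size:
        geno[:, causal_cols] = gc.astype(np.int8)

    sample_ids = [f"S{i:06d}" for i in range(n)]
    cohort = CohortData(
        sample_ids=sample_ids,
        phenotype=y,
        age=age,
        sex=sex,
        smoking=smoking,
        pcs=pcs,
        genotypes=geno,
        variants=variants,
        gene_table=gene_table,
    )
    if config.quality_model is None:
        return cohort
    return inject_quality_fields(cohort, config)


def inject_quality_fields(cohort: CohortData, config: SimulationConfig) -> CohortData:
    """Attach QUAL/GQ/DP fields, honoring the configured corruption rates.

    Engineered violations are recorded in ``cohort.quality_ledger`` as
    dicts with the rule name and site (and sample, for genotype-level
    corruption) so tests can audit them.
    """
    qm = config.quality_model
    if qm is None:
        raise ValueError("config has no quality model")
    thr = _PRESET_THRESHOLDS[qm.preset]
    rng = _substreams(config.seed)["quality"]
    n, m = cohort.genotypes.shape

    qual = np.clip(rng.normal(qm.qual_mean, qm.qual_sd, m), thr["qual"] + 50.0, None)
    gq = (qm.gq_mean + qm.gq_sd * rng.standard_normal((n, m), dtype=np.float32))
    gq = np.clip(gq, thr["mean_gq"] + 10, 99).astype(np.int16)
    dp = np.clip(
        rng.poisson(qm.dp_mean, size=(n, m)), thr["singleton_dp"] + 5, None
    ).astype(np.int16)

    ledger: list = []
    rates = dict(qm.corruption)
    for rule, rate in rates.items():
        if rule == "site_qual":
            hit = rng.random(m) < rate
            qual[hit] = rng.uniform(0.0, thr["qual"], size=int(hit.sum()))
            ledger.extend({"rule": "site_qual", "site": int(j)}
                          for j in np.flatnonzero(hit))
        elif rule == "site_mean_gq":
            hit = rng.random(m) < rate
            for j in np.flatnonzero(hit):
                gq[:, j] = rng.integers(5, int(thr["mean_gq"]) - 5, size=n)
            ledger.extend({"rule": "site_mean_gq", "site": int(j)}
                          for j in np.flatnonzero(hit))
        elif rule == "singleton":
            # applies to sites that are singletons: degrade the carrier
            minor_count = np.minimum(
                np.where(cohort.genotypes >= 0, cohort.genotypes, 0).sum(0),
                np.where(cohort.genotypes >= 0, 2 - cohort.genotypes, 0).sum(0),
            )
            singles = np.flatnonzero(minor_count == 1)
            hit = singles[rng.random(singles.size) < rate]
            for j in hit:
                carriers = np.flatnonzero(cohort.genotypes[:, j] == 1)
                if carriers.size == 0:
                    continue
                i = carriers[0]
                gq[i, j] = rng.integers(0, thr["singleton_gq"])
                dp[i, j] = rng.integers(0, thr["singleton_dp"])
                ledger.append({"rule": "singleton", "site": int(j), "sample": int(i)})
        elif rule == "genotype_mask":
            k = rng.binomial(n * m, rate)
            flat = rng.choice(n * m, size=k, replace=False)
            ii, jj = np.unravel_index(flat, (n, m))
            gq[ii, jj] = rng.integers(0, thr["mask_gq"], size=k)
            ledger.extend(
                {"rule": "genotype_mask", "site": int(j), "sample": int(i)}
                for i, j in zip(ii, jj)
            )
        else:
            raise ValueError(f"unknown corruption rule {rule!r}")

    return replace_fields(cohort, qual=qual, gq=gq, dp=dp, quality_ledger=ledger)


def replace_fields(cohort: CohortData, **kw) -> CohortData:
    """Shallow-copy the cohort with some fields replaced."""
    data = {f: getattr(cohort, f) for f in cohort.__dataclass_fields__}
    data.update(kw)
    return CohortData(**data)


def permute_phenotype(cohort: CohortData, seed: int) -> CohortData:
    """Uniform random permutation of the phenotype vector only.

    Genotypes and covariates are untouched, so case/control totals are
    conserved; this is the permutation null used by the two-stage
    threshold calibration.
    """
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples to permute")
    rng = np.random.default_rng(seed)
    return replace_fields(cohort, phenotype=rng.permutation(cohort.phenotype))


# --------------------------------------------------------------------------
# I/O: VCF v4.2 + phenotype/covariate TSV + gene annotation TSV
# --------------------------------------------------------------------------

def write_cohort(cohort: CohortData, out_prefix: str) -> dict:
    """Write the cohort as ``{prefix}.vcf``, ``{prefix}.pheno.tsv`` and
    ``{prefix}.genes.tsv``; returns the paths.  Round-trip through
    :func:`read_cohort` reproduces dosages, missingness and quality
    fields exactly."""
    import pysam

    if cohort.n_samples == 0 or cohort.n_variants == 0:
        raise ValueError("refusing to write an empty cohort")
    paths = {
        "vcf": f"{out_prefix}.vcf",
        "pheno": f"{out_prefix}.pheno.tsv",
        "genes": f"{out_prefix}.genes.tsv",
    }

    header = pysam.VariantHeader()
    for chrom in pd.unique(cohort.variants["chrom"]):
        end = int(cohort.variants.loc[cohort.variants.chrom == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=end + 100_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for sid in cohort.sample_ids:
        header.add_sample(sid)

    qual = cohort.qual if cohort.qual is not None else np.full(cohort.n_variants, 100.0)
    with pysam.VariantFile(paths["vcf"], "w", header=header) as vcf:
        for j, row in enumerate(cohort.variants.itertuples()):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
                qual=float(qual[j]),
                id=str(row.id),
            )
            for i, sid in enumerate(cohort.sample_ids):
                d = int(cohort.genotypes[i, j])
                rec.samples[sid]["GT"] = (
                    (None, None) if d < 0 else ((0, 0), (0, 1), (1, 1))[d]
                )
                if cohort.gq is not None:
                    rec.samples[sid]["GQ"] = int(cohort.gq[i, j])
                if cohort.dp is not None:
                    rec.samples[sid]["DP"] = int(cohort.dp[i, j])
            vcf.write(rec)

    pheno = cohort.covariates().copy()
    pheno.insert(0, "status", cohort.phenotype)
    pheno.index.name = "sample_id"
    pheno.drop(columns=["smoking_ever"]).to_csv(paths["pheno"], sep="\t")
    cohort.gene_table.to_csv(paths["genes"], sep="\t", index=False)
    return paths


def read_cohort(prefix_or_paths) -> CohortData:
    """Read a cohort written by :func:`write_cohort` (or equivalent files)."""
    import pysam

    if isinstance(prefix_or_paths, dict):
        paths = prefix_or_paths
    else:
        paths = {
            "vcf": f"{prefix_or_paths}.vcf",
            "pheno": f"{prefix_or_paths}.pheno.tsv",
            "genes": f"{prefix_or_paths}.genes.tsv",
        }
    pheno = pd.read_csv(paths["pheno"], sep="\t", index_col="sample_id",
                        float_precision="round_trip")
    gene_table = pd.read_csv(paths["genes"], sep="\t", dtype={"chrom": str})
    pc_cols = [c for c in pheno.columns if c.startswith("PC")]

    rows, quals, geno_cols, gq_cols, dp_cols = [], [], [], [], []
    with pysam.VariantFile(paths["vcf"]) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            rows.append(
                dict(chrom=str(rec.contig), pos=rec.pos, ref=rec.ref,
                     alt=alts[0] if alts else ".", id=rec.id or ".")
            )
            quals.append(rec.qual if rec.qual is not None else np.nan)
            g = np.empty(len(sample_ids), dtype=np.int8)
            gq = np.full(len(sample_ids), -1, dtype=np.int16)
            dp = np.full(len(sample_ids), -1, dtype=np.int16)
            for i, sid in enumerate(sample_ids):
                s = rec.samples[sid]
                gt = s.get("GT", (None, None))
                g[i] = -1 if gt is None or None in gt else sum(gt)
                if s.get("GQ") is not None:
                    gq[i] = s["GQ"]
                if s.get("DP") is not None:
                    dp[i] = s["DP"]
            geno_cols.append(g)
            gq_cols.append(gq)
            dp_cols.append(dp)

    variants = pd.DataFrame(rows)
    # assign variants to annotated gene spans (primary span, no flank here;
    # flanked assignment is the QC module's job)
    gene = np.array([""] * len(variants), dtype=object)
    for t in gene_table.itertuples():
        hit = (
            (variants.chrom == str(t.chrom))
            & (variants.pos >= t.start)
            & (variants.pos <= t.end)
        )
        gene[hit.to_numpy()] = t.gene
    variants["gene"] = gene

    pheno = pheno.loc[sample_ids]
    return CohortData(
        sample_ids=sample_ids,
        phenotype=pheno["status"].to_numpy(dtype=np.int8),
        age=pheno["age"].to_numpy(dtype=float),
        sex=pheno["sex"].to_numpy(dtype=np.int8),
        smoking=pheno["smoking"].to_numpy(dtype=np.int8),
        pcs=pheno[pc_cols].to_numpy(dtype=float),
        genotypes=np.column_stack(geno_cols).astype(np.int8),
        variants=variants,
        gene_table=gene_table,
        qual=np.asarray(quals, dtype=float),
        gq=np.column_stack(gq_cols),
        dp=np.column_stack(dp_cols),
    )
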