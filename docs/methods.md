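# Methods

## The gene-based Bayes-factor statistic

For a gene with QC-passed rare-variant dosage block G (n samples × m
sites, minor-allele counts in {0,1,2}) and binary phenotype y, the gene
statistic combines two factors of evidence:

* **Burden factor.** The per-sample burden b_i = Σ_v G_iv enters a
  logistic model of disease (with covariates when adjusting); 2·log BF₀
  is the likelihood-ratio statistic for b, so it is χ²(1) under the
  null.  An alternate conjugate beta-binomial backend (separate vs
  common minor-allele rates in cases/controls with Beta(½, ½) priors)
  is available for covariate-free analyses; the burden construction is
  isolated behind a backend switch so a different Bayes-factor algebra
  can replace it without touching callers.
* **Informative prior.** A p-value p_prior sensitive to per-site
  allelic differences: either a one-sided Kolmogorov–Smirnov test (D⁺,
  detecting an excess of small within-gene single-variant p-values) or
  a SKAT variance-component test with Beta(MAF; 1, 25) weights.

The combined statistic is T = 2·log BF = 2·log BF₀ − 2·ln p_prior and
is referred to χ²(3): the burden factor contributes one degree of
freedom and, because a null p_prior is Uniform(0,1), −2·ln p_prior
contributes a χ²(2).

### Why the prior is computed conditionally on the burden

χ²(3) requires the two factors to be independent under the null.  A
plain KS or SKAT prior shares the aggregate-shift direction with the
burden factor, and the positive dependence inflates Var(T) above 6
(measured ≈ 6.9 for KS, ≈ 7.6 for SKAT at n = 2000, m = 25), which a
goodness-of-fit test on a few thousand null genes detects.  The default
therefore makes the prior measure per-site imbalance *beyond* the
aggregate burden:

* **KS prior** — each variant's case-carrier count k_j is referred to
  Hypergeometric(C, K, c_j), conditioning on the gene's total carrier
  slots C = Σc_j and total case-carrier count K = Σk_j, instead of the
  unconditional Hypergeometric(N, n_cases, c_j).
* **SKAT prior** — the weighted score vector is projected orthogonal to
  the unweighted burden direction and the χ²-mixture uses the residual
  covariance (the burden-adjusted SKAT decomposition; the projected
  quadratic form is asymptotically independent of the burden score).

With the conditional priors, simulated null scans give Var(T) ≈ 6.2,
KS goodness-of-fit p-values of 0.2–0.9 and type-I error at nominal 0.05
within half a percentage point (2,000 genes, 1,000 + 1,000 samples, 25
RVs per gene).  Unconditional variants remain available
(`PriorSpec(burden_conditional=False)`), with the caveat that the χ²(3)
reference is then anti-conservative.

### Discreteness of rare-variant p-values: fuzzy smoothing

Exact carrier-based tests of rare variants are discrete; feeding their
conservative or mid-p values into the KS prior distorts its null
distribution (measured: mid-p makes T under-dispersed, Var ≈ 4.1;
score-test p-values make it over-dispersed, Var ≈ 8.4, type-I ≈ 0.11).
The default therefore uses *fuzzy* (randomized) p-values — the null CDF
just below the observed outcome plus a uniform share of the outcome's
own probability — which are exactly Uniform(0,1) under the null.  The
uniform draws come from a dedicated substream keyed by the prior seed
and a CRC32 of the gene id, never from the data, so results are fully
deterministic and independent of scan order.  Deterministic `midp` and
plain-exact `none` modes are available for users who prefer a
(conservative) non-randomized test.

With covariate adjustment the per-variant p-values feeding the KS prior
switch to Rao score tests on mean-imputed dosages, since exact
conditioning is no longer available.

### What the priors are sensitive to

The two priors discriminate between causal architectures: the weighted
quadratic (SKAT) prior is markedly more sensitive to signal
concentrated in a single rare site, while the KS prior responds to the
number of moderately imbalanced sites.  A single extreme site can move
the one-sided KS statistic by at most 1/m regardless of how extreme its
p-value is, so a KS prior can never dominate on one-variant signal —
the test suite asserts the attainable contrast (quadratic prior wins
concentrated signal; both priors are powered against the null in
diffuse and concentrated regimes).

## SKAT engine

Q = (y − μ̂)ᵀ G W Gᵀ (y − μ̂) with μ̂ from the covariates-only logistic
fit; the null distribution is the mixture Σ λ_k χ²₁ with λ from the
projected kernel.  Tail probabilities are computed by Imhof
characteristic-function inversion, truncated where analytic envelope
and oscillation tail bounds guarantee the requested absolute accuracy
(1e-6), with a Liu four-moment fallback that is flagged.  Equal
eigenvalues reproduce χ²(k) closed forms to 1e-6.  At very small sample
sizes (n ≈ 60) the asymptotic p-value tracks a phenotype-permutation
estimate closely in the tail (|Δp| ≲ 0.003 for p ≤ 0.1) but overstates
significance by a few percent in the distribution bulk — a known
finite-sample feature of quadratic-form asymptotics with binary
outcomes; comparisons with permutation oracles are therefore made in
the tail.

## Firth single-variant analysis

The Firth fit maximizes ℓ(β) + ½·log det I(β) by damped Newton steps
with step-halving, giving finite estimates under complete separation
(for the saturated intercept+indicator model the slope equals the
Haldane–Anscombe ½-cell-corrected log odds ratio — a closed form the
tests exploit).  P-values are penalized likelihood-ratio tests with the
coefficient constrained to zero and the penalty kept on the full
design; confidence limits are profile-penalized-likelihood, with a
flagged Wald fallback when profiling cannot bracket.  Convergence:
gradient norm below 1e-8, at most 50 iterations.  Missing dosages are
mean-imputed (2·MAF) to keep n constant.  FDR selection uses
Benjamini–Hochberg q-values by default (deterministic, sufficient for
a fixed q ≤ 0.01 gate); a Storey-style π₀-smoother option exists.

## QC cascades

Two presets encode the discovery- and replication-style pipelines (see
README for the rules).  Numerical/order choices: all thresholds are
strict inequalities, so boundary values survive; genotype masking
(GQ/DP) is applied before missing-rate, HWE and MAF computation, while
the mean-GQ site rule uses pre-mask GQ values; rules are evaluated in a
fixed order (site quality → biallelic/sex-chromosome → singleton → HWE
in controls → missing rate → MAF) with first-failure attribution, so
per-rule exclusion counts partition the excluded sites; a missing GQ/DP
value fails the mask (conservative); singletons are sites with exactly
one minor allele among non-missing genotypes after masking; the
heterozygosity outlier rule uses the n−1 standard deviation and a zero
SD yields no outliers; sex chromosomes match {X, Y, chrX, chrY}.  Gene
regions are annotated spans ±1000 bp, 1-based inclusive on both ends,
floored at position 1; a variant may belong to several overlapping
genes; genes need ≥ 20 QC-passed RVs to be analyzable, applied per
cohort.  The ≥ 20-RV count is taken after the full cascade including
the MAF filter, consistent with counting bi-allelic RVs.

## Two-stage calibration

For B permutation replicates (default 100) the phenotype of each cohort
is permuted — phenotype only, which also breaks phenotype–covariate
links — and all gene p-values recomputed in both cohorts via a
precomputed scanner (carrier indicators, hypergeometric tables and
smoothing uniforms are phenotype-independent, so each replicate costs a
matrix-vector product plus lookups).  A grid pair (γ, λ) is admissible
when the number of replicates containing at least one gene with
P_d ≤ γ and P_r ≤ λ is ≤ B·α — the empirical version of
Pr(V ≥ 1) ≤ α; counting total hits instead is available by flag.  The
least stringent admissible pair is returned (ties toward larger γ, then
larger λ) along with the full event-count grid.  Default grids:
γ ∈ {10⁻³, 5×10⁻⁴, 10⁻⁴, 5×10⁻⁵}, λ ∈ {0.05, 0.01}.  The replication
threshold λ applies to the replication cohort's gene BF p-value, not
its prior p-value.  Validation uses fresh permutation seeds as fresh
null replicates.  Fisher's method combines the two stages:
p = exp(−X/2)(1 + X/2) with X = −2(ln P_d + ln P_r).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **MAF spectrum** — a four-bin mixture (monomorphic / (0, 0.01) /
  [0.01, 0.05) / [0.05, 0.5]) with default weights 10.12 / 75.79 /
  4.47 / 9.62 % and log-uniform within-bin frequencies kept away from
  bin edges so *observed* sample MAFs land in the intended bin at
  realistic cohort sizes; a rare-only preset models the post-QC world
  the gene tests operate in.
* **Disease model** — retrospective sampling: a super-population is
  drawn, disease assigned by logit P(case) = intercept + Σ β_v G_v +
  γ'X, and individuals kept until the case/control quotas fill (an
  explicit failure names the population cap).  Covariates: age
  ~ N(60, 10²), sex ~ Bernoulli(½), smoking never/former/current
  (35/40/25 %) with strong disease effects (log-OR 0.9 former, 1.6
  current) so adjusted and unadjusted analyses differ measurably, and
  5 standard-normal PCs with zero default effect.  The default
  intercept −2 gives a baseline prevalence near 12 %.  Non-causal sites
  are drawn only for retained individuals — exact under retrospective
  sampling because they are independent of the phenotype.
* **Causal architectures** — "sparse" (a fraction of sites, default
  20 %, carries a per-allele log-OR) or "uniform" (every site carries
  the same shift).
* **Quality fields** — QUAL ~ N(1000, 200²), GQ ~ N(80, 10²), DP ~
  Poisson(50), clipped to clear every preset threshold; corruption
  rates engineer violations of specific rules (site QUAL, site mean-GQ,
  singleton carrier quality, genotype-level GQ) and every engineered
  violation is recorded in a ledger for auditing.
* **Reproducibility** — one master seed fans out into named substreams
  (frequencies, population, quality, layout); identical config + seed
  gives byte-identical cohorts, and phenotype permutation touches the
  phenotype vector only.

What the generator does **not** emulate: linkage disequilibrium between
sites, kinship/family structure, case enrichment by family history or
early onset, sequencing-read-level artifacts, and population
stratification beyond the supplied PC effects.  Passing tests therefore
demonstrate calibration and power under independent-site,
unrelated-sample conditions; real exomes add LD and structure the
pipeline addresses only through its covariate adjustments and
user-supplied exclusion lists (relatedness pruning is consumed as a
config input, not computed).

## Problem sizes used in tests

The null-calibration suite uses 2,000 genes × 25 RVs at 1,000 + 1,000
samples; the FWER validation calibrates on a 200-gene cohort pair
(B = 100) and validates on 500 fresh null replicates; the acceptance
script runs a reduced 800-gene calibration and a 150-gene, 300-replicate
FWER check.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances while keeping a full run on one CPU in
minutes.

## Known limitations

* The Bayes-factor construction here is the simplest one satisfying the
  printed χ²(3) contract; other algebraic constructions with the same
  null behaviour exist and can be swapped in behind the burden backend
  and prior seams.
* Fuzzy p-values introduce an auxiliary (seeded, reproducible)
  randomization into the KS prior; users who cannot accept that should
  use `smoothing="midp"` and expect mild conservatism.
* The KS-prior fast scanner implements the unadjusted, burden-
  conditional path only; adjusted scans go through `genome_scan`.
* Exact carrier tests ignore the distinction between heterozygous and
  homozygous carriers (appropriate for MAF < 1 %, where homozygotes are
  vanishingly rare).
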