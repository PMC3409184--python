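# Methods

`strainscan` implements association mapping of quantitative and
pharmacological-response traits across a panel of classical inbred mouse
strains, with the multiple-testing calibration, quality control and
validation statistics such a study needs. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## The mixed model

For animal-level phenotypes `y` (n animals, s strains),

    y = X b + Z u + e,    Var(u) = sg2 * K,    Var(e) = se2 * I,

where `Z` is the animal-to-strain incidence matrix, `K` the strain kinship
matrix, `X` the fixed effects (intercept, optionally one-hot treatment with
the control arm as baseline — never the SNP column, which the scan appends
itself). Writing `delta = se2/sg2`, the restricted likelihood is profiled to
a one-dimensional function of `delta` using the spectral decomposition of
`Q2' Z K Z' Q2`, where the columns of `Q2` are an explicit orthonormal basis
of the orthogonal complement of `col(X)` (complete QR). Working in that
basis, rather than eigendecomposing `S H S` directly, keeps the
zero-eigenvalue directions of the genetic covariance cleanly separated from
`col(X)`; with a naive `S H S` decomposition the tied zero eigenvalues let
the solver return eigenvectors contaminated by the intercept, which biases
the fit (we verified the implementation against the closed-form REML of the
balanced one-way random-effects model, which it matches to ~1e-7).

`delta` is maximized on a 100-interval natural-log grid spanning
[1e-5, 1e5], each local grid maximum refined by bounded scalar minimization
to 1e-8; solutions at the grid edge are flagged `boundary`. Heritability is
reported as `h2 = sg2/(sg2+se2) = 1/(1+delta)`, estimated by fitting this
null model with no SNP — that same fit is the per-trait heritability table.

### Kinship

Kinship is the identity-by-state allele-sharing fraction over jointly called
SNPs, diagonal forced to 1. Pairwise-complete estimation with a forced unit
diagonal can leave small negative eigenvalues (we observe down to about
-8e-4 at 22 strains with 3% missing calls), so wherever the matrix enters a
covariance, negative eigenvalues are clipped to zero and a 1e-6 diagonal
ridge is added. A plain ridge of 1e-6 alone is *not* sufficient for
positive definiteness at realistic missingness.

### The scan and its two REML modes

SNPs are first filtered for informativeness (called in at least 20 of 22
strains, minor allele in at least 4 — minor defined among non-missing calls,
exact ties resolved by calling the first strain's allele major) and
collapsed into strain distribution patterns (SDPs): SNPs with identical
(pattern, missing-mask) pairs are one statistical test whose result is
broadcast to all member SNPs. Strains with a missing call at an SDP are
dropped for that test (per-SDP complete case); SDPs monomorphic among the
remaining strains are flagged `degenerate` rather than scored.

Two scan modes are provided:

- **Null-reuse (default).** Variance components are estimated once per scan
  on the null model and re-used for every SDP; each SDP is then a
  generalized-least-squares F-test (df 1, n − rank(X) − 1, two-sided) of the
  minor-allele code under that fixed covariance. This is the standard
  large-panel shortcut and is what the orchestrator runs.
- **Exact per-SDP REML** (`exact_reml=True`). Variance components are
  re-estimated with the marker in the fixed effects, i.e. the classical
  REML-based marker F-test. The distinction matters enormously for strong
  loci: a QTL explaining ~70% of strain-level variance reaches only
  p ~ 1e-4..1e-5 under null-reuse (the null fit absorbs the QTL variance
  into `sg2`, inflating the implied standard error), but p < 1e-20 under
  per-SDP REML. Power claims in the acceptance suite therefore use the
  exact mode; everything about calibration uses the default mode.

Variance explained by an SDP is `1 − RSS(with SNP)/RSS(without SNP)` after
whitening by the covariance of whichever mode produced the fit.

## Drug-effect phenotypes

Treated and control animals are separate cohorts, so per-animal drug
responses are inferred: for each treated animal, either the difference or
the fold change between its value and the mean of the reference-arm animals
of the same strain. Three ECG-amplitude traits (Qamp, QRSarea, Samp) default
to difference mode; all other traits to fold change, log-transformed with
the natural log before scanning (the log base is configurable; monotone
rescalings leave p-values unchanged and only relabel effect sizes).
Drug-vs-drug contrasts (e.g. high-dose agonist vs blocker) use the other
drug arm as reference under the same scheme.

A variance screen excludes a scan when any animal deviates from its strain
mean by more than `k_sd` (default 3) residual standard deviations. The SD
pools residuals across strains within the scan — per-strain SDs on ~9
animals are too unstable — with a per-strain option exposed.

## Multiple-testing calibration

Two thresholds are reported side by side:

- **Strict Bonferroni**: `alpha / (n_SDPs × n_scans)`, where `n_scans`
  counts only scans passing QC. At the published panel scale
  (47999 SDPs × 89 scans, alpha 0.05) this gives −log10 p = 7.9.
- **Suggestive**: `alpha / (n_eff_pheno × n_eff_geno)`. `n_eff_pheno` is the
  number of trait-covariance eigenvectors explaining 99.5% of trait
  variance; `n_eff_geno` inverts the median, across phenotype permutations,
  of the minimum scan p-value (rounded to the nearest integer — the
  published 4.914e-4 inverts to 2035, and 16 × 2035 gives −log10 p = 5.8).
  The inverse-median estimator is implemented as published; note it is
  biased for small SDP counts (the median minimum of m independent uniforms
  is 1 − 2^(−1/m), whose inverse is ≈ m/ln 2), which a unit test documents
  at m = 1.

Permutations default to shuffling individual animals (100 permutations,
seeded); permuting whole strain blocks is available and requires balanced
replicates.

## Scan QC and what "calibrated" means at 22 strains

QC replaces visual QQ inspection: a scan fails when genomic inflation
`lambda` (median 1-df chi-square over its null median) leaves [0.8, 1.25]
or when p-values below 0.01 exceed 3× the uniform expectation; a
manual-override list mirrors eye-ball judgment. Expected QQ quantiles use
(i − 0.5)/n, with i/(n+1) behind a flag.

An intrinsic property of strain-panel scans deserves emphasis: every SDP
statistic is a function of the ~21 strain-level degrees of freedom, so
within one scan p-values are strongly dependent and per-scan `lambda`
fluctuates with standard deviation of order sqrt(2/21) ≈ 0.3 even when the
test is perfectly calibrated. Moreover, permuting *individual animals*
produces systematically deflated scans (median lambda ≈ 0.73 in our
measurements): the null REML fit absorbs chance strain-mean over-dispersion
into `sg2` but cannot compensate under-dispersion, because `sg2 ≥ 0`.
Permuting *strain labels* — the exchangeable unit of the mixed model —
preserves genuine strain-level variance, keeps the model correctly
specified, and yields lambda concentrated near 1 (cross-seed median ≈ 1.1).
The calibration acceptance test therefore permutes strain labels, asserts
the inflation band on the cross-seed median, and applies its KS uniformity
check to one independently drawn SDP p-value per seed (within-scan
p-values are not an i.i.d. sample). This also explains why a fraction of
real scans must be discarded by QQ inspection in studies of this design.

## Hits, loci and surrogate imputation

SNPs are classed significant (p ≤ strict), suggestive (strict < p ≤
suggestive) or null; labeled SNPs on one chromosome within `merge_distance`
(default 1 Mb, the LD scale of classical inbred panels) merge into loci.
Loci on different chromosomes sharing an identical SDP are cross-annotated,
never merged. A significant SDP with missing strain calls is corrected by
the nearest fully-called compatible SNP (patterns agreeing at all jointly
observed strains) within 1 Mb of any member SNP — ties by smaller distance,
then lower coordinate — or marked "no surrogate".

## Validation statistics

**Expression enrichment.** A two-component Gaussian mixture is EM-fitted to
log expression values (quantile-split initialization, canonicalized
m1 < m2, convergence at log-likelihood gain < 1e-8, non-convergence
flagged). Genes are "expressed" above the smallest value whose posterior
membership in the high component reaches 95%, "non-expressed" below the
analogous low-component cutoff, ambiguous between. Because the log
posterior odds are quadratic in x when the component sds differ, the
posterior is monotone only between its stationary point and the dominated
tail; cutoff root-finding is bracketed accordingly and aborts with a
diagnostic if monotonicity fails there. Genes within 500 kb of hit SNPs
(closed 1-based intervals on both sides) are tested for an excess of
expressed genes against the expressed fraction of *all* probed genes
(window genes not removed from the background), with an exact one-sided
binomial tail computed by direct pmf summation; a two-sided variant doubles
the smaller tail.

**Replication.** Primary loci are re-tested by scanning their member SNPs
in an independent panel sharing at least 19 strains; the replication scan's
genome-wide inflation is estimated and, by default, each statistic is
genomic-control corrected (1-df chi-square divided by lambda) before
conversion to a p-value. A locus replicates when its best corrected member
p-value is ≤ 0.05; loci untestable in the replication panel (markers absent
or degenerate) leave the denominator. The summary statistic is the exact
binomial tail of the replication count at chance rate alpha — 8 of 35 at
0.05 gives p = 0.0003.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime the analysis assumes:
22 strains in a handful of ancestral clusters sharing megabase-scale
haplotype blocks (each block: two ancestral haplotypes assigned to clusters
at random, plus a 5% within-cluster flip rate and 3% missing calls); 9
biological replicates per strain × 4 treatment arms; traits built as
baseline + polygenic strain effect drawn with covariance h2·K + treatment
shift + optional treatment-specific QTL + unit-total residual, so the
strain-level heritability of a QTL-free trait equals `h2` (default 0.6) by
construction; and log expression from a two-component mixture with weights
(0.45, 0.55), means (2, 6.5) and sds (0.5, 1.0). One master seed drives
everything; each stage derives its own stream from a CRC-hash of the stage
name, so stages are independently reproducible.

Deliberate departures from real data: no recombination map or subspecies
ancestry mosaic, exchangeable rather than phylogenetic cluster structure,
Gaussian residuals, and missingness independent of genotype. Tests passing
on these panels demonstrate the statistical machinery (calibration,
recovery, power, invariances) — not robustness to the measurement
pathologies of real phenotyping.

Two generator configurations serve different checks. The structured default
(6 clusters, 50-SNP blocks) reproduces long-LD kinship structure and is
used for heritability recovery and QTL power. Calibration checks use the
no-LD configuration (every strain its own cluster, single-SNP blocks),
because a 6-cluster panel admits at most 2^6/2 distinct cluster
bipartitions and cannot produce the thousands of distinct SDPs that a
genome-wide null calibration needs.

## Problem sizes and defaults used by the test suite

Unit tests run panels of 200–500 SNPs. Acceptance checks use: 2000 SDPs for
the OLS-equivalence oracle; 20 seeds × ~4600 SDPs × 198 animals for null
calibration; 100 seeds × 3 heritability levels at 22 strains × 36 animals
for recovery; 50 seeds × ~380 SDPs in exact REML mode for power; 5000 genes
for the mixture. These sizes were chosen so the full suite completes in a
few minutes while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- Single genetic variance component; no GxE interaction test.
- The null-reuse scan understates strong single-locus signals (by design;
  use `exact_reml=True` when effect sizes matter).
- The effective-test estimator inherits the published estimator's small-m
  bias rather than correcting it.
- Genomic-control replication correction assumes a uniform inflation of the
  1-df statistic; it is our reading of "corrected inflated/deflated
  p-values", and is documented rather than hidden.
- VCF/PLINK ingestion, probe-to-gene mapping and expression preprocessing
  are out of scope; normalized expression is consumed, not produced.
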