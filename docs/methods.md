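# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the known limitations of the
package. It states how quantities are computed; all empirical numbers it
refers to are produced by the test suite or `scripts/acceptance.py` at run
time.

## Pseudobulk construction

Cells with a mitochondrial read fraction above 0.20 are removed (boundary
kept). Genes must be detected (count > 0) in at least 10% of all cells in
the study, have a mean count of at least 0.1 across all cells, and not be
on an exclusion list (mitochondrial / ribosomal identifiers); both gene
filters are computed over all cells, not per cell type. A cell type enters
mapping when at least 40 donors contribute at least 5 cells each, and
donors below 5 cells are excluded per cell type.

Normalization uses per-cell library-size factors relative to the median
depth of the cell type's cells (cells with zero depth get factor 1),
followed by log2(1 + x) and the mean over each donor's cells. This is a
deliberate simplification of pooled-deconvolution (scran-style) size
factors: it preserves the "normalize, log-transform, mean-aggregate"
contract without the pooling machinery, and on simulated data the two
differ only through the size-factor estimator. The pseudocount is 1 so
zero counts map to zero; normalization is per cell type. Both choices are
configurable.

## Variant QC and kinship

SNPs are kept when biallelic, autosomal, minor allele frequency strictly
above 0.05, and exact Hardy–Weinberg p above 10⁻⁶. The HWE test is the
exact conditional test: all heterozygote counts compatible with the
observed allele counts are enumerated and configurations no more probable
than the observed one are summed (monomorphic sites return p = 1). LD
pruning is greedy and windowed (250-SNP windows, 50-SNP steps, r² > 0.9):
within a window, while any surviving pair exceeds the threshold, the
lower-MAF member is removed (ties: later position) — a deterministic rule;
plink's internal order of operations is not reproduced. The genomic
relationship matrix is the variance-standardized K = ZZᵀ/m with per-SNP
mean-imputed, centered, unit-variance dosages; zero-variance SNPs are
excluded.

The cis window defaults to 1 Mb around the gene body (closed interval,
BED starts converted to 1-based). The window is configurable, including
arbitrarily large values that make every SNP on the chromosome cis.

## Mixed-model association

Each gene's pseudobulk vector is inverse-normal transformed
(Φ⁻¹((rank−0.5)/n), average ranks for ties). For the main eQTL scan the
top 20 expression PCs (computed per cell type on the transformed donor ×
gene matrix) are regressed out; the PC count is capped at (n_donors−10)/2
so small cohorts keep usable residual degrees of freedom.

The null model y = Cα + u_g + u_w + ε with
Cov = σ²_g K + σ²_w diag(1/nCells) + σ²_e I is fitted by REML once per
gene. The two variance ratios (σ²_g, σ²_w)/σ²_e are profiled: a coarse
log-spaced grid (including exact zeros) is scanned with σ²_e solved
analytically at each point, then a Nelder-Mead refinement runs in
log-ratio space. Each evaluation is a fresh Cholesky factorization — at
the donor counts this pipeline targets (tens to a few hundred) this is
faster and simpler than low-rank update schemes. The whitening transform
is the inverse Cholesky factor of the fitted covariance; every cis SNP is
then tested by least squares on the whitened design (the standard
fast-LMM compromise: variance components are not refitted per SNP).

Wald p-values use the t distribution with the residual degrees of freedom
rather than a normal approximation. This matters: the interaction design
(intercept + 20 PCs + disease + SNP + SNP×disease) consumes a large share
of a 60-donor cohort's information, and the empirical-Bayes stage
downstream is driven by the extreme tail of the test statistics, where
normal and t(≈36) differ by an order of magnitude in tail mass. With
normal p-values the disease-label permutation produced a visible excess of
false interaction eQTLs; with the t correction the permuted run is clean.
For the same reason the effect panel handed to the shrinkage stage
converts (β̂, ŝ, dof) into normal-equivalent standard errors,
ŝ_eff = |β̂| / Φ⁻¹(p_t/2), which is the identity in the bulk of the
distribution and inflates ŝ only in the tails.

Interaction scans model y = Cα + PCγ + gβ + dδ + (g·d)β_int + random
effects and Wald-test β_int. PCs are kept as fixed effects and not
pre-regressed, because disease status is typically correlated with leading
expression PCs and residualizing would absorb part of the interaction
signal. Cell types need at least 10 donors per disease group; SNPs with
MAF ≤ 5% in either group are excluded before testing and the observed
per-group MAF is re-checked post hoc.

## Multivariate shrinkage and significance

Effects are modeled across cell types as
b ~ π₀δ₀ + Σ π_k N(0, ω_k U_k) with observations
b̂ ~ N(b, S V S), S the per-test standard errors and V a residual
correlation estimated from tests with all |z| < 2 (identity when too few).
The covariance library combines canonical matrices (identity,
per-condition singletons, equal effects) with data-driven ones: rank-1
outer products of the top 5 principal components of the strong-association
matrix (univariate adaptive-shrinkage LFSR < 0.1 in some condition), the
rank-5 reconstruction, and 50 fixed-point iterations of an
extreme-deconvolution EM refinement of those candidates. When no strong
association exists (e.g. permuted-label runs) the library is canonical
only — learning covariances from noise extremes demonstrably overfits the
null. The scaling grid ω runs geometrically from (min ŝ)²/10 to 4·max b̂²
with √2 spacing. Mixture weights are fitted by EM (relative log-likelihood
tolerance 10⁻⁸, 1,000 iterations max) on a random subset of 10,000 tests
(all tests when fewer); tests missing in a condition enter with an
enormous standard error rather than being dropped.

Posteriors are the responsibility-weighted mixtures of the per-component
conditional normals. The local false sign rate per condition is
min{P(b ≥ 0 | data), P(b ≤ 0 | data)}, both sides including the point
mass at zero; a fully null posterior therefore has LFSR near 1, and no
test with LFSR ≥ 0.5 can ever be called.

Significance is two-tier: LFSR ≤ 0.05 in at least one cell type, which
opens a relaxed ≤ 0.1 tier for the same test in other cell types. Top
eQTLs take the lowest significant LFSR per gene per cell type (ties:
larger |posterior β|, then smaller position). Pairwise sharing between
cell types requires significance in both, the same sign, and
min|β|/max|β| ≥ 0.5 ("within a factor of 0.5" read as a magnitude ratio —
the common convention of sharing utilities). Classification uses a
two-cell-type buffer: global when significant in ≥ R−2 conditions, unique
at exactly 1, multi otherwise. Sign adjustment orients each row so the
majority sign among significant entries is positive (ties: sign of the
largest |β|). Representative pruning per gene uses Euclidean distances
between per-vector-centered absolute effect vectors, threshold 0.2;
groups of ≥ 3 are cut by average-linkage clustering at the k in [2, 5]
maximizing the mean silhouette width, keeping per cluster the member
significant in the most cell types (ties: lower minimum LFSR). Per-vector
centering is the default; per-condition centering is available via the
`centering` argument.

## Colocalization

Per SNP, the Wakefield log approximate Bayes factor is
½log(1−r) + z²r/2 with r = W²/(W²+se²); W defaults to 0.15 for
quantitative traits and 0.2 (log-odds scale) for case-control. The
five-hypothesis posterior uses priors (p1, p2, p12) = (10⁻⁴, 10⁻⁴, 10⁻⁵)
and is evaluated entirely in log space. Genes require ≥ 100 shared
variable (0 < MAF < 1) SNPs after allele harmonization (swapped alleles
flip the GWAS sign); PP4 ≥ 0.6 is the shared-causal-variant call. The
eQTL side can enter either as shrunken posterior means/SDs (default) or
via the LFSR-as-p substitution |z| = Φ⁻¹(1 − LFSR) with the posterior-mean
sign; the upstream description under-determines this, so both modes are
provided and neither is claimed canonical.

## Enrichment and differential expression

Fisher's exact test (sample odds ratio ad/bc, conditional two-sided p)
compares eQTL classes against GWAS risk variants (nominal threshold 10⁻⁶)
using TSS-distance-matched nulls: a Gaussian KDE of log10(1+|distance|)
is fitted to the target set, a second KDE with the same absolute bandwidth
to the candidate pool, and pool members are rejection-sampled without
replacement with probability proportional to the density ratio. The
log-distance scale and the shared bandwidth keep the ratio stable across
the orders of magnitude that TSS distances span.

Differential expression between disease groups uses the Wilcoxon rank-sum
test with tie correction reported as an AUC (U/(n_A n_B)), a two-sided
normal-approximation p, and logFC = difference of mean log(1+count);
Benjamini–Hochberg adjustment is applied within cell type. (BH is not
idempotent on its own output — only monotonicity and dominance over the
raw p-values are guaranteed.) Interaction eGenes are partitioned into
differentially expressed (adjusted p < 0.1), equally expressed (detected
in > 30% of cells in both groups and |logFC| < 0.2), and other.

## Synthetic cohorts

The generator emulates the data such a study consumes, with a recorded
truth table. Genotypes: per gene, a block of SNPs built from haplotypes by
copy-with-mutation (copy probability √r² so adjacent SNPs have r² near the
target; frequencies uniform in the MAF range; blocks independent between
genes). Optional relative pairs share one full haplotype (expected GRM
entry ≈ 0.5, kinship 0.25); the real cohort's kinship distribution is
unknown, so relatedness is a free parameter, not an emulation target.
Disease status is assigned independently of genotype, isolating
interaction effects from confounding. Cell types fall into 4 contiguous
lineage groups; planted eQTLs are global (all cell types), lineage (one
group), or unique (one cell type), with per-allele effects on log2
expression drawn N(0, effect_size_sd) and interaction effects
N(0, interaction_effect_sd) on a subset of eQTL genes.

The donor-level latent mean per gene and cell type is baseline + βg + δd +
β_int·g·d + ε with Var(ε) = noise_sd²·(1 + 1/nCells); nCells is
gamma-Poisson with configurable mean and dispersion. Cell-level counts are
Poisson around the exponentiated latent mean with a lognormal per-cell
library factor, so normalized log mean-aggregation recovers the latent
mean up to a small Jensen bias (independent of nCells) plus sampling noise
that shrinks with nCells. Defaults describe the package's own calibration
cohort: 60 donors (half ILD), 5 cell types, 300 genes × 20 cis-SNPs, 30%
eQTL genes with effect SD 0.8, 10% interaction genes with effect SD 1,
mean 40 cells per donor and cell type, noise SD 0.5.

What the generator does not emulate: coalescent LD structure and allele
frequency spectra, read-level count overdispersion beyond Poisson,
ambient RNA/doublets, cell-type misassignment, imputation error, or
genotype–disease confounding. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that the pipeline is robust to every real-data pathology.

## Calibration experiments and problem sizes

`sceqtl.calibration` packages the experiments the tests and the
acceptance script run:

- interaction permutation: the full interaction stage on true vs
  donor-permuted disease labels; the permuted count as a percentage of
  the true count is the empirical false-positive rate (acceptance runs
  the 300-gene default; the test suite a 150-gene version). At 60 donors
  a single permutation draw is a high-variance estimator: an occasional
  draw retains enough genotype-weighted correlation with the true labels
  that a strong planted interaction leaks an attenuated — but, after
  cross-cell-type shrinkage, detectable — signal into the "null" scan.
  This is leakage of genuine signal through an unlucky draw, not test
  miscalibration (per-test p-values are uniform under genotype
  shuffling), and it disappears at realistic cohort sizes and effect
  scales. The permuted count is therefore summarized as the median over
  five independent donor-level permutations.
- genotype permutation: the cis scan after donor-level genotype shuffling
  on an LD-free cohort (so the ≥ 10⁴ p-values are approximately
  independent draws for a KS uniformity test).
- effect recovery at 150 donors; mixture-weight recovery on a 0.7/0.3
  two-component simulation of 10,000 tests; sharing-pattern
  classification accuracy at 150 donors and 10 cell types (expected
  labels are obtained by applying the same global/multi/unique rule to
  the true planted pattern); false-sign-rate control on a direct
  panel simulation.

Problem sizes were chosen so each experiment completes in minutes on one
CPU while keeping enough tests for the statistical assertions.

## Numerical choices

Eigenvalues of covariance candidates are floored at 10⁻¹⁰ of the largest
(PSD clipping). REML uses Cholesky with a clipping fallback for non-PD
fitted covariances. Degenerate SNP designs (no variance in the tested
coefficient after whitening) are skipped and logged. EM components with
weight below 10⁻¹⁰ are dropped from posterior computation. Mixture
likelihoods use batched Cholesky factorizations across tests. p-values
are floored at the smallest positive double.

## Known limitations

- Size factors are library-size-based, not pooled deconvolution.
- Single-causal-variant colocalization only; no LD-aware fine-mapping.
- The LMM tests reuse the null-model whitening per gene (score/Wald
  approximation), as is standard for fast eQTL scans.
- The extreme-deconvolution refinement runs a fixed 50 iterations rather
  than to a convergence criterion.
- No trans-eQTLs, conditional secondary signals, or X/Y/MT variants.
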