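"""Synthetic cohort generator with recorded ground truth.

Emulates the data a cell-type-resolved pseudobulk eQTL study consumes:
biallelic genotypes in approximate Hardy-Weinberg equilibrium with LD blocks
and optional close relatives, per-donor per-cell-type cell counts, single-cell
expression whose donor-level mean follows a linear model with planted
cis-eQTL effects (in global / lineage / unique sharing patterns), disease
labels, genotype x disease interaction effects, and residual noise whose
variance scales with 1 + 1/nCells.  Every planted effect is recorded in a
truth table so downstream stages can be scored against known ground truth.

The generative model per donor d, cell type c, gene g:

    mu = baseline(g, c) + beta * dosage(d)            (if c carries the eQTL)
         + delta(g, c) * disease(d)
         + beta_int * dosage(d) * disease(d)          (if c carries the
                                                       interaction)
         + eps,   eps ~ N(0, noise_sd^2 * (1 + 1/nCells(d, c)))

``mu`` is a log2-scale latent pseudobulk mean; cell-level counts are Poisson
around the exponentiated latent mean with a per-cell library-size factor, so
that library-size normalization followed by log2(1+x) mean-aggregation
recovers ``mu`` up to a small Jensen bias and sampling noise that shrinks
with nCells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

# genes are spaced far enough apart that default 1 Mb cis windows never overlap
_GENE_SPACING = 2_500_000
_GENE_LENGTH = 10_000
_GENES_PER_CHROM = 50
_SNP_SPACING = 1_000


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    The defaults describe the cohort used throughout the package's own
    calibration analyses: 60 donors split evenly between disease (ILD) and
    control, 5 cell types in 4 lineage groups, 300 genes with a 20-SNP LD
    block each, 30% of genes carrying a cis-eQTL (per-allele effect SD 0.8 on
    log2 expression) and 10% carrying a genotype x disease interaction of SD
    1, negative-binomial cell counts with mean 40 per donor and cell type,
    and residual noise SD 0.5.
    """

    n_donors: int = 60
    frac_cases: float = 0.5
    n_celltypes: int = 5
    n_genes: int = 300
    snps_per_gene: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_r2: float = 0.5
    relatedness_pairs: int = 0
    eqtl_fraction: float = 0.3
    effect_size_sd: float = 0.8
    sharing_pattern_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    interaction_fraction: float = 0.1
    interaction_effect_sd: float = 1.0
    disease_effect_sd: float = 0.2
    cells_per_donor_dist: tuple[float, float] = (40.0, 2.0)
    noise_sd: float = 0.5
    n_lineages: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise InvalidConfigError("n_donors must be >= 2")
        fracs = {
            "frac_cases": self.frac_cases,
            "ld_block_r2": self.ld_block_r2,
            "eqtl_fraction": self.eqtl_fraction,
            "interaction_fraction": self.interaction_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if abs(sum(self.sharing_pattern_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("sharing_pattern_probs must sum to 1")
        if self.interaction_fraction > self.eqtl_fraction:
            raise InvalidConfigError("interaction_fraction cannot exceed eqtl_fraction")
        if 2 * self.relatedness_pairs > self.n_donors:
            raise InvalidConfigError("too many relatedness pairs for n_donors")


@dataclass
class SimulatedCohort:
    """Everything one simulation produced, plus the ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    genes: pd.DataFrame  # BED-like: chrom, start, end, strand, gene_id
    donor_meta: pd.DataFrame  # donor_id, disease_status
    cells: pd.DataFrame  # cell_id, donor_id, cell_type, mito_fraction, n_features, disease_status
    counts: np.ndarray  # genes x cells raw counts
    truth: pd.DataFrame  # gene, snp, cell_type, true_beta, is_interaction, true_beta_interaction, pattern_label
    latent: dict[str, pd.DataFrame] = field(default_factory=dict)  # cell type -> donor x gene latent mean
    ncells: pd.DataFrame | None = None  # donor x cell type
    celltypes: list[str] = field(default_factory=list)
    lineages: dict[str, int] = field(default_factory=dict)  # cell type -> lineage group


def _celltype_names(n: int) -> list[str]:
    return [f"ct{i:02d}" for i in range(n)]


def _lineage_partition(celltypes: list[str], n_lineages: int) -> dict[str, int]:
    """Fixed contiguous partition of cell types into lineage groups."""
    n = len(celltypes)
    k = min(n_lineages, n)
    bounds = np.linspace(0, n, k + 1).astype(int)
    out = {}
    for g in range(k):
        for ct in celltypes[bounds[g] : bounds[g + 1]]:
            out[ct] = g
    return out


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate dosages with per-gene LD blocks; returns (genotypes, gene BED).

    Haplotypes are built by copy-with-mutation within each gene's block: SNP
    j+1 copies SNP j's allele with probability sqrt(ld_block_r2), giving
    adjacent-SNP r^2 approximately ld_block_r2.  ``relatedness_pairs``
    consecutive donor pairs share one full haplotype (parent-offspring-like;
    expected relative-scale kinship 0.25, GRM entry about 0.5).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_snps = cfg.n_genes * cfg.snps_per_gene
    lo, hi = cfg.maf_range
    freq = rng.uniform(lo, hi, size=n_snps)
    copy_p = np.sqrt(cfg.ld_block_r2)

    n_hap = 2 * cfg.n_donors
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    fresh = (rng.random((n_hap, n_snps)) < freq).astype(np.int8)
    copy = rng.random((n_hap, n_snps)) < copy_p
    hap[:, :] = fresh
    for j in range(1, n_snps):
        if j % cfg.snps_per_gene == 0:  # block boundary: no copying across genes
            continue
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])

    # relatives: donor 2k+1 inherits donor 2k's first haplotype
    for k in range(cfg.relatedness_pairs):
        hap[2 * (2 * k + 1)] = hap[2 * (2 * k)]

    dosage = (hap[0::2] + hap[1::2]).astype(float)

    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    chrom = [str(1 + i // _GENES_PER_CHROM) for i in range(cfg.n_genes)]
    within = np.arange(cfg.n_genes) % _GENES_PER_CHROM
    start0 = within * _GENE_SPACING + 1_000_000  # BED 0-based start
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start0,
            "end": start0 + _GENE_LENGTH,
            "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-"),
            "gene_id": gene_ids,
        }
    )

    # SNPs for gene i sit inside its cis window, upstream of the gene body
    snp_rows = []
    for i in range(cfg.n_genes):
        base = start0[i] - cfg.snps_per_gene * _SNP_SPACING  # 1-based positions below
        for j in range(cfg.snps_per_gene):
            snp_rows.append(
                (f"snp{i:04d}_{j:02d}", chrom[i], int(base + j * _SNP_SPACING + 1), "A", "G")
            )
    snp_meta = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    donors = [f"D{i:03d}" for i in range(cfg.n_donors)]
    return GenotypeMatrix(dosage=dosage, donors=donors, snp_meta=snp_meta), genes


def _plant_effects(cfg: SimConfig, rng: np.random.Generator, celltypes: list[str], lineages: dict[str, int]) -> pd.DataFrame:
    """Draw the truth table: which (gene, snp, cell type) carry which effects."""
    n_eqtl = int(round(cfg.eqtl_fraction * cfg.n_genes))
    n_int = int(round(cfg.interaction_fraction * cfg.n_genes))
    eqtl_genes = rng.choice(cfg.n_genes, size=n_eqtl, replace=False)
    int_genes = set(rng.choice(eqtl_genes, size=n_int, replace=False)) if n_int else set()
    labels = ["global", "lineage", "unique"]
    groups: dict[int, list[str]] = {}
    for ct, g in lineages.items():
        groups.setdefault(g, []).append(ct)

    rows = []
    for gi in eqtl_genes:
        snp_j = rng.integers(cfg.snps_per_gene)
        snp_id = f"snp{gi:04d}_{snp_j:02d}"
        beta = rng.normal(0.0, cfg.effect_size_sd)
        pattern = labels[rng.choice(3, p=np.asarray(cfg.sharing_pattern_probs))]
        if pattern == "global":
            cts = list(celltypes)
        elif pattern == "lineage":
            cts = list(groups[int(rng.choice(sorted(groups)))])
        else:
            cts = [celltypes[int(rng.integers(len(celltypes)))]]
        is_int = gi in int_genes
        beta_int = rng.normal(0.0, cfg.interaction_effect_sd) if is_int else 0.0
        for ct in cts:
            rows.append(
                (f"gene{gi:04d}", snp_id, ct, beta, is_int, beta_int, pattern)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "snp",
            "cell_type",
            "true_beta",
            "is_interaction",
            "true_beta_interaction",
            "pattern_label",
        ],
    )


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Simulate genotypes, cells, counts, and the ground-truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genotypes, genes = simulate_genotypes(cfg, rng)
    celltypes = _celltype_names(cfg.n_celltypes)
    lineages = _lineage_partition(celltypes, cfg.n_lineages)
    truth = _plant_effects(cfg, rng, celltypes, lineages)

    donors = genotypes.donors
    n_cases = int(round(cfg.frac_cases * cfg.n_donors))
    status = np.array(["control"] * cfg.n_donors, dtype=object)
    status[rng.choice(cfg.n_donors, size=n_cases, replace=False)] = "ILD"
    donor_meta = pd.DataFrame({"donor_id": donors, "disease_status": status})
    is_case = (status == "ILD").astype(float)

    # nCells: gamma-Poisson (negative binomial) per donor x cell type
    mean_cells, disp = cfg.cells_per_donor_dist
    lam = rng.gamma(shape=disp, scale=mean_cells / disp, size=(cfg.n_donors, cfg.n_celltypes))
    ncells = rng.poisson(lam)
    ncells_df = pd.DataFrame(ncells, index=donors, columns=celltypes)

    # baselines and per-(gene, cell type) disease shifts on the log2 scale
    gene_base = rng.uniform(1.0, 4.0, size=cfg.n_genes)
    ct_shift = rng.normal(0.0, 0.5, size=(cfg.n_celltypes, cfg.n_genes))
    delta = rng.normal(0.0, cfg.disease_effect_sd, size=(cfg.n_celltypes, cfg.n_genes))

    gene_idx = {f"gene{i:04d}": i for i in range(cfg.n_genes)}
    snp_idx = {s: j for j, s in enumerate(genotypes.snp_meta["id"])}

    latent: dict[str, pd.DataFrame] = {}
    gene_cols = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    for ci, ct in enumerate(celltypes):
        mu = np.tile(gene_base + ct_shift[ci], (cfg.n_donors, 1))
        mu += np.outer(is_case, delta[ci])
        sub = truth[truth["cell_type"] == ct]
        for row in sub.itertuples():
            g = genotypes.dosage[:, snp_idx[row.snp]]
            j = gene_idx[row.gene]
            mu[:, j] += row.true_beta * g
            if row.is_interaction:
                mu[:, j] += row.true_beta_interaction * g * is_case
        nc = np.maximum(ncells[:, ci], 1)
        eps_sd = cfg.noise_sd * np.sqrt(1.0 + 1.0 / nc)
        mu += rng.normal(size=mu.shape) * eps_sd[:, None]
        latent[ct] = pd.DataFrame(mu, index=donors, columns=gene_cols)

    # cell-level Poisson counts around the exponentiated latent mean
    cell_rows = []
    count_blocks = []
    cell_no = 0
    for ci, ct in enumerate(celltypes):
        for di, d in enumerate(donors):
            n = ncells[di, ci]
            if n == 0:
                continue
            rate = np.maximum(2.0 ** latent[ct].to_numpy()[di] - 1.0, 0.0)
            lib = rng.lognormal(mean=0.0, sigma=0.3, size=n)
            block = rng.poisson(lib[None, :] * rate[:, None])
            count_blocks.append(block)
            mito = rng.beta(2.0, 20.0, size=n)
            for k in range(n):
                cell_rows.append(
                    (
                        f"cell{cell_no:06d}",
                        d,
                        ct,
                        float(mito[k]),
                        int((block[:, k] > 0).sum()),
                        status[di],
                    )
                )
                cell_no += 1
    counts = (
        np.concatenate(count_blocks, axis=1)
        if count_blocks
        else np.zeros((cfg.n_genes, 0), dtype=int)
    )
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "donor_id", "cell_type", "mito_fraction", "n_features", "disease_status"],
    )
    return SimulatedCohort(
        config=cfg,
        genotypes=genotypes,
        genes=genes,
        donor_meta=donor_meta,
        cells=cells,
        counts=counts,
        truth=truth,
        latent=latent,
        ncells=ncells_df,
        celltypes=celltypes,
        lineages=lineages,
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=int(seed))


def simulate_gwas_stats(
    cohort: SimulatedCohort,
    gene: str,
    n_individuals: int = 1000,
    shared: bool = True,
    effect: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic GWAS summary statistics over one gene's cis-SNP block.

    A fresh population with the cohort's LD structure is simulated; a
    quantitative trait is driven by the gene's planted causal SNP
    (``shared=True``) or by a different SNP of the block (``shared=False``),
    and per-SNP marginal OLS gives (beta, se).  Columns match the GWAS
    summary-statistics interface of the colocalization stage.
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    meta = cohort.genotypes.snp_meta
    block = meta.index[meta["id"].str.startswith(f"snp{gene[4:]}_")].to_numpy()
    if block.size == 0:
        raise ValueError(f"gene {gene!r} has no SNP block")
    freq = cohort.genotypes.allele_freq()[block]
    copy_p = np.sqrt(cfg.ld_block_r2)
    n_hap = 2 * n_individuals
    fresh = (rng.random((n_hap, block.size)) < freq).astype(np.int8)
    copy = rng.random((n_hap, block.size)) < copy_p
    hap = fresh.copy()
    for j in range(1, block.size):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    dose = (hap[0::2] + hap[1::2]).astype(float)

    planted = cohort.truth[cohort.truth["gene"] == gene]
    snp_ids = meta.loc[block, "id"].tolist()
    if not planted.empty and planted["snp"].iat[0] in snp_ids:
        causal_local = snp_ids.index(planted["snp"].iat[0])
    else:
        causal_local = 0
    if not shared:
        causal_local = (causal_local + block.size // 2) % block.size
    y = effect * dose[:, causal_local] + rng.standard_normal(n_individuals)

    betas, ses, pvals = [], [], []
    from scipy import stats as _st

    for j in range(block.size):
        x = dose[:, j]
        if np.std(x) == 0:
            betas.append(0.0); ses.append(1.0); pvals.append(1.0)
            continue
        res = _st.linregress(x, y)
        betas.append(res.slope)
        ses.append(res.stderr)
        pvals.append(res.pvalue)
    sub = meta.loc[block]
    return pd.DataFrame(
        {
            "snp": sub["id"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "effect_allele": sub["alt"].to_numpy(),
            "other_allele": sub["ref"].to_numpy(),
            "beta": betas,
            "se": ses,
            "p": pvals,
            "maf": np.minimum(freq, 1 - freq),
            "n": n_individuals,
        }
    )


def export_fixture(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write the cohort as VCF + MTX/TSV + BED + truth TSV; returns paths."""
    from . import io as _io  # deferred: io imports scipy.io

    return _io.write_cohort(cohort, out_dir)
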