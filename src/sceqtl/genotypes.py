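"""Variant-level QC, kinship, and cis-window indexing.

Implements the genotype side of the eQTL pipeline: an exact Hardy-Weinberg
equilibrium test, MAF/HWE variant filters, greedy windowed LD pruning, a
variance-standardized genomic relationship matrix (GRM), and the gene ->
cis-SNP index used by the association stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000
"""Default cis window in bp around the gene body (1 Mb)."""


@dataclass
class GenotypeMatrix:
    """Donor x SNP dosage matrix with per-SNP metadata.

    ``dosage`` holds allele counts in {0, 1, 2}; missing entries are NaN.
    ``snp_meta`` has columns ``id, chrom, pos, ref, alt`` with 1-based
    positions, sorted by position within chromosome.
    """

    dosage: np.ndarray
    donors: list[str]
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.donors), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.donors)} donors x {len(self.snp_meta)} SNPs"
            )

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_snps(self) -> int:
        return self.snp_meta.shape[0]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, ignoring missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency (not folded)."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        x = self.dosage.copy()
        mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = mean[idx[1]]
        return x

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            donors=list(self.donors),
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
        )


@dataclass
class KinshipMatrix:
    """Symmetric donor x donor genetic relationship matrix."""

    values: np.ndarray
    donors: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.donors)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match donor list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    def psd_clipped(self, floor: float = 0.0) -> np.ndarray:
        """Eigenvalue-clipped positive semi-definite version of the matrix."""
        w, v = np.linalg.eigh((self.values + self.values.T) / 2.0)
        if w.min() < floor:
            logger.info("clipping %d negative kinship eigenvalues", int((w < floor).sum()))
        w = np.clip(w, floor, None)
        return (v * w) @ v.T


@dataclass
class CisIndex:
    """Map from gene id to the indices of SNPs within the cis window."""

    window: int
    gene_snps: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.gene_snps[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_snps

    def genes(self) -> list[str]:
        return list(self.gene_snps)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one.  Monomorphic sites return p = 1.

    Parameters
    ----------
    n_aa, n_ab, n_bb
        Genotype counts (homozygous ref, heterozygous, homozygous alt).
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_a = 2 * n_aa + n_ab  # allele-A count
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0

    # All het counts with the parity of n_rare, from 0/1 up to n_rare.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = (n - hets - rare_hom).astype(int)
    # log P(het | allele counts) up to a common constant:
    # P = n! / (nAA! nAa! naa!) * 2^nAa * nA! na! / (2n)!
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_ab)]
    # two-sided: sum configurations with probability <= observed
    p = prob[prob <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """(n_ref_hom, n_het, n_alt_hom) from one SNP's dosage column."""
    d = dosage_col[~np.isnan(dosage_col)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def filter_variants(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    autosomes_only: bool = True,
) -> np.ndarray:
    """Boolean mask of SNPs passing MAF (strict >), HWE, and autosome filters.

    Mirrors the variant inclusion rule used for pseudobulk eQTL mapping:
    biallelic autosomal SNPs with MAF greater than ``maf_min`` and an exact
    HWE p-value above ``hwe_alpha``.
    """
    maf = g.maf()
    mask = maf > maf_min
    if autosomes_only:
        chroms = g.snp_meta["chrom"].astype(str)
        auto = chroms.str.removeprefix("chr").str.isdigit().to_numpy()
        mask &= auto
    for j in np.flatnonzero(mask):
        caa, cab, cbb = genotype_counts(g.dosage[:, j])
        if caa + cab + cbb == 0:
            mask[j] = False
            continue
        if hwe_exact_test(caa, cab, cbb) <= hwe_alpha:
            mask[j] = False
    logger.info("variant filter: %d of %d SNPs retained", int(mask.sum()), g.n_snps)
    return mask


def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = np.nan
    c = (xc.T @ xc) / x.shape[0]
    r = c / np.outer(sd, sd)
    return np.nan_to_num(r**2, nan=0.0)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 250,
    step_snps: int = 50,
    r2_max: float = 0.9,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns a boolean keep-mask.

    Within each window of ``window_snps`` position-sorted SNPs, while any
    surviving pair has dosage r^2 above ``r2_max``, the member with the lower
    MAF is removed (ties: the later position).  The window then slides by
    ``step_snps``.  Matches the plink-style ``--indep-pairwise 250 50 0.9``
    contract without reproducing plink's internals.
    """
    if window_snps < step_snps:
        raise ValueError("window_snps must be >= step_snps")
    keep = np.ones(g.n_snps, dtype=bool)
    if g.n_snps < 2:
        return keep
    x = g.imputed()
    maf = g.maf()
    starts = range(0, max(g.n_snps - 1, 1), step_snps)
    for s in starts:
        idx = np.flatnonzero(keep[s : s + window_snps]) + s
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(x[:, idx])
        np.fill_diagonal(r2, 0.0)
        while True:
            i, j = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[i, j] <= r2_max:
                break
            a, b = idx[i], idx[j]
            # remove the lower-MAF member; ties -> later position
            drop = a if (maf[a] < maf[b] or (maf[a] == maf[b] and a > b)) else b
            keep[drop] = False
            k = i if drop == a else j
            r2[k, :] = 0.0
            r2[:, k] = 0.0
    logger.info("LD prune: %d of %d SNPs retained", int(keep.sum()), g.n_snps)
    return keep


def make_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """Variance-standardized genomic relationship matrix.

    Missing dosages are mean-imputed per SNP; each SNP column is centered and
    scaled to unit variance; K = Z Z^T / n_snps.  Zero-variance SNPs are
    excluded (logged).
    """
    x = g.imputed()
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    if not ok.all():
        logger.info("GRM: excluding %d zero-variance SNPs", int((~ok).sum()))
    if ok.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs for a GRM")
    z = (x[:, ok] - mean[ok]) / sd[ok]
    k = (z @ z.T) / ok.sum()
    return KinshipMatrix(values=(k + k.T) / 2.0, donors=list(g.donors))


def cis_index(
    genes: pd.DataFrame,
    snp_meta: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> CisIndex:
    """Index SNPs within ``window`` bp of each gene body (closed interval).

    ``genes`` is BED-like with 0-based half-open ``start``/``end``; SNP
    positions are 1-based.  A SNP is cis to a gene when its position lies in
    [gene_start - window, gene_end + window] on the same chromosome, with
    gene_start/gene_end in 1-based inclusive coordinates.
    """
    out = CisIndex(window=int(window))
    known = set(snp_meta["chrom"].astype(str))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in snp_meta.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chrom[str(chrom)] = (pos[order], sub.index.to_numpy()[order])
    for row in genes.itertuples():
        chrom = str(row.chrom)
        if chrom not in known:
            logger.info("cis_index: no SNPs on chromosome %s (gene %s)", chrom, row.gene_id)
            out.gene_snps[row.gene_id] = np.array([], dtype=int)
            continue
        pos, orig = by_chrom[chrom]
        start_1b = int(row.start) + 1  # BED -> 1-based inclusive
        end_1b = int(row.end)
        lo = np.searchsorted(pos, start_1b - window, side="left")
        hi = np.searchsorted(pos, end_1b + window, side="right")
        out.gene_snps[row.gene_id] = np.sort(orig[lo:hi])
    return out
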