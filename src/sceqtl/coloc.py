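"""Bayesian colocalization of eQTL and GWAS signals (single causal variant).

For each gene region the five hypotheses are: H0 no association with either
trait, H1/H2 association with one trait only, H3 two distinct causal
variants, H4 one shared causal variant.  Evidence per SNP is a Wakefield
approximate Bayes factor computed from (beta, se) and a prior effect-size
SD; hypothesis posteriors combine per-SNP ABFs with prior probabilities
(p1, p2, p12) in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

W_QUANT = 0.15  # prior effect SD, quantitative traits
W_CC = 0.2  # prior effect SD on the log-odds scale, case-control traits


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_shared_snps: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("PP vector must have 5 entries")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("PP vector must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float = W_QUANT) -> np.ndarray:
    """Log approximate Bayes factor: 0.5 log(1-r) + z^2 r / 2, r = W^2/(W^2+se^2)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def coloc_abf(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Five-hypothesis posterior from two aligned log-ABF vectors.

    PP0..PP4 are proportional to {1, p1 S1, p2 S2, p1 p2 (S1 S2 - S12),
    p12 S12} with S1 = sum exp(lABF1), S2 = sum exp(lABF2), and
    S12 = sum exp(lABF1 + lABF2), all evaluated with log-sum-exp.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.size == 0 or labf1.shape != labf2.shape:
        raise ValueError("need two aligned, nonempty lABF vectors")
    ls1 = logsumexp(labf1)
    ls2 = logsumexp(labf2)
    ls12 = logsumexp(labf1 + labf2)
    # log sum over ordered distinct pairs: S1*S2 - S12 (computed stably)
    lsum, sign = logsumexp(
        [ls1 + ls2, ls12], b=[1.0, -1.0], return_sign=True
    )
    lh = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + (lsum if sign > 0 else -np.inf),
            np.log(p12) + ls12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_shared_snps=labf1.size, priors=(p1, p2, p12))


def harmonize(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    min_shared: int = 100,
) -> pd.DataFrame | None:
    """Intersect two summary-statistic tables on chrom:pos with allele alignment.

    Both tables need columns (snp, chrom, pos, effect_allele, other_allele,
    beta, se).  When the GWAS effect/other alleles are swapped relative to
    the eQTL side, the GWAS beta sign is flipped.  Returns the merged panel
    or None when fewer than ``min_shared`` variable SNPs are shared.
    """
    e = eqtl.copy()
    gw = gwas.copy()
    for df in (e, gw):
        df["key"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    merged = e.merge(gw, on="key", suffixes=("_e", "_g"))
    if merged.empty:
        return None
    same = (merged["effect_allele_e"] == merged["effect_allele_g"]) & (
        merged["other_allele_e"] == merged["other_allele_g"]
    )
    swapped = (merged["effect_allele_e"] == merged["other_allele_g"]) & (
        merged["other_allele_e"] == merged["effect_allele_g"]
    )
    merged = merged[same | swapped].copy()
    flip = swapped.loc[merged.index]
    merged.loc[flip, "beta_g"] = -merged.loc[flip, "beta_g"]
    if "maf_g" in merged:
        variable = (merged["maf_g"] > 0) & (merged["maf_g"] < 1)
        merged = merged[variable]
    if len(merged) < min_shared:
        logger.info("harmonize: only %d shared SNPs (< %d), skipped", len(merged), min_shared)
        return None
    return merged.reset_index(drop=True)


def lfsr_significance_input(
    post_beta: np.ndarray,
    post_sd: np.ndarray,
    lfsr: np.ndarray,
    mode: str = "posterior",
) -> tuple[np.ndarray, np.ndarray]:
    """(beta, se) pairs for the eQTL side of colocalization.

    ``posterior`` mode passes the shrunken posterior mean and SD straight
    through.  ``lfsr`` mode realizes the LFSR-in-place-of-p substitution:
    |z| = Phi^-1(1 - lfsr) signed by the posterior mean, with beta the
    posterior mean and se = |beta| / |z|.
    """
    post_beta = np.asarray(post_beta, float)
    post_sd = np.asarray(post_sd, float)
    lfsr = np.asarray(lfsr, float)
    if mode == "posterior":
        return post_beta, np.maximum(post_sd, 1e-12)
    if mode != "lfsr":
        raise ValueError(f"unknown mode {mode!r}")
    capped = np.clip(lfsr, 1e-300, 1.0)
    z = norm.ppf(1.0 - capped)
    z = np.maximum(z, 0.0)
    sign = np.where(post_beta >= 0, 1.0, -1.0)
    beta = np.where(np.abs(post_beta) > 0, post_beta, z * 1e-6 * sign)
    with np.errstate(divide="ignore"):
        se = np.where(z > 0, np.abs(beta) / z, np.abs(beta) * 1e12 + 1.0)
    return beta, se


def colocalize_gene(
    eqtl_stats: pd.DataFrame,
    gwas_stats: pd.DataFrame,
    min_shared: int = 100,
    w_eqtl: float = W_QUANT,
    w_gwas: float = W_QUANT,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult | None:
    """Harmonize one gene's cis panel against a GWAS and run coloc-ABF."""
    merged = harmonize(eqtl_stats, gwas_stats, min_shared=min_shared)
    if merged is None:
        return None
    l1 = wakefield_abf(merged["beta_e"].to_numpy(), merged["se_e"].to_numpy(), w_eqtl)
    l2 = wakefield_abf(merged["beta_g"].to_numpy(), merged["se_g"].to_numpy(), w_gwas)
    return coloc_abf(l1, l2, p1=p1, p2=p2, p12=p12)
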