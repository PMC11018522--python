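"""Enrichment testing and pseudobulk differential expression.

Fisher's exact test for enrichment of eQTL classes among GWAS risk variants
against TSS-distance-matched null sets (KDE rejection sampling), a
Wilcoxon rank-sum test reported as an AUC (the probability that a random
case cell exceeds a random control cell), Benjamini-Hochberg adjustment,
and the partition of interaction eGenes into differentially expressed /
equally expressed / other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds ratio = ad/bc, conditional hypergeometric p).  A zero
    margin is an error; OR is inf when bc = 0.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def matched_null(
    pool_distances: np.ndarray,
    target_distances: np.ndarray,
    size: int,
    seed: int,
    max_rounds: int = 1000,
) -> np.ndarray:
    """TSS-distance-matched null set by KDE rejection sampling.

    A Gaussian KDE (Silverman bandwidth) of log10(1 + |distance|) is fitted
    to the target and to the pool; pool members are accepted with
    probability proportional to the target/pool density ratio, without
    replacement, until ``size`` members are drawn.  Returns indices into
    the pool.
    """
    pool = np.log10(1.0 + np.abs(np.asarray(pool_distances, float)))
    target = np.log10(1.0 + np.abs(np.asarray(target_distances, float)))
    if size > pool.size:
        raise ValueError(f"requested {size} from a pool of {pool.size}")
    rng = np.random.default_rng(seed)
    jitter = 1e-9 * rng.standard_normal(pool.size)  # KDE needs nonzero spread
    kde_t = stats.gaussian_kde(target + 1e-9 * rng.standard_normal(target.size))
    # equalize the absolute bandwidths so the density ratio is not distorted
    bw_abs = kde_t.factor * max(target.std(), 1e-6)
    kde_p = stats.gaussian_kde(pool + jitter, bw_method=bw_abs / max(pool.std(), 1e-6))
    dens_t = kde_t(pool)
    dens_p = np.maximum(kde_p(pool), 1e-300)
    w = dens_t / dens_p
    w = w / w.max()
    chosen: list[int] = []
    available = np.ones(pool.size, dtype=bool)
    for _ in range(max_rounds):
        if len(chosen) >= size:
            break
        idx = np.flatnonzero(available)
        accept = rng.random(idx.size) < w[idx]
        for i in idx[accept]:
            if len(chosen) >= size:
                break
            chosen.append(int(i))
            available[i] = False
        if not available.any():
            break
    if len(chosen) < size:
        raise RuntimeError(
            f"rejection sampling exhausted the pool at {len(chosen)} < {size}; "
            "request a smaller null set"
        )
    return np.asarray(chosen[:size])


def wilcoxauc(x_a: np.ndarray, x_b: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon rank-sum with AUC and log fold change.

    AUC = U / (nA nB) estimates P(a random A value exceeds a random B
    value, ties counted half).  The p-value is the two-sided normal
    approximation with tie correction; logFC = mean(A) - mean(B), both
    groups assumed already on a log scale.
    """
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = x_a.size, x_b.size
    combined = np.concatenate([x_a, x_b])
    ranks = stats.rankdata(combined)
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    auc = u / (n_a * n_b)
    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n_a * n_b / 2.0) / np.sqrt(var_u)
        p = 2.0 * stats.norm.sf(abs(z))
    logfc = float(x_a.mean() - x_b.mean())
    return float(auc), float(min(p, 1.0)), logfc


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_by_disease(
    counts: np.ndarray,
    cells: pd.DataFrame,
    gene_ids: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-cell-type Wilcoxon DE between ILD and control cells.

    Expression is log(pseudocount + count) per cell; returns a long table
    (cell_type, gene, auc, p, logfc, frac_ild, frac_control, p_adj) with BH
    adjustment within cell type.
    """
    counts = np.asarray(counts, float)
    rows = []
    for ct, grp in cells.reset_index(drop=True).groupby("cell_type", sort=False):
        case_cols = grp.index[grp["disease_status"] == "ILD"].to_numpy()
        ctrl_cols = grp.index[grp["disease_status"] == "control"].to_numpy()
        if case_cols.size == 0 or ctrl_cols.size == 0:
            logger.info("de_by_disease: cell type %s lacks one group, skipped", ct)
            continue
        log_case = np.log(pseudocount + counts[:, case_cols])
        log_ctrl = np.log(pseudocount + counts[:, ctrl_cols])
        for i, gene in enumerate(gene_ids):
            auc, p, logfc = wilcoxauc(log_case[i], log_ctrl[i])
            frac_i = float((counts[i, case_cols] > 0).mean())
            frac_c = float((counts[i, ctrl_cols] > 0).mean())
            rows.append((ct, gene, auc, p, logfc, frac_i, frac_c))
    out = pd.DataFrame(
        rows, columns=["cell_type", "gene", "auc", "p", "logfc", "frac_ild", "frac_control"]
    )
    if not out.empty:
        out["p_adj"] = out.groupby("cell_type")["p"].transform(lambda s: bh_adjust(s.to_numpy()))
    return out


def int_egene_overlap(
    de: pd.DataFrame,
    int_egenes: pd.DataFrame,
    de_alpha: float = 0.1,
    widely_expressed_frac: float = 0.30,
    logfc_max: float = 0.2,
) -> pd.DataFrame:
    """Partition interaction eGenes into DE / equally-expressed / other.

    Per (cell_type, gene) in ``int_egenes``: DE when adjusted p < de_alpha;
    equally expressed when detected in more than ``widely_expressed_frac``
    of cells in BOTH disease groups and |logFC| < logfc_max; otherwise (or
    when the DE entry is missing) "other".
    """
    de_idx = de.set_index(["cell_type", "gene"]) if not de.empty else de
    rows = []
    for rec in int_egenes.itertuples():
        key = (rec.cell_type, rec.gene)
        if de.empty or key not in de_idx.index:
            logger.info("int_egene_overlap: no DE record for %s/%s", *key)
            rows.append((*key, "other"))
            continue
        r = de_idx.loc[key]
        if float(r["p_adj"]) < de_alpha:
            cat = "DE"
        elif (
            float(r["frac_ild"]) > widely_expressed_frac
            and float(r["frac_control"]) > widely_expressed_frac
            and abs(float(r["logfc"])) < logfc_max
        ):
            cat = "equal"
        else:
            cat = "other"
        rows.append((*key, cat))
    out = pd.DataFrame(rows, columns=["cell_type", "gene", "category"])
    return out


def enrichment_vs_matched_null(
    class_snps: set[str],
    gwas_snps: set[str],
    pool: pd.DataFrame,
    target_distances: np.ndarray,
    seed: int,
    null_size: int | None = None,
) -> tuple[float, float, int]:
    """Fisher enrichment of a SNP class among GWAS hits vs a matched null.

    ``pool`` has columns (snp, tss_distance) for candidate non-significant
    SNPs.  Returns (odds ratio, p, null size used).
    """
    size = null_size or min(len(class_snps), len(pool))
    idx = matched_null(
        pool["tss_distance"].to_numpy(), target_distances, size=size, seed=seed
    )
    null_snps = set(pool["snp"].iloc[idx])
    a = len(class_snps & gwas_snps)
    b = len(class_snps - gwas_snps)
    c = len(null_snps & gwas_snps)
    d = len(null_snps - gwas_snps)
    # guard empty margins with a Haldane-style fallback
    if min(a + c, b + d, a + b, c + d) == 0:
        logger.info("enrichment: degenerate margin (a=%d b=%d c=%d d=%d)", a, b, c, d)
        return np.nan, 1.0, size
    odds, p = fisher_exact(a, b, c, d)
    return odds, p, size
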