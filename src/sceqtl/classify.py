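"""Significance calling, top-eQTL selection, sharing, and classification.

Two-tier significance: an association is significant in a cell type if its
LFSR is at most 0.05 there, or at most 0.1 there provided it reaches 0.05 in
some cell type (the relaxed tier compensates for unevenly powered cell
types).  Top eQTLs (lowest significant LFSR per gene per cell type) are
compared pairwise between cell types — shared when significant in both with
the same sign and an effect-size ratio of at least 0.5 — and classified as
global (significant in all but a two-cell-type buffer), unique (one cell
type), or multi (anything between).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def call_significance(
    lfsr: np.ndarray,
    primary: float = 0.05,
    secondary: float = 0.1,
) -> np.ndarray:
    """Two-tier significance matrix from a tests x conditions LFSR matrix.

    A condition is called significant iff its LFSR <= primary, or its
    LFSR <= secondary while some condition of the same test reaches primary.
    """
    if primary > secondary:
        raise ValueError("primary threshold must not exceed secondary")
    lfsr = np.asarray(lfsr, dtype=float)
    anchor = (lfsr <= primary).any(axis=1, keepdims=True)
    return (lfsr <= primary) | ((lfsr <= secondary) & anchor)


def select_top(
    ids: pd.DataFrame,
    lfsr: np.ndarray,
    sig: np.ndarray,
    betas: np.ndarray,
    conditions: list[str],
    snp_pos: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Top eQTL per (gene, cell type): the significant SNP with lowest LFSR.

    Ties break by larger |posterior beta|, then smaller genomic position.
    Returns a long table (gene, cell_type, snp, lfsr, beta).
    """
    lfsr = np.asarray(lfsr, float)
    betas = np.asarray(betas, float)
    sig = np.asarray(sig, bool)
    pos = snp_pos or {}
    rows = []
    genes = ids["gene"].to_numpy()
    snps = ids["snp"].to_numpy()
    for gene in pd.unique(genes):
        tidx = np.flatnonzero(genes == gene)
        for r, ct in enumerate(conditions):
            cand = tidx[sig[tidx, r]]
            if cand.size == 0:
                continue
            order = sorted(
                cand,
                key=lambda i: (
                    lfsr[i, r],
                    -abs(betas[i, r]),
                    pos.get(snps[i], 0),
                ),
            )
            i = order[0]
            rows.append((gene, ct, snps[i], float(lfsr[i, r]), float(betas[i, r])))
    return pd.DataFrame(rows, columns=["gene", "cell_type", "snp", "lfsr", "beta"])


def pairwise_sharing(
    top_ids: pd.DataFrame,
    betas: np.ndarray,
    sig: np.ndarray,
    conditions: list[str],
    factor: float = 0.5,
) -> pd.DataFrame:
    """Fraction of top eQTLs shared between every pair of cell types.

    ``top_ids`` indexes the rows of ``betas``/``sig`` that are top eQTLs
    (one row per test in the union of per-cell-type top sets).  For a pair
    (a, b), eligible tests are those significant in both; shared tests
    additionally have the same effect sign and min|beta|/max|beta| >=
    ``factor``.  Diagonal is 1; pairs with no eligible test are NaN.
    """
    betas = np.asarray(betas, float)
    sig = np.asarray(sig, bool)
    r = len(conditions)
    out = np.full((r, r), np.nan)
    np.fill_diagonal(out, 1.0)
    for a in range(r):
        for b in range(a + 1, r):
            both = sig[:, a] & sig[:, b]
            if not both.any():
                logger.info("pairwise_sharing: no eligible pair for (%s, %s)", conditions[a], conditions[b])
                continue
            ba, bb = betas[both, a], betas[both, b]
            same_sign = np.sign(ba) == np.sign(bb)
            lo = np.minimum(np.abs(ba), np.abs(bb))
            hi = np.maximum(np.abs(ba), np.abs(bb))
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(hi > 0, lo / hi, 1.0)
            shared = same_sign & (ratio >= factor)
            out[a, b] = out[b, a] = shared.mean()
    return pd.DataFrame(out, index=conditions, columns=conditions)


def classify_eqtl(sig_row: np.ndarray, buffer: int = 2) -> str:
    """Global / multi / unique label from one test's significance vector.

    global: significant in at least R - buffer conditions (36 of 38 for the
    main analysis, 31 of 33 for interaction eQTLs); unique: exactly one;
    multi: in between; none: zero.
    """
    sig_row = np.asarray(sig_row, bool)
    r = sig_row.size
    if r < 3:
        raise ValueError("need at least 3 conditions to classify")
    s = int(sig_row.sum())
    if s == 0:
        return "none"
    if s == 1:
        return "unique"
    if s >= r - buffer:
        return "global"
    return "multi"


def classify_all(sig: np.ndarray, buffer: int = 2) -> np.ndarray:
    return np.array([classify_eqtl(row, buffer=buffer) for row in np.asarray(sig, bool)])


def sign_adjust(betas: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Orient each row so the majority sign among significant entries is +.

    Ties break by the sign of the largest |beta| among significant entries;
    rows with no significant entry are left unchanged.
    """
    betas = np.asarray(betas, float).copy()
    sig = np.asarray(sig, bool)
    for i in range(betas.shape[0]):
        s = sig[i]
        if not s.any():
            continue
        vals = betas[i, s]
        pos = int((vals > 0).sum())
        neg = int((vals < 0).sum())
        if pos > neg:
            orient = 1.0
        elif neg > pos:
            orient = -1.0
        else:
            orient = np.sign(vals[np.argmax(np.abs(vals))]) or 1.0
        betas[i] *= orient
    return betas


def _centered_abs(vec: np.ndarray, per_condition_mean: np.ndarray | None = None) -> np.ndarray:
    a = np.abs(vec)
    if per_condition_mean is not None:
        return a - per_condition_mean
    return a - a.mean()


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over points, from a precomputed distance matrix."""
    n = dist.shape[0]
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():  # singleton cluster: conventionally 0
            sil[i] = 0.0
            continue
        a = dist[i, own].mean()
        b = np.inf
        for lab in np.unique(labels):
            if lab == labels[i]:
                continue
            other = labels == lab
            if other.any():
                b = min(b, dist[i, other].mean())
        if not np.isfinite(b):
            return -1.0
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def prune_representatives(
    top: pd.DataFrame,
    effect_vectors: dict[tuple[str, str], np.ndarray],
    sig_counts: dict[tuple[str, str], int],
    min_lfsr: dict[tuple[str, str], float] | None = None,
    distance_threshold: float = 0.2,
    k_range: tuple[int, int] = (2, 5),
    centering: str = "vector",
) -> pd.DataFrame:
    """Per-gene pruning of top eQTLs to a representative subset.

    Distances are Euclidean between centered absolute effect vectors.  One
    eQTL: kept.  Two: both kept iff their distance exceeds the threshold,
    else the one significant in more cell types.  Three or more: all kept if
    every pairwise distance exceeds the threshold; otherwise average-linkage
    hierarchical clustering cut at the k in ``k_range`` maximizing the mean
    silhouette width, keeping per cluster the member significant in the most
    cell types (ties: lower minimum LFSR).
    """
    min_lfsr = min_lfsr or {}

    def better(key_a, key_b) -> bool:
        ca, cb = sig_counts.get(key_a, 0), sig_counts.get(key_b, 0)
        if ca != cb:
            return ca > cb
        return min_lfsr.get(key_a, 1.0) < min_lfsr.get(key_b, 1.0)

    keep_rows = []
    for gene, grp in top.groupby("gene", sort=False):
        uniq_snps = list(dict.fromkeys(grp["snp"]))
        keys = [(gene, s) for s in uniq_snps]
        if len(keys) == 1:
            keep_rows.append((gene, uniq_snps[0]))
            continue
        if centering == "condition":
            stack = np.vstack([np.abs(effect_vectors[k]) for k in keys])
            cmean = stack.mean(axis=0)
            vecs = [np.abs(effect_vectors[k]) - cmean for k in keys]
        else:
            vecs = [_centered_abs(effect_vectors[k]) for k in keys]
        m = len(keys)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dist[i, j] = dist[j, i] = float(np.linalg.norm(vecs[i] - vecs[j]))
        if m == 2:
            if dist[0, 1] > distance_threshold:
                keep_rows.extend([(gene, s) for s in uniq_snps])
            else:
                winner = keys[0] if better(keys[0], keys[1]) else keys[1]
                keep_rows.append((gene, winner[1]))
            continue
        offdiag = dist[np.triu_indices(m, 1)]
        if (offdiag > distance_threshold).all():
            keep_rows.extend([(gene, s) for s in uniq_snps])
            continue
        z = linkage(squareform(dist, checks=False), method="average")
        lo, hi = k_range
        hi = min(hi, m - 1)
        lo = min(lo, hi)
        best_labels, best_sil = None, -np.inf
        for k in range(lo, hi + 1):
            labels = fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil = _mean_silhouette(dist, labels)
            if sil > best_sil:
                best_sil, best_labels = sil, labels
        if best_labels is None:
            best_labels = np.ones(m, dtype=int)
        for lab in np.unique(best_labels):
            members = [keys[i] for i in np.flatnonzero(best_labels == lab)]
            winner = members[0]
            for k2 in members[1:]:
                if better(k2, winner):
                    winner = k2
            keep_rows.append((gene, winner[1]))
    return pd.DataFrame(keep_rows, columns=["gene", "snp"])
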