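"""Cell, gene, and cell-type inclusion filters plus pseudobulk aggregation.

The eQTL-mapping QC rules: cells with more than 20% mitochondrial reads are
removed; genes expressed in fewer than 10% of all cells, with mean count
below 0.1, or on an exclusion list (mitochondrial / ribosomal) are dropped;
a cell type enters mapping only if at least 40 donors contribute at least 5
cells, and donors below 5 cells are excluded per cell type.  Retained counts
are library-size normalized, log2(1+x) transformed, and mean-aggregated to
one value per (donor, cell type, gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkTensor:
    """Per-cell-type donor x gene pseudobulk plus per-donor cell counts."""

    expr: dict[str, pd.DataFrame]  # cell type -> donor x gene mean log2 expression
    ncells: pd.DataFrame  # donor x cell type counts (0 where donor excluded)
    donor_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def celltypes(self) -> list[str]:
        return list(self.expr)

    def genes(self) -> list[str]:
        first = next(iter(self.expr.values()))
        return list(first.columns)

    def donors(self, celltype: str) -> list[str]:
        return list(self.expr[celltype].index)


def filter_cells(cells: pd.DataFrame, mito_max: float = 0.20) -> pd.DataFrame:
    """Remove cells whose mitochondrial read fraction exceeds ``mito_max``.

    The boundary is kept: a cell at exactly ``mito_max`` survives ("more
    than" is removed).  Order is preserved.
    """
    if not 0.0 < mito_max <= 1.0:
        raise ValueError(f"mito_max must be in (0, 1], got {mito_max}")
    if cells.empty:
        raise ValueError("cell table is empty")
    keep = cells["mito_fraction"] <= mito_max
    out = cells.loc[keep]
    logger.info("filter_cells: %d of %d cells retained", len(out), len(cells))
    if out.empty:
        logger.warning("filter_cells removed every cell (mito_max=%g)", mito_max)
    return out


def filter_genes(
    counts: np.ndarray,
    gene_ids: list[str],
    min_frac_cells: float = 0.10,
    min_mean_count: float = 0.1,
    exclude: set[str] | None = None,
) -> list[str]:
    """Gene inclusion filter, computed over ALL cells in the study.

    Keeps genes detected (count > 0) in at least ``min_frac_cells`` of cells
    AND with mean count across all cells at least ``min_mean_count`` AND not
    on the exclusion list.
    """
    if len(gene_ids) == 0:
        raise ValueError("empty gene universe")
    counts = np.asarray(counts)
    n_cells = counts.shape[1]
    if n_cells == 0:
        raise ValueError("no cells available for gene filtering")
    frac = (counts > 0).sum(axis=1) / n_cells
    mean = counts.mean(axis=1)
    exclude = exclude or set()
    kept = [
        g
        for i, g in enumerate(gene_ids)
        if frac[i] >= min_frac_cells and mean[i] >= min_mean_count and g not in exclude
    ]
    logger.info("filter_genes: %d of %d genes retained", len(kept), len(gene_ids))
    return kept


def select_celltypes(
    ncells: pd.DataFrame,
    min_donors: int = 40,
    min_cells: int = 5,
) -> dict[str, list[str]]:
    """Cell types eligible for eQTL mapping and their qualifying donors.

    A cell type is retained when at least ``min_donors`` donors have at
    least ``min_cells`` cells of it; within a retained cell type, only those
    donors are kept.  Returns {cell type: [donor ids]}.
    """
    out: dict[str, list[str]] = {}
    for ct in ncells.columns:
        ok = ncells.index[ncells[ct] >= min_cells].tolist()
        if len(ok) >= min_donors:
            out[ct] = ok
    logger.info(
        "select_celltypes: %d of %d cell types retained", len(out), ncells.shape[1]
    )
    if not out:
        logger.warning("no cell type met the %d-donor / %d-cell criterion", min_donors, min_cells)
    return out


def normalize_aggregate(
    counts: np.ndarray,
    cells: pd.DataFrame,
    gene_ids: list[str],
    keep_genes: list[str],
    celltype_donors: dict[str, list[str]],
    donor_meta: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
) -> PseudobulkTensor:
    """Library-size normalize, log2-transform, and mean-aggregate per donor.

    Within each retained cell type, per-cell size factors are the cell's
    total count divided by the median total count of that cell type's cells
    (cells with zero depth get factor 1).  Normalized counts are
    log2(pseudocount + x) transformed and averaged over each donor's cells.
    """
    counts = np.asarray(counts, dtype=float)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = [gene_pos[g] for g in keep_genes]
    expr: dict[str, pd.DataFrame] = {}
    nc_cols: dict[str, pd.Series] = {}
    for ct, donors in celltype_donors.items():
        in_ct = cells.index[(cells["cell_type"] == ct) & cells["donor_id"].isin(donors)]
        sub = counts[np.ix_(rows, cells.index.get_indexer(in_ct))]
        depth = sub.sum(axis=0)
        med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
        sf = np.where(depth > 0, depth / med, 1.0)
        logx = np.log2(pseudocount + sub / sf)
        donor_of = cells.loc[in_ct, "donor_id"].to_numpy()
        mat = np.full((len(donors), len(keep_genes)), np.nan)
        ncounts = np.zeros(len(donors), dtype=int)
        kept_donors = []
        for di, d in enumerate(donors):
            cols = donor_of == d
            if not cols.any():
                logger.info("normalize_aggregate: donor %s has no retained %s cells", d, ct)
                continue
            mat[di] = logx[:, cols].mean(axis=1)
            ncounts[di] = int(cols.sum())
            kept_donors.append(di)
        mat = mat[kept_donors]
        expr[ct] = pd.DataFrame(mat, index=[donors[i] for i in kept_donors], columns=keep_genes)
        nc_cols[ct] = pd.Series(
            ncounts[kept_donors], index=[donors[i] for i in kept_donors]
        )
    all_donors = sorted({d for s in nc_cols.values() for d in s.index})
    ncells = pd.DataFrame(0, index=all_donors, columns=list(expr))
    for ct, s in nc_cols.items():
        ncells.loc[s.index, ct] = s
    meta = donor_meta if donor_meta is not None else pd.DataFrame()
    return PseudobulkTensor(expr=expr, ncells=ncells, donor_meta=meta)


def aggregate_cohort(
    counts: np.ndarray,
    cells: pd.DataFrame,
    gene_ids: list[str],
    donor_meta: pd.DataFrame | None = None,
    mito_max: float = 0.20,
    min_frac_cells: float = 0.10,
    min_mean_count: float = 0.1,
    exclude_genes: set[str] | None = None,
    min_donors: int = 40,
    min_cells: int = 5,
) -> PseudobulkTensor:
    """Full QC + aggregation: cell filter, gene filter, cell-type selection,
    then normalized mean-aggregation.  ``counts`` is genes x cells, aligned
    with ``cells`` rows."""
    cells = cells.reset_index(drop=True)
    kept_cells = filter_cells(cells, mito_max=mito_max)
    sub_counts = np.asarray(counts)[:, kept_cells.index.to_numpy()]
    kept_cells = kept_cells.reset_index(drop=True)
    keep_genes = filter_genes(
        sub_counts,
        gene_ids,
        min_frac_cells=min_frac_cells,
        min_mean_count=min_mean_count,
        exclude=exclude_genes,
    )
    ncells = (
        kept_cells.groupby(["donor_id", "cell_type"], sort=False)
        .size()
        .unstack(fill_value=0)
    )
    ct_donors = select_celltypes(ncells, min_donors=min_donors, min_cells=min_cells)
    return normalize_aggregate(
        sub_counts, kept_cells, gene_ids, keep_genes, ct_donors, donor_meta=donor_meta
    )
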