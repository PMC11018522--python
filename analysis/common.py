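"""Shared setup for the numbered analysis scripts.

All scripts operate on the same deterministic synthetic cohort (the default
``SimConfig``: 60 donors, 5 cell types, 300 genes x 20 cis-SNPs, 30% eQTL
genes, 10% interaction genes) and write their outputs under ``results/``.
Early stages are cheap and recomputed on demand; expensive stage outputs
(association tables) are written once and read back by later scripts.
"""

from __future__ import annotations

import logging
from pathlib import Path

from sceqtl import genotypes, qc, synthdata
from sceqtl.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")


def config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.coloc_min_shared = 15  # synthetic cis blocks carry 20 SNPs
    return cfg


def cohort(cfg: PipelineConfig | None = None):
    cfg = cfg or config()
    return synthdata.simulate_cohort(cfg.sim)


def prepared(cfg: PipelineConfig | None = None):
    """Cohort + QC'd pseudobulk + filtered genotypes + kinship + cis index."""
    cfg = cfg or config()
    coh = cohort(cfg)
    pb = qc.aggregate_cohort(
        coh.counts, coh.cells, list(coh.genes["gene_id"]),
        donor_meta=coh.donor_meta,
        mito_max=cfg.mito_max,
        min_frac_cells=cfg.gene_min_frac_cells,
        min_mean_count=cfg.gene_min_mean_count,
        min_donors=cfg.celltype_min_donors,
        min_cells=cfg.celltype_min_cells,
    )
    g = coh.genotypes
    gf = g.subset_snps(genotypes.filter_variants(g, maf_min=cfg.maf_min, hwe_alpha=cfg.hwe_alpha))
    kin = genotypes.make_grm(gf)
    cis = genotypes.cis_index(coh.genes, gf.snp_meta, window=cfg.cis_window)
    return coh, pb, gf, kin, cis
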