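"""End-to-end orchestration: simulate -> QC -> genotype QC -> association ->
shrinkage -> classification -> interaction -> colocalization -> enrichment.

Each stage writes its outputs (plain TSV/JSON) and a small manifest (row
counts, seed) into the run directory; the resolved configuration is written
beside the outputs so a run can be reproduced from it alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, classify, enrich, io, qc, shrinkage, synthdata
from .config import PipelineConfig
from .genotypes import cis_index, filter_variants, ld_prune, make_grm

logger = logging.getLogger(__name__)


def _manifest(run_dir: Path, stage: str, **info) -> None:
    path = run_dir / "manifests" / f"{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    info["stage"] = stage
    info["time"] = time.time()
    path.write_text(json.dumps(info, indent=2, default=str))


def interaction_analysis(
    pb: qc.PseudobulkTensor,
    g,
    cis,
    disease: pd.Series,
    kinship,
    cfg: PipelineConfig,
    seed: int = 0,
) -> dict:
    """Interaction-eQTL scan + shrinkage + two-tier significance.

    Returns the association table, the effect panel on the interaction
    coefficients, the LFSR matrix, the significance matrix, and the number
    of significant (gene, SNP, cell type) interaction eQTLs.
    """
    spec = assoc.AssocModelSpec(
        n_expr_pcs=cfg.n_expr_pcs, min_donors=cfg.celltype_min_donors
    )
    table = assoc.map_interaction(
        pb, g, cis, disease,
        kinship=kinship, spec=spec,
        min_donors_per_group=cfg.interaction_min_donors_per_group,
        maf_per_group_min=cfg.interaction_maf_per_group,
    )
    if table.empty:
        return {"table": table, "panel": None, "lfsr": None, "sig": None, "n_significant": 0}
    panel = shrinkage.panel_from_assoc(table, beta_col="beta_int", se_col="se_int")
    fit, mean, sd, lfsr = shrinkage.mash_pipeline(
        panel,
        n_pcs=cfg.mash_n_pcs,
        ed_iters=cfg.mash_ed_iters,
        strong_lfsr=cfg.mash_strong_lfsr,
        subset_size=cfg.mash_subset_size,
        seed=seed,
    )
    sig = classify.call_significance(lfsr, cfg.lfsr_primary, cfg.lfsr_secondary)
    # only count conditions where the test was actually measured
    sig = sig & panel.observed()
    return {
        "table": table,
        "panel": panel,
        "fit": fit,
        "post_mean": mean,
        "post_sd": sd,
        "lfsr": lfsr,
        "sig": sig,
        "n_significant": int(sig.sum()),
    }


def run_pipeline(cfg: PipelineConfig, run_dir) -> dict:
    """Execute every stage on a (simulated) cohort; returns key results."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.write(run_dir / "config.yaml")
    results: dict = {}

    # --- simulate ---------------------------------------------------------
    cohort = synthdata.simulate_cohort(cfg.sim)
    io.write_table(cohort.truth, run_dir / "truth.tsv")
    _manifest(run_dir, "simulate", n_donors=cfg.sim.n_donors, n_cells=len(cohort.cells), seed=cfg.sim.seed)
    results["cohort"] = cohort

    # --- QC + pseudobulk --------------------------------------------------
    pb = qc.aggregate_cohort(
        cohort.counts, cohort.cells, list(cohort.genes["gene_id"]),
        donor_meta=cohort.donor_meta,
        mito_max=cfg.mito_max,
        min_frac_cells=cfg.gene_min_frac_cells,
        min_mean_count=cfg.gene_min_mean_count,
        min_donors=cfg.celltype_min_donors,
        min_cells=cfg.celltype_min_cells,
    )
    io.write_pseudobulk(pb, run_dir / "pseudobulk")
    _manifest(run_dir, "qc", celltypes=len(pb.celltypes), genes=len(pb.genes()) if pb.celltypes else 0)
    results["pseudobulk"] = pb
    if not pb.celltypes:
        raise RuntimeError("stage qc: no cell type passed the inclusion filters")

    # --- genotype QC ------------------------------------------------------
    g = cohort.genotypes
    mask = filter_variants(g, maf_min=cfg.maf_min, hwe_alpha=cfg.hwe_alpha)
    g_f = g.subset_snps(mask)
    keep = ld_prune(g_f, cfg.ld_window, cfg.ld_step, cfg.ld_r2_max)
    g_pruned = g_f.subset_snps(keep)
    kinship = make_grm(g_pruned)
    cis = cis_index(cohort.genes, g_f.snp_meta, window=cfg.cis_window)
    _manifest(run_dir, "genotypes", snps_in=g.n_snps, snps_filtered=int(mask.sum()), snps_pruned=int(keep.sum()))
    results.update({"genotypes": g_f, "kinship": kinship, "cis": cis})

    # --- cis association --------------------------------------------------
    spec = assoc.AssocModelSpec(n_expr_pcs=cfg.n_expr_pcs, min_donors=cfg.celltype_min_donors)
    table = assoc.map_cis(pb, g_f, cis, kinship=kinship, spec=spec)
    io.write_table(table, run_dir / "assoc_cis.tsv.gz")
    _manifest(run_dir, "map", n_tests=len(table))
    results["assoc"] = table
    if table.empty:
        raise RuntimeError("stage map: no cis association could be tested")

    # --- shrinkage --------------------------------------------------------
    panel = shrinkage.panel_from_assoc(table)
    fit, post_mean, post_sd, lfsr = shrinkage.mash_pipeline(
        panel, n_pcs=cfg.mash_n_pcs, ed_iters=cfg.mash_ed_iters,
        strong_lfsr=cfg.mash_strong_lfsr, subset_size=cfg.mash_subset_size,
        seed=cfg.seed,
    )
    _manifest(run_dir, "mash", n_tests=panel.n_tests, n_conditions=panel.n_conditions)
    results.update({"panel": panel, "mash_fit": fit, "post_mean": post_mean, "post_sd": post_sd, "lfsr": lfsr})

    # --- significance / classification ------------------------------------
    sig = classify.call_significance(lfsr, cfg.lfsr_primary, cfg.lfsr_secondary) & panel.observed()
    snp_pos = dict(zip(g_f.snp_meta["id"], g_f.snp_meta["pos"]))
    top = classify.select_top(panel.ids, lfsr, sig, post_mean, panel.conditions, snp_pos=snp_pos)
    io.write_table(top, run_dir / "top_eqtls.tsv")
    # classification of top eQTL tests
    test_key = panel.ids["gene"].astype(str) + "|" + panel.ids["snp"].astype(str)
    row_of = {k: i for i, k in enumerate(test_key)}
    top_tests = sorted({f"{r.gene}|{r.snp}" for r in top.itertuples()})
    tidx = np.array([row_of[k] for k in top_tests], dtype=int)
    labels = classify.classify_all(sig[tidx], buffer=cfg.global_buffer) if tidx.size else np.array([])
    sharing = classify.pairwise_sharing(
        panel.ids.iloc[tidx], post_mean[tidx], sig[tidx], panel.conditions, factor=cfg.sharing_factor
    ) if tidx.size else pd.DataFrame()
    io.write_table(sharing.reset_index(), run_dir / "sharing.tsv")
    label_table = pd.DataFrame(
        {"test": top_tests, "label": labels}
    )
    io.write_table(label_table, run_dir / "eqtl_classes.tsv")
    _manifest(run_dir, "classify", n_top=len(top), n_global=int((labels == "global").sum()) if tidx.size else 0)
    results.update({"sig": sig, "top": top, "labels": label_table, "sharing": sharing})

    # --- interaction ------------------------------------------------------
    disease = cohort.donor_meta.set_index("donor_id")["disease_status"]
    inter = interaction_analysis(pb, g_f, cis, disease, kinship, cfg, seed=cfg.seed)
    if not inter["table"].empty:
        io.write_table(inter["table"], run_dir / "assoc_interaction.tsv.gz")
    _manifest(run_dir, "interact", n_tests=len(inter["table"]), n_significant=inter["n_significant"])
    results["interaction"] = inter

    # --- colocalization ---------------------------------------------------
    coloc_rows = []
    eqtl_genes = [gn for gn in pd.unique(top["gene"])][:10] if not top.empty else []
    snp_meta_idx = g_f.snp_meta.set_index("id")
    from .coloc import colocalize_gene

    for gene in eqtl_genes:
        sub = table[table["gene"] == gene]
        cts = pd.unique(sub["cell_type"])
        gwas = synthdata.simulate_gwas_stats(
            cohort, gene, n_individuals=1000, shared=True, seed=cfg.seed + 7
        )
        for ct in cts:
            stats_ct = sub[sub["cell_type"] == ct]
            estats = pd.DataFrame(
                {
                    "snp": stats_ct["snp"],
                    "chrom": snp_meta_idx.loc[stats_ct["snp"], "chrom"].to_numpy(),
                    "pos": snp_meta_idx.loc[stats_ct["snp"], "pos"].to_numpy(),
                    "effect_allele": snp_meta_idx.loc[stats_ct["snp"], "alt"].to_numpy(),
                    "other_allele": snp_meta_idx.loc[stats_ct["snp"], "ref"].to_numpy(),
                    "beta": stats_ct["beta"].to_numpy(),
                    "se": stats_ct["se"].to_numpy(),
                }
            )
            res = colocalize_gene(
                estats, gwas, min_shared=cfg.coloc_min_shared,
                p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12,
            )
            if res is not None:
                coloc_rows.append((gene, ct, *res.pp, res.n_shared_snps))
    coloc_table = pd.DataFrame(
        coloc_rows, columns=["gene", "cell_type", "pp0", "pp1", "pp2", "pp3", "pp4", "n_shared_snps"]
    )
    io.write_table(coloc_table, run_dir / "coloc.tsv")
    _manifest(run_dir, "coloc", n_results=len(coloc_table))
    results["coloc"] = coloc_table

    # --- enrichment / DE --------------------------------------------------
    de = enrich.de_by_disease(cohort.counts, cohort.cells, list(cohort.genes["gene_id"]))
    io.write_table(de, run_dir / "de.tsv.gz")
    if inter["sig"] is not None and inter["n_significant"] > 0:
        ip = inter["panel"]
        rows = []
        for r in range(len(ip.conditions)):
            for t in np.flatnonzero(inter["sig"][:, r]):
                rows.append((ip.conditions[r], ip.ids["gene"].iat[t]))
        int_egenes = pd.DataFrame(rows, columns=["cell_type", "gene"]).drop_duplicates()
        overlap = enrich.int_egene_overlap(de, int_egenes, de_alpha=cfg.de_alpha)
        io.write_table(overlap, run_dir / "int_egene_overlap.tsv")
        results["int_overlap"] = overlap
    _manifest(run_dir, "enrich", n_de=len(de))
    results["de"] = de
    return results
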