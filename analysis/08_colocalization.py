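#!/usr/bin/env python
"""Colocalization of cell-type eQTL signals with synthetic GWAS traits.

For each of a handful of planted eQTL genes, simulates one GWAS whose
causal variant is shared with the eQTL and one whose causal variant is a
different SNP of the block, then computes PP0..PP4 per cell type.  A shared
causal variant should drive PP4 toward 1; a distinct one should favor PP3.
Writes results/coloc.tsv.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, config, prepared

from sceqtl import io, synthdata
from sceqtl.coloc import colocalize_gene


def main() -> None:
    cfg = config()
    coh, pb, gf, kin, cis = prepared(cfg)
    table = io.read_table(RESULTS / "assoc_cis.tsv.gz")
    meta = gf.snp_meta.set_index("id")
    # strongest planted eQTL genes make clean colocalization examples
    strong = (coh.truth[coh.truth["true_beta"].abs() > 0.8]
              .drop_duplicates("gene").head(6)["gene"].tolist())
    rows = []
    for gene in strong:
        sub = table[table["gene"] == gene]
        if sub.empty:
            continue
        for shared in (True, False):
            gwas = synthdata.simulate_gwas_stats(coh, gene, n_individuals=2000,
                                                 shared=shared, seed=cfg.seed + 13)
            for ct, stats_ct in sub.groupby("cell_type"):
                estats = pd.DataFrame({
                    "snp": stats_ct["snp"],
                    "chrom": meta.loc[stats_ct["snp"], "chrom"].to_numpy(),
                    "pos": meta.loc[stats_ct["snp"], "pos"].to_numpy(),
                    "effect_allele": meta.loc[stats_ct["snp"], "alt"].to_numpy(),
                    "other_allele": meta.loc[stats_ct["snp"], "ref"].to_numpy(),
                    "beta": stats_ct["beta"].to_numpy(),
                    "se": stats_ct["se"].to_numpy(),
                })
                res = colocalize_gene(estats, gwas, min_shared=cfg.coloc_min_shared,
                                      p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12)
                if res is not None:
                    rows.append((gene, ct, shared, *res.pp, res.n_shared_snps))
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "shared_causal",
                                      "pp0", "pp1", "pp2", "pp3", "pp4", "n_shared_snps"])
    io.write_table(out, RESULTS / "coloc.tsv")
    called = out[out["pp4"] >= cfg.coloc_pp4_call]
    print(f"{len(out)} gene/cell-type colocalization tests")
    for shared, grp in out.groupby("shared_causal"):
        print(f"  shared_causal={shared}: median PP4 {grp['pp4'].median():.3f}, "
              f"median PP3 {grp['pp3'].median():.3f}")
    print(f"calls at PP4 >= {cfg.coloc_pp4_call}: {len(called)} "
          f"({(called['shared_causal']).mean():.0%} with a truly shared variant)")


if __name__ == "__main__":
    main()
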