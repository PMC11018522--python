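#!/usr/bin/env python
"""Significance calling, top eQTLs, pairwise sharing, classification.

Applies the two-tier LFSR rule (0.05 anchor, 0.1 secondary), selects top
eQTLs per gene per cell type, computes the factor-0.5 pairwise sharing
matrix, labels eQTLs global/multi/unique, and prunes representatives for
visualization.  Outputs under results/.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, config, prepared

from sceqtl import classify, io, shrinkage


def main() -> None:
    cfg = config()
    coh, pb, gf, kin, cis = prepared(cfg)
    table = io.read_table(RESULTS / "assoc_cis.tsv.gz")
    post = io.read_table(RESULTS / "posterior.tsv.gz")
    panel = shrinkage.panel_from_assoc(table)
    lf = post.pivot_table(index=["gene", "snp"], columns="cell_type", values="lfsr")
    pm = post.pivot_table(index=["gene", "snp"], columns="cell_type", values="post_mean")
    lf = lf.reindex(pd.MultiIndex.from_frame(panel.ids))
    pm = pm.reindex(lf.index)
    lfsr = np.nan_to_num(lf.to_numpy(), nan=1.0)
    betas = np.nan_to_num(pm.to_numpy(), nan=0.0)
    sig = classify.call_significance(lfsr, cfg.lfsr_primary, cfg.lfsr_secondary)
    snp_pos = dict(zip(gf.snp_meta["id"], gf.snp_meta["pos"]))
    top = classify.select_top(panel.ids, lfsr, sig, betas, list(lf.columns), snp_pos=snp_pos)
    io.write_table(top, RESULTS / "top_eqtls.tsv")
    egenes = top["gene"].nunique()
    print(f"significant top eQTLs: {len(top)}; eGenes: {egenes}")
    key = {(r.gene, r.snp): i for i, r in enumerate(panel.ids.itertuples())}
    tidx = sorted({key[(r.gene, r.snp)] for r in top.itertuples()})
    labels = classify.classify_all(sig[tidx], buffer=cfg.global_buffer)
    counts = pd.Series(labels).value_counts()
    print("classification of top eQTL tests:")
    print(counts.to_string())
    sharing = classify.pairwise_sharing(panel.ids.iloc[tidx], betas[tidx], sig[tidx],
                                        list(lf.columns), factor=cfg.sharing_factor)
    io.write_table(sharing.reset_index(), RESULTS / "sharing.tsv")
    off = sharing.to_numpy()[~np.eye(len(sharing), dtype=bool)]
    print(f"median pairwise sharing: {np.nanmedian(off):.1%}")
    # truth-based sanity: planted global effects should rarely be 'unique'
    truth_patterns = coh.truth.drop_duplicates(["gene", "snp"]).set_index(["gene", "snp"])["pattern_label"]
    hits = [(panel.ids["gene"].iat[i], panel.ids["snp"].iat[i]) for i in tidx]
    planted = [truth_patterns.get(h) for h in hits]
    n_planted = sum(p is not None for p in planted)
    print(f"top eQTL tests at planted causal SNPs: {n_planted} of {len(hits)}")


if __name__ == "__main__":
    main()
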