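#!/usr/bin/env python
"""Cell/gene/cell-type QC and pseudobulk aggregation.

Applies the mitochondrial-fraction cell filter, the 10%-of-cells / mean-0.1
gene filters and the 40-donor / 5-cell cell-type inclusion rule, then
normalizes and mean-aggregates to donor x gene pseudobulk per cell type
(written under results/pseudobulk/).
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, config, prepared

from sceqtl import io


def main() -> None:
    cfg = config()
    coh, pb, gf, kin, cis = prepared(cfg)
    paths = io.write_pseudobulk(pb, RESULTS / "pseudobulk")
    print(f"retained cell types: {pb.celltypes}")
    print(f"retained genes: {len(pb.genes())} of {cfg.sim.n_genes}")
    for ct in pb.celltypes:
        print(f"  {ct}: {pb.expr[ct].shape[0]} donors, "
              f"median nCells {pb.ncells[ct][pb.ncells[ct] > 0].median():.0f}")
    print(f"pseudobulk written to {paths['ncells'].parent}")


if __name__ == "__main__":
    main()
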