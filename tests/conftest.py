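import numpy as np
import pytest

from sceqtl import assoc, genotypes, qc, synthdata


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthdata.SimConfig(
        n_donors=30, n_celltypes=3, n_genes=40, snps_per_gene=10,
        eqtl_fraction=0.3, interaction_fraction=0.1, seed=1,
    )
    return synthdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mapped_cohort():
    """A mid-size cohort taken through QC, genotype QC and cis mapping once."""
    cfg = synthdata.SimConfig(
        n_donors=80, n_celltypes=5, n_genes=60, snps_per_gene=8,
        eqtl_fraction=0.4, effect_size_sd=1.0, interaction_fraction=0.1, seed=3,
    )
    cohort = synthdata.simulate_cohort(cfg)
    pb = qc.aggregate_cohort(
        cohort.counts, cohort.cells, list(cohort.genes["gene_id"]),
        donor_meta=cohort.donor_meta, min_donors=40, min_cells=5,
    )
    g = cohort.genotypes
    mask = genotypes.filter_variants(g)
    gf = g.subset_snps(mask)
    kin = genotypes.make_grm(gf)
    cis = genotypes.cis_index(cohort.genes, gf.snp_meta)
    spec = assoc.AssocModelSpec(n_expr_pcs=10, min_donors=40)
    table = assoc.map_cis(pb, gf, cis, kinship=kin, spec=spec)
    return {
        "cohort": cohort, "pb": pb, "g": gf, "kinship": kin,
        "cis": cis, "table": table,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
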