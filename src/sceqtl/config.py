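"""Pipeline configuration: every stage threshold in one schema-checked place.

Defaults are the study's stated values: mito fraction 0.20, gene filters
10% / mean 0.1, cell-type inclusion 40 donors x 5 cells, MAF > 0.05, HWE
p > 1e-6, LD pruning 250/50/0.9, 20 expression PCs, two-tier LFSR
0.05 / 0.1, sharing factor 0.5, global-classification buffer 2, pruning
distance 0.2 with k in [2, 5], interaction group minimum 10 donors,
colocalization minimum 100 shared SNPs with a PP4 call at 0.6, and a GWAS
risk-variant threshold of 1e-6.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthdata import SimConfig


@dataclass
class PipelineConfig:
    # synthetic cohort (used when no external inputs are given)
    sim: SimConfig = field(default_factory=SimConfig)
    # QC / aggregation
    mito_max: float = 0.20
    gene_min_frac_cells: float = 0.10
    gene_min_mean_count: float = 0.1
    celltype_min_donors: int = 40
    celltype_min_cells: int = 5
    # genotype QC
    maf_min: float = 0.05
    hwe_alpha: float = 1e-6
    ld_window: int = 250
    ld_step: int = 50
    ld_r2_max: float = 0.9
    cis_window: int = 1_000_000
    # association
    n_expr_pcs: int = 20
    interaction_min_donors_per_group: int = 10
    interaction_maf_per_group: float = 0.05
    # shrinkage
    mash_n_pcs: int = 5
    mash_ed_iters: int = 50
    mash_strong_lfsr: float = 0.1
    mash_subset_size: int = 10_000
    # significance / classification
    lfsr_primary: float = 0.05
    lfsr_secondary: float = 0.1
    sharing_factor: float = 0.5
    global_buffer: int = 2
    prune_distance: float = 0.2
    prune_k_min: int = 2
    prune_k_max: int = 5
    # colocalization
    coloc_min_shared: int = 100
    coloc_pp4_call: float = 0.6
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    # enrichment / DE
    gwas_p_threshold: float = 1e-6
    de_alpha: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["maf_range"] = list(d["sim"]["maf_range"])
        d["sim"]["sharing_pattern_probs"] = list(d["sim"]["sharing_pattern_probs"])
        d["sim"]["cells_per_donor_dist"] = list(d["sim"]["cells_per_donor_dist"])
        return d

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_data = data.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        for key in ("maf_range", "sharing_pattern_probs", "cells_per_donor_dist"):
            if key in sim_data:
                sim_data[key] = tuple(sim_data[key])
        return cls(sim=SimConfig(**sim_data), **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
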