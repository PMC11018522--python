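"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 (GT field, 1-based positions) for genotypes, MatrixMarket MTX plus
features/cell-metadata TSVs for single-cell counts, BED (0-based half-open)
for gene bodies, and TSV for pseudobulk, association tables, truth tables
and GWAS summary statistics.  All text formats are gzip-capable via the
``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t") if "b" not in mode else gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> Path:
    """Write dosages as a VCF v4.2 with GT-only genotype fields."""
    path = Path(path)
    with _opener(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.donors) + "\n")
        for j, row in enumerate(g.snp_meta.itertuples()):
            gts = []
            for d in g.dosage[:, j]:
                gts.append("./." if np.isnan(d) else _GT_STRING[int(d)])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read GT fields into a dosage matrix; multiallelic records are dropped."""
    from cyvcf2 import VCF  # htslib-backed; handles plain and gzipped VCF

    path = Path(path)
    vcf = VCF(str(path))
    donors = list(vcf.samples)
    metas = []
    rows = []
    n_multi = 0
    for record_no, variant in enumerate(vcf, 1):
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        dose = []
        for gt in variant.genotypes:
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                dose.append(np.nan)
            else:
                dose.append(float(sum(alleles)))
        if len(dose) != len(donors):
            raise ValueError(f"{path}: record {record_no} has a malformed GT column")
        metas.append(
            (variant.ID or f"{variant.CHROM}:{variant.POS}", variant.CHROM,
             int(variant.POS), variant.REF, variant.ALT[0])
        )
        rows.append(dose)
    vcf.close()
    if n_multi:
        logger.info("read_vcf: dropped %d multiallelic records", n_multi)
    snp_meta = pd.DataFrame(metas, columns=["id", "chrom", "pos", "ref", "alt"])
    dosage = np.asarray(rows, dtype=float).T if rows else np.zeros((len(donors), 0))
    return GenotypeMatrix(dosage=dosage, donors=donors, snp_meta=snp_meta)


# ---------------------------------------------------------------------------
# MTX + metadata

def write_mtx(counts: np.ndarray, cells: pd.DataFrame, gene_ids: list[str], out_dir) -> dict[str, Path]:
    """Write genes x cells counts as MTX with features and cell-metadata TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "cells": out_dir / "cells.tsv",
    }
    mmwrite(str(paths["mtx"]), sparse.csr_matrix(np.asarray(counts)))
    pd.Series(gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_mtx(out_dir) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    out_dir = Path(out_dir)
    counts = np.asarray(mmread(str(out_dir / "matrix.mtx")).todense())
    gene_ids = pd.read_csv(out_dir / "features.tsv", sep="\t", header=None)[0].tolist() if counts.shape[0] else []
    cells = pd.read_csv(out_dir / "cells.tsv", sep="\t")
    return counts, cells, gene_ids


# ---------------------------------------------------------------------------
# BED and tables

BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def write_bed(genes: pd.DataFrame, path) -> Path:
    """Genes as 6-column BED (0-based half-open starts)."""
    path = Path(path)
    out = genes.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    out.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, dtype={"chrom": str})
    return df[["chrom", "start", "end", "strand", "gene_id"]]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pseudobulk(pb, out_dir) -> dict[str, Path]:
    """One donors x genes TSV per cell type plus an nCells TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ct, df in pb.expr.items():
        p = out_dir / f"pseudobulk_{ct}.tsv"
        df.to_csv(p, sep="\t")
        paths[ct] = p
    ncp = out_dir / "ncells.tsv"
    pb.ncells.to_csv(ncp, sep="\t")
    paths["ncells"] = ncp
    return paths


# ---------------------------------------------------------------------------
# whole-cohort fixture

def write_cohort(cohort, out_dir) -> dict[str, str]:
    """Serialize a simulated cohort (VCF, MTX set, BED, truth and donor TSVs)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    paths: dict[str, str] = {}
    paths["vcf"] = str(write_vcf(cohort.genotypes, out_dir / "genotypes.vcf"))
    mtx_paths = write_mtx(cohort.counts, cohort.cells, list(cohort.genes["gene_id"]), out_dir / "sc")
    paths.update({k: str(v) for k, v in mtx_paths.items()})
    paths["bed"] = str(write_bed(cohort.genes, out_dir / "genes.bed"))
    paths["truth"] = str(write_table(cohort.truth, out_dir / "truth.tsv"))
    paths["donors"] = str(write_table(cohort.donor_meta, out_dir / "donors.tsv"))
    return paths


def read_cohort_inputs(out_dir) -> dict:
    """Read back a fixture directory into in-memory inputs."""
    out_dir = Path(out_dir)
    g = read_vcf(out_dir / "genotypes.vcf")
    counts, cells, gene_ids = read_mtx(out_dir / "sc")
    genes = read_bed(out_dir / "genes.bed")
    truth = read_table(out_dir / "truth.tsv")
    donors = read_table(out_dir / "donors.tsv")
    return {
        "genotypes": g,
        "counts": counts,
        "cells": cells,
        "gene_ids": gene_ids,
        "genes": genes,
        "truth": truth,
        "donor_meta": donors,
    }
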