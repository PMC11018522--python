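"""Calibration and recovery experiments on synthetic cohorts.

Each experiment simulates a cohort with known ground truth, runs the
relevant pipeline stages, and reports a scalar summary: the
permuted-disease-label false-positive rate of the interaction-eQTL
procedure, the uniformity of association p-values under genotype
shuffling, planted-effect recovery, mixture-weight recovery, sharing-pattern
classification accuracy, and false-sign-rate control of the LFSR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import assoc, classify, genotypes, qc, shrinkage, synthdata
from .config import PipelineConfig
from .pipeline import interaction_analysis

logger = logging.getLogger(__name__)


def _prepare(cfg_sim: synthdata.SimConfig):
    cohort = synthdata.simulate_cohort(cfg_sim)
    pb = qc.aggregate_cohort(
        cohort.counts, cohort.cells, list(cohort.genes["gene_id"]),
        donor_meta=cohort.donor_meta, min_donors=40, min_cells=5,
    )
    g = cohort.genotypes
    gf = g.subset_snps(genotypes.filter_variants(g))
    kin = genotypes.make_grm(gf)
    cis = genotypes.cis_index(cohort.genes, gf.snp_meta)
    return cohort, pb, gf, kin, cis


def interaction_permutation_experiment(
    seed: int,
    n_donors: int = 60,
    n_celltypes: int = 5,
    n_genes: int = 300,
    snps_per_gene: int = 20,
    interaction_fraction: float = 0.10,
    interaction_effect_sd: float = 1.0,
    n_permutations: int = 5,
) -> dict:
    """Disease-label permutation calibration of the interaction-eQTL stage.

    Simulates a cohort with planted genotype x disease interactions, runs the
    full interaction stage (LMM interaction term, multivariate shrinkage,
    two-tier LFSR significance) with the true labels and with donor-level
    permuted labels, and reports the permuted count as a percentage of the
    true-label count.

    At this cohort size a single permutation draw is a high-variance
    estimator of the false-positive rate: with 60 donors, occasional draws
    retain a genotype-weighted correlation with the true labels and leak
    genuine planted interaction signal into the "null" scan.  The permuted
    count is therefore summarized as the median over ``n_permutations``
    independent donor-level permutations.
    """
    sim = synthdata.SimConfig(
        n_donors=n_donors, frac_cases=0.5, n_celltypes=n_celltypes,
        n_genes=n_genes, snps_per_gene=snps_per_gene,
        eqtl_fraction=max(0.3, interaction_fraction),
        interaction_fraction=interaction_fraction,
        interaction_effect_sd=interaction_effect_sd, seed=seed,
    )
    cfg = PipelineConfig(sim=sim, seed=seed)
    cohort, pb, gf, kin, cis = _prepare(sim)
    disease = cohort.donor_meta.set_index("donor_id")["disease_status"]
    res_true = interaction_analysis(pb, gf, cis, disease, kin, cfg, seed=seed)
    n_true = res_true["n_significant"]
    perm_counts = []
    for i in range(1, n_permutations + 1):
        perm = assoc.permute_disease(cohort.donor_meta, seed=seed + i)
        perm_labels = perm.set_index("donor_id")["disease_status"]
        res_perm = interaction_analysis(pb, gf, cis, perm_labels, kin, cfg, seed=seed)
        perm_counts.append(res_perm["n_significant"])
        logger.info("interaction permutation %d/%d: %d significant",
                    i, n_permutations, perm_counts[-1])
    n_perm = float(np.median(perm_counts))
    pct = 100.0 * n_perm / n_true if n_true else float("nan")
    logger.info("interaction permutation: true=%d permuted median=%s of %s (%.2f%%)",
                n_true, n_perm, perm_counts, pct)
    return {
        "n_true": n_true,
        "n_perm": n_perm,
        "perm_counts": perm_counts,
        "n_tests": int(len(res_true["table"])),
        "pct": pct,
    }


def genotype_permutation_experiment(
    seed: int,
    n_donors: int = 100,
    n_genes: int = 550,
    snps_per_gene: int = 20,
) -> np.ndarray:
    """Association p-values after donor-level genotype shuffling.

    LD within blocks is switched off so the returned p-values are
    approximately independent draws, suitable for a Kolmogorov-Smirnov
    uniformity check.
    """
    sim = synthdata.SimConfig(
        n_donors=n_donors, n_celltypes=1, n_genes=n_genes,
        snps_per_gene=snps_per_gene, ld_block_r2=0.0,
        eqtl_fraction=0.3, interaction_fraction=0.0, seed=seed,
    )
    cohort, pb, gf, kin, cis = _prepare(sim)
    g_shuf = assoc.permute_genotypes(gf, seed=seed + 1)
    kin_shuf = genotypes.make_grm(g_shuf)
    spec = assoc.AssocModelSpec(n_expr_pcs=20, min_donors=40)
    table = assoc.map_cis(pb, g_shuf, cis, kinship=kin_shuf, spec=spec)
    return table["p"].to_numpy()


def effect_recovery_experiment(
    seed: int,
    n_donors: int = 150,
    n_genes: int = 200,
) -> dict:
    """Correlation between estimated and planted per-allele effects.

    Planted effects with |beta| >= 0.5 are compared against the mixed-model
    estimates at the causal SNP (one cell type, inverse-normal scale).
    """
    sim = synthdata.SimConfig(
        n_donors=n_donors, n_celltypes=1, n_genes=n_genes, snps_per_gene=5,
        eqtl_fraction=0.6, effect_size_sd=0.8, interaction_fraction=0.0,
        noise_sd=0.5, seed=seed,
    )
    cohort, pb, gf, kin, cis = _prepare(sim)
    spec = assoc.AssocModelSpec(n_expr_pcs=20, min_donors=40)
    table = assoc.map_cis(pb, gf, cis, kinship=kin, spec=spec)
    merged = cohort.truth.merge(table, on=["gene", "snp", "cell_type"])
    strong = merged[np.abs(merged["true_beta"]) >= 0.5]
    r = float(np.corrcoef(strong["true_beta"], strong["beta"])[0, 1])
    return {"correlation": r, "n_effects": int(len(strong))}


def mixture_recovery_experiment(
    seed: int,
    n_tests: int = 10_000,
    n_conditions: int = 5,
    pi_null: float = 0.7,
) -> dict:
    """Two-component weight recovery: pi_null null + (1-pi_null) equal effects."""
    rng = np.random.default_rng(seed)
    sig = rng.random(n_tests) >= pi_null
    b = np.zeros((n_tests, n_conditions))
    b[sig] = rng.standard_normal(int(sig.sum()))[:, None]
    s = 0.3
    bhat = b + s * rng.standard_normal((n_tests, n_conditions))
    panel = shrinkage.EffectPanel(
        bhat=bhat, shat=np.full_like(bhat, s),
        ids=pd.DataFrame({"gene": np.arange(n_tests), "snp": "s"}),
        conditions=[f"c{i}" for i in range(n_conditions)],
    )
    fit = shrinkage.fit_mixture(panel, {"equal": np.ones((n_conditions, n_conditions))}, seed=seed)
    return {"pi_null_true": pi_null, "pi_null_hat": float(fit.pi[0])}


def classification_experiment(
    seed: int,
    n_donors: int = 150,
    n_celltypes: int = 10,
    n_genes: int = 100,
    beta_min: float = 0.8,
) -> dict:
    """Sharing-pattern classification accuracy on strong planted effects.

    The expected label of a planted eQTL is obtained by applying the
    global/multi/unique rule to its true planted cell-type pattern; accuracy
    is the fraction of strong effects whose called label matches.
    """
    sim = synthdata.SimConfig(
        n_donors=n_donors, n_celltypes=n_celltypes, n_genes=n_genes,
        snps_per_gene=5, eqtl_fraction=0.5, effect_size_sd=1.2,
        interaction_fraction=0.0, noise_sd=0.5, seed=seed,
    )
    cohort, pb, gf, kin, cis = _prepare(sim)
    spec = assoc.AssocModelSpec(n_expr_pcs=20, min_donors=40)
    table = assoc.map_cis(pb, gf, cis, kinship=kin, spec=spec)
    panel = shrinkage.panel_from_assoc(table)
    fit, mean, sd, lfsr = shrinkage.mash_pipeline(panel, seed=seed)
    sig = classify.call_significance(lfsr) & panel.observed()
    labels = classify.classify_all(sig, buffer=2)
    key = {(r.gene, r.snp): i for i, r in enumerate(panel.ids.itertuples())}
    correct = total = 0
    for (gene, snp), grp in cohort.truth.groupby(["gene", "snp"]):
        if abs(grp["true_beta"].iat[0]) < beta_min or (gene, snp) not in key:
            continue
        planted = set(grp["cell_type"])
        true_vec = np.array([ct in planted for ct in panel.conditions])
        expected = classify.classify_eqtl(true_vec, buffer=2)
        total += 1
        correct += labels[key[(gene, snp)]] == expected
    acc = correct / total if total else float("nan")
    return {"accuracy": float(acc), "n_strong": int(total)}


def false_sign_rate_experiment(
    seed: int,
    n_tests: int = 6000,
    n_conditions: int = 5,
    alpha: float = 0.05,
) -> dict:
    """Realized wrong-sign-or-null fraction among effects called at LFSR <= alpha."""
    rng = np.random.default_rng(seed)
    sig = rng.random(n_tests) < 0.3
    b = np.zeros((n_tests, n_conditions))
    b[sig] = rng.standard_normal(int(sig.sum()))[:, None]
    s = 0.3
    bhat = b + s * rng.standard_normal((n_tests, n_conditions))
    panel = shrinkage.EffectPanel(
        bhat=bhat, shat=np.full_like(bhat, s),
        ids=pd.DataFrame({"gene": np.arange(n_tests), "snp": "s"}),
        conditions=[f"c{i}" for i in range(n_conditions)],
    )
    fit, mean, sd, lfsr = shrinkage.mash_pipeline(panel, ed_iters=20, seed=seed)
    called = lfsr <= alpha
    n_called = int(called.sum())
    if n_called == 0:
        return {"fsr": 0.0, "n_called": 0, "mc_se": 0.0}
    wrong = ((np.sign(mean) != np.sign(b)) | (b == 0)) & called
    fsr = float(wrong.sum() / n_called)
    mc_se = float(np.sqrt(max(fsr, 1.0 / n_called) * (1 - min(fsr, 1.0)) / n_called))
    return {"fsr": fsr, "n_called": n_called, "mc_se": mc_se}
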