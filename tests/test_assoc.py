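"""Mixed-model association: transforms, REML, Wald tests, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sceqtl import assoc
from sceqtl.assoc import (
    AssocModelSpec,
    fit_null_lmm,
    inverse_normal_transform,
    permute_disease,
    permute_genotypes,
    regress_out_pcs,
)
from sceqtl.assoc import test_snp as snp_wald  # alias: bare name would be collected


class TestInverseNormalTransform:
    def test_three_point_quantiles(self):
        got = inverse_normal_transform(np.array([10.0, 20.0, 30.0]))
        want = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert got[1] == 0.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        y = rng.random(50)
        np.testing.assert_allclose(
            inverse_normal_transform(y), inverse_normal_transform(np.exp(5 * y)), atol=1e-12
        )

    def test_symmetric_ranks_sum_to_zero(self, rng):
        y = rng.standard_normal(101)
        assert inverse_normal_transform(y).sum() == pytest.approx(0.0, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))


class TestRegressOutPcs:
    def test_zero_pcs_returns_centered(self, rng):
        x = rng.standard_normal((20, 5)) + 3.0
        out = regress_out_pcs(x, n_pcs=0)
        np.testing.assert_allclose(out, x - x.mean(axis=0), atol=1e-12)

    def test_full_rank_capture(self, rng):
        # matrix of exact rank 3: residuals vanish with n_pcs=3
        a = rng.standard_normal((30, 3)) @ rng.standard_normal((3, 8))
        out = regress_out_pcs(a, n_pcs=3)
        assert np.abs(out).max() < 1e-8

    def test_residuals_orthogonal_to_pcs(self, rng):
        x = rng.standard_normal((40, 15))
        out = regress_out_pcs(x, n_pcs=5)
        xc = x - x.mean(axis=0)
        u, _, _ = np.linalg.svd(xc, full_matrices=False)
        inner = u[:, :5].T @ out
        assert np.abs(inner).max() < 1e-8

    def test_too_many_pcs_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_out_pcs(rng.standard_normal((10, 5)), n_pcs=10)


class TestNullLmm:
    def test_no_genetic_variance_detected(self, rng):
        # iid phenotype with a realistic (non-identity) kinship: the genetic
        # component should get little weight and the total should match Var(y)
        n = 120
        y = rng.standard_normal(n)
        z = rng.binomial(2, 0.3, size=(n, 500)).astype(float)
        z = (z - z.mean(0)) / z.std(0)
        k = z @ z.T / 500
        fit = fit_null_lmm(y, np.ones((n, 1)), k, None)
        total = fit.sigma2_g + fit.sigma2_e
        assert fit.sigma2_g / total < 0.3
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.3)

    def test_variance_component_recovery(self, rng):
        """Average relative error of (sigma2_g, sigma2_e) over replicates < 20%
        at n = 300 with a strong genetic signal."""
        n = 300
        z = rng.standard_normal((n, 400))
        z = (z - z.mean(0)) / z.std(0)
        k = z @ z.T / 400
        lam, q = np.linalg.eigh(k)
        lam = np.clip(lam, 0, None)
        s2g_true, s2e_true = 2.0, 1.0
        rel_g, rel_e = [], []
        for _ in range(10):
            u = q @ (np.sqrt(lam) * rng.standard_normal(n))
            y = np.sqrt(s2g_true) * u + np.sqrt(s2e_true) * rng.standard_normal(n)
            fit = fit_null_lmm(y, np.ones((n, 1)), k, None)
            rel_g.append((fit.sigma2_g - s2g_true) / s2g_true)
            rel_e.append((fit.sigma2_e - s2e_true) / s2e_true)
        assert abs(np.mean(rel_g)) < 0.2
        assert abs(np.mean(rel_e)) < 0.2

    def test_whitening_makes_covariance_identity(self, rng):
        n = 150
        w = rng.uniform(0.5, 2.0, n)
        k = np.eye(n)
        y = rng.standard_normal(n) * np.sqrt(1 + 0.8 * w)
        fit = fit_null_lmm(y, np.ones((n, 1)), k, w)
        cov = fit.sigma2_g * k + fit.sigma2_w * np.diag(w) + fit.sigma2_e * np.eye(n)
        t = fit.whitening
        np.testing.assert_allclose(t @ cov @ t.T, np.eye(n), atol=1e-8)

    def test_positive_weights_required(self, rng):
        with pytest.raises(ValueError):
            fit_null_lmm(rng.standard_normal(10), np.ones((10, 1)), None, np.zeros(10))


class TestTestSnp:
    def test_equals_ols_when_no_structure(self, rng):
        """K = I and constant weights: beta/se/p match the OLS t-test to 1e-8."""
        n = 60
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.4, n).astype(float)
        c = np.ones((n, 1))
        fit = fit_null_lmm(y, c, np.eye(n), np.full(n, 2.0))
        beta, se, p = snp_wald(y, g, c, fit.whitening)
        x = np.column_stack([c, g])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        s2 = resid @ resid / (n - 2)
        se_ols = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        t_ols = coef[1] / se_ols
        p_ols = 2 * stats.t.sf(abs(t_ols), n - 2)
        assert beta == pytest.approx(coef[1], abs=1e-8)
        assert se == pytest.approx(se_ols, abs=1e-8)
        assert p == pytest.approx(p_ols, abs=1e-8)

    def test_allele_flip_negates_beta(self, rng):
        n = 50
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n).astype(float)
        c = np.ones((n, 1))
        fit = fit_null_lmm(y, c, None, None)
        b1, s1, p1 = snp_wald(y, g, c, fit.whitening)
        b2, s2, p2 = snp_wald(y, 2.0 - g, c, fit.whitening)
        assert b2 == pytest.approx(-b1, abs=1e-10)
        assert s2 == pytest.approx(s1, abs=1e-10)
        assert p2 == pytest.approx(p1, abs=1e-10)

    def test_null_p_values_uniform(self, rng):
        """Type-I error at 0.05 within [0.04, 0.06] over 10^4 null tests."""
        n = 80
        c = np.ones((n, 1))
        fit = fit_null_lmm(rng.standard_normal(n), c, None, None)
        pvals = []
        for _ in range(200):
            y = rng.standard_normal(n)
            for _ in range(50):
                g = rng.binomial(2, 0.3, n).astype(float)
                _, _, p = snp_wald(y, g, c, fit.whitening)
                pvals.append(p)
        pvals = np.asarray(pvals)
        assert 0.04 <= (pvals < 0.05).mean() <= 0.06

    def test_constant_dosage_rejected(self, rng):
        n = 30
        c = np.ones((n, 1))
        fit = fit_null_lmm(rng.standard_normal(n), c, None, None)
        with pytest.raises(ValueError):
            snp_wald(rng.standard_normal(n), np.full(n, 2.0), c, fit.whitening)


class TestMapCis:
    def test_recovers_planted_effects(self, mapped_cohort):
        table = mapped_cohort["table"]
        truth = mapped_cohort["cohort"].truth
        merged = truth.merge(table, on=["gene", "snp", "cell_type"])
        big = merged[np.abs(merged["true_beta"]) >= 0.5]
        assert len(big) >= 10
        r = np.corrcoef(big["true_beta"], big["beta"])[0, 1]
        assert r >= 0.6  # modest cohort; acceptance-scale recovery is checked separately
        # signs agree for strong effects
        assert (np.sign(big["true_beta"]) == np.sign(big["beta"])).mean() > 0.95

    def test_donor_order_invariance(self, mapped_cohort, rng):
        """Shuffling donor rows of the pseudobulk leaves estimates unchanged."""
        pb = mapped_cohort["pb"]
        ct = pb.celltypes[0]
        gene = mapped_cohort["cohort"].truth["gene"].iat[0]
        import copy

        pb2 = copy.copy(pb)
        perm = rng.permutation(len(pb.expr[ct]))
        pb2.expr = dict(pb.expr)
        pb2.expr[ct] = pb.expr[ct].iloc[perm]
        spec = AssocModelSpec(n_expr_pcs=10, min_donors=40)
        t1 = assoc.map_cis(pb, mapped_cohort["g"], mapped_cohort["cis"],
                           kinship=mapped_cohort["kinship"], spec=spec)
        t2 = assoc.map_cis(pb2, mapped_cohort["g"], mapped_cohort["cis"],
                           kinship=mapped_cohort["kinship"], spec=spec)
        a = t1[(t1["gene"] == gene) & (t1["cell_type"] == ct)].set_index("snp")["beta"]
        b = t2[(t2["gene"] == gene) & (t2["cell_type"] == ct)].set_index("snp")["beta"]
        np.testing.assert_allclose(a.to_numpy(), b.loc[a.index].to_numpy(), atol=1e-6)


class TestInteraction:
    def test_group_minimum_enforced(self, mapped_cohort):
        cohort = mapped_cohort["cohort"]
        disease = pd.Series("control", index=cohort.donor_meta["donor_id"])
        disease.iloc[:9] = "ILD"  # 9 cases < 10
        out = assoc.map_interaction(
            mapped_cohort["pb"], mapped_cohort["g"], mapped_cohort["cis"], disease,
            kinship=mapped_cohort["kinship"], spec=AssocModelSpec(n_expr_pcs=5, min_donors=40),
        )
        assert out.empty

    def test_planted_interactions_covered(self):
        """beta_int estimates cover planted interactions for most effects."""
        from sceqtl import genotypes, qc, synthdata

        cfg = synthdata.SimConfig(
            n_donors=150, n_celltypes=1, n_genes=60, snps_per_gene=3,
            eqtl_fraction=0.5, interaction_fraction=0.5,
            interaction_effect_sd=1.0, seed=21,
        )
        cohort = synthdata.simulate_cohort(cfg)
        pb = qc.aggregate_cohort(
            cohort.counts, cohort.cells, list(cohort.genes["gene_id"]),
            donor_meta=cohort.donor_meta, min_donors=40, min_cells=5,
        )
        g = cohort.genotypes
        gf = g.subset_snps(genotypes.filter_variants(g))
        cis = genotypes.cis_index(cohort.genes, gf.snp_meta)
        disease = cohort.donor_meta.set_index("donor_id")["disease_status"]
        out = assoc.map_interaction(
            pb, gf, cis, disease, kinship=genotypes.make_grm(gf),
            spec=AssocModelSpec(n_expr_pcs=10, min_donors=40),
        )
        tr = cohort.truth[cohort.truth["is_interaction"]]
        merged = tr.merge(out, on=["gene", "snp", "cell_type"])
        assert len(merged) >= 15
        # INT compresses the scale; check sign agreement and correlation
        strong = merged[np.abs(merged["true_beta_interaction"]) >= 0.5]
        assert (np.sign(strong["true_beta_interaction"]) == np.sign(strong["beta_int"])).mean() >= 0.9

    def test_per_group_maf_pruning(self, mapped_cohort):
        out = assoc.map_interaction(
            mapped_cohort["pb"], mapped_cohort["g"], mapped_cohort["cis"],
            mapped_cohort["cohort"].donor_meta.set_index("donor_id")["disease_status"],
            kinship=mapped_cohort["kinship"],
            spec=AssocModelSpec(n_expr_pcs=5, min_donors=40),
        )
        if not out.empty:
            assert (out["maf_ild"] > 0.05).all()
            assert (out["maf_control"] > 0.05).all()


class TestPermutations:
    def test_disease_permutation_roundtrip(self, small_cohort):
        meta = small_cohort.donor_meta
        p1 = permute_disease(meta, seed=3)
        assert sorted(p1["disease_status"]) == sorted(meta["disease_status"])
        assert permute_disease(meta, seed=3).equals(p1)  # reproducible

    def test_genotype_permutation_preserves_frequencies(self, small_cohort):
        g = small_cohort.genotypes
        gp = permute_genotypes(g, seed=1)
        np.testing.assert_allclose(g.maf(), gp.maf(), atol=1e-12)
        assert not np.array_equal(g.dosage, gp.dosage)
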