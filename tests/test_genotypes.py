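"""Variant QC: exact HWE test, filters, LD pruning, GRM, cis indexing."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from sceqtl.genotypes import (
    GenotypeMatrix,
    cis_index,
    filter_variants,
    genotype_counts,
    hwe_exact_test,
    ld_prune,
    make_grm,
)


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional HWE distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    probs = {}
    total = Fraction(0)
    for het in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        # multinomial count of genotype configurations x 2^het phasings
        ways = Fraction(
            comb(n, het) * comb(n - het, rare_hom) * 2**het
        )
        probs[het] = ways
        total += ways
    probs = {h: p / total for h, p in probs.items()}
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


def _geno(dosage, chrom="1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    meta = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosage=dosage, donors=[f"d{i}" for i in range(n)], snp_meta=meta)


class TestHweExact:
    def test_monomorphic_site_is_p_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 12) == 1.0

    def test_total_heterozygote_excess_fails(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every genotype table with total <= 30 agrees with the rational oracle."""
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestFilterVariants:
    def test_maf_boundary_is_strict(self):
        # 40 donors, dosages giving exactly MAF 0.05 vs above: 4/80 alleles
        col_at = np.zeros(40)
        col_at[:4] = 1  # MAF 0.05 exactly -> dropped
        col_above = np.zeros(40)
        col_above[:6] = 1  # MAF 0.075 -> kept (HWE fine)
        g = _geno(np.column_stack([col_at, col_above]))
        mask = filter_variants(g)
        assert mask.tolist() == [False, True]

    def test_hwe_failure_dropped(self):
        het = np.ones(60)  # all heterozygous: HWE p << 1e-6
        ok = np.array([0, 1, 2] * 20)
        g = _geno(np.column_stack([het, ok]))
        mask = filter_variants(g)
        assert mask.tolist() == [False, True]

    def test_non_autosomal_dropped_and_idempotent(self, rng):
        dosage = rng.integers(0, 3, size=(50, 4)).astype(float)
        g = _geno(dosage, chrom="X")
        assert not filter_variants(g).any()
        g2 = _geno(dosage, chrom="7")
        mask = filter_variants(g2)
        g_kept = g2.subset_snps(mask)
        assert filter_variants(g_kept).all()  # idempotent


class TestLdPrune:
    def test_duplicate_column_removes_exactly_one(self, rng):
        col = rng.integers(0, 3, size=100).astype(float)
        other = rng.integers(0, 3, size=100).astype(float)
        g = _geno(np.column_stack([col, col, other]))
        keep = ld_prune(g)
        assert keep.sum() == 2
        assert keep[2]

    def test_independent_snps_all_kept(self, rng):
        dosage = rng.binomial(2, 0.5, size=(500, 20)).astype(float)
        assert ld_prune(_geno(dosage)).all()

    def test_no_remaining_pair_above_threshold(self, rng):
        """Brute-force pair scan over the kept set on a correlated toy panel."""
        base = rng.binomial(1, 0.5, size=(200, 1)).astype(float) * 2
        cols = [base[:, 0]]
        for _ in range(9):
            flip = rng.random(200) < 0.15
            new = cols[-1].copy()
            new[flip] = rng.integers(0, 3, size=int(flip.sum()))
            cols.append(new)
        g = _geno(np.column_stack(cols))
        r2_max = 0.9
        keep = ld_prune(g, window_snps=10, step_snps=5, r2_max=r2_max)
        kept = np.flatnonzero(keep)
        x = g.imputed()
        for i, j in itertools.combinations(kept, 2):
            r = np.corrcoef(x[:, i], x[:, j])[0, 1]
            assert r**2 <= r2_max + 1e-9

    def test_window_smaller_than_step_rejected(self, rng):
        g = _geno(rng.integers(0, 3, size=(20, 5)).astype(float))
        with pytest.raises(ValueError):
            ld_prune(g, window_snps=10, step_snps=50)


class TestGrm:
    def test_matches_naive_two_loop_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(5, 8)).astype(float)
        g = _geno(dosage)
        k = make_grm(g).values
        x = dosage.copy()
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        want = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                want[i, j] = sum(z[i, s] * z[j, s] for s in range(8)) / 8
        np.testing.assert_allclose(k, want, atol=1e-10)

    def test_duplicate_donor_has_self_relatedness(self, rng):
        dosage = rng.integers(0, 3, size=(6, 30)).astype(float)
        dosage[1] = dosage[0]
        k = make_grm(_geno(dosage)).values
        assert k[0, 1] == pytest.approx(k[0, 0])

    def test_unrelated_donors_off_diagonal_near_zero(self, rng):
        dosage = rng.binomial(2, 0.3, size=(200, 2000)).astype(float)
        k = make_grm(_geno(dosage)).values
        off = k[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert abs(np.diag(k).mean() - 1.0) < 0.05

    def test_invariant_to_snp_order(self, rng):
        dosage = rng.integers(0, 3, size=(10, 40)).astype(float)
        g1 = _geno(dosage)
        perm = rng.permutation(40)
        g2 = _geno(dosage[:, perm])
        np.testing.assert_allclose(make_grm(g1).values, make_grm(g2).values, atol=1e-12)


class TestCisIndex:
    def _setup(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [1000, 50_000, 1000],
                "end": [2000, 51_000, 3000],
                "strand": ["+", "-", "+"],
                "gene_id": ["g1", "g2", "g3"],
            }
        )
        snps = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(6)],
                "chrom": ["1", "1", "1", "2", "2", "3"],
                "pos": [500, 1500, 60_000, 100, 2500, 1000],
                "ref": "A",
                "alt": "G",
            }
        )
        return genes, snps

    def test_matches_quadratic_oracle(self):
        genes, snps = self._setup()
        window = 1000
        idx = cis_index(genes, snps, window=window)
        for row in genes.itertuples():
            start_1b, end_1b = row.start + 1, row.end
            want = sorted(
                j for j, s in snps.iterrows()
                if s["chrom"] == row.chrom and start_1b - window <= s["pos"] <= end_1b + window
            )
            assert idx[row.gene_id].tolist() == want

    def test_boundary_snp_included(self):
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [999], "end": [2000], "strand": ["+"], "gene_id": ["g"]}
        )
        snps = pd.DataFrame(
            {"id": ["a", "b"], "chrom": ["1", "1"], "pos": [900, 899], "ref": "A", "alt": "G"}
        )
        # gene start (1-based) = 1000; window 100 -> [900, 2100]
        idx = cis_index(genes, snps, window=100)
        assert idx["g"].tolist() == [0]

    def test_other_chromosome_excluded(self):
        genes, snps = self._setup()
        idx = cis_index(genes, snps, window=10_000_000)
        assert 5 not in idx["g1"].tolist()  # s5 is on chromosome 3


def test_genotype_counts_ignores_missing():
    col = np.array([0, 1, 2, np.nan, 1])
    assert genotype_counts(col) == (1, 2, 1)
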