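import numpy as np
import pytest

from sswool.data_io import GenotypeMatrix, PedigreeTable
from sswool.genotype_qc import AlleleFrequencies, allele_frequencies
from sswool.relationships import (
    a_inverse,
    genomic_relationship,
    h_inverse,
    numerator_relationship,
    subset_a22,
    tune_and_blend,
)
from sswool.synthetic_data import SimConfig, simulate_pedigree


def _random_pedigree(n_founders, n_generations, seed):
    cfg = SimConfig(
        n_founders=n_founders,
        n_generations=n_generations,
        target_h2={"T": 0.3},
        phenotypic_variance={"T": 1.0},
        trait_means={"T": 0.0},
        genetic_correlation_targets={},
        phenotyped_sex="both",
        seed=seed,
    )
    return simulate_pedigree(cfg)[0]


class TestNumeratorRelationship:
    def test_unrelated_founders_identity(self):
        ped = PedigreeTable(["a", "b", "c"], [None] * 3, [None] * 3)
        a = numerator_relationship(ped)
        np.testing.assert_array_equal(a.values, np.eye(3))

    def test_trio_expectations(self, trio_pedigree):
        a = numerator_relationship(trio_pedigree).values
        assert a[0, 2] == pytest.approx(0.5)  # sire-offspring
        assert a[1, 2] == pytest.approx(0.5)
        assert a[2, 2] == pytest.approx(1.0)  # unrelated parents -> F=0

    def test_half_sib_mating_inbreeding(self):
        # sire S x (D1, D2) -> half sibs H1, H2; their offspring has F = 1/8
        ped = PedigreeTable(
            ["S", "D1", "D2", "H1", "H2", "O"],
            [None, None, None, "S", "S", "H1"],
            [None, None, None, "D1", "D2", "H2"],
        )
        a = numerator_relationship(ped)
        assert a.values[5, 5] == pytest.approx(1.125)
        assert a.inbreeding[5] == pytest.approx(0.125)

    def test_positive_semidefinite_on_random_pedigrees(self):
        for seed in (1, 2, 3):
            ped = _random_pedigree(30, 3, seed)
            w = np.linalg.eigvalsh(numerator_relationship(ped).values)
            assert w.min() >= -1e-10


class TestAInverse:
    def test_founders_identity(self):
        ped = PedigreeTable(["a", "b"], [None] * 2, [None] * 2)
        np.testing.assert_allclose(a_inverse(ped).toarray(), np.eye(2))

    def test_trio_known_inverse(self, trio_pedigree):
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(a_inverse(trio_pedigree).toarray(), expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_inverse_of_tabular_a(self, seed):
        ped = _random_pedigree(40, 3, seed)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped, a.inbreeding).toarray()
        err = np.abs(a.values @ ainv - np.eye(len(ped))).max()
        assert err < 1e-8


class TestSubsetA22:
    def test_all_genotyped_is_a_itself(self, trio_pedigree):
        a = numerator_relationship(trio_pedigree)
        np.testing.assert_array_equal(subset_a22(a, list(trio_pedigree.animals)), a.values)

    def test_single_founder(self, trio_pedigree):
        a = numerator_relationship(trio_pedigree)
        np.testing.assert_array_equal(subset_a22(a, ["sire"]), np.array([[1.0]]))

    def test_unknown_id_errors(self, trio_pedigree):
        a = numerator_relationship(trio_pedigree)
        with pytest.raises(KeyError):
            subset_a22(a, ["ghost"])


class TestGenomicRelationship:
    def test_single_homozygote_self_relationship(self):
        m = 8
        g = GenotypeMatrix(np.zeros((1, m)), ["x"])
        freqs = AlleleFrequencies(np.full(m, 0.5), np.zeros(m, dtype=bool))
        gm = genomic_relationship(g, freqs)
        # z = -1 per SNP, lambda = 1/(m*0.5): G = m / (m*0.5) = 2
        assert gm.values[0, 0] == pytest.approx(2.0)

    def test_identical_individuals(self, toy_genotypes):
        d = np.vstack([toy_genotypes.dosage[0], toy_genotypes.dosage[0]])
        g = GenotypeMatrix(d, ["a", "b"])
        freqs = AlleleFrequencies(np.full(4, 0.4), np.zeros(4, dtype=bool))
        gm = genomic_relationship(g, freqs)
        assert gm.values[0, 1] == pytest.approx(gm.values[0, 0])
        assert gm.values[0, 1] == pytest.approx(gm.values[1, 1])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, size=50), size=(20, 50)).astype(float)
        g = GenotypeMatrix(d, [f"i{k}" for k in range(20)])
        freqs = allele_frequencies(g)
        gm = genomic_relationship(g, freqs)
        p = freqs.p
        keep = (p > 0) & (p < 1)
        lam = 1.0 / (2 * p[keep] * (1 - p[keep])).sum()
        z = d[:, keep] - 2 * p[keep]
        naive = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                naive[i, j] = (z[i] * z[j]).sum() * lam
        np.testing.assert_allclose(gm.values, naive, atol=1e-10)

    def test_mean_diagonal_near_one_in_hw_panel(self):
        rng = np.random.default_rng(7)
        m, n = 2000, 500
        p = rng.uniform(0.1, 0.9, size=m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        g = GenotypeMatrix(d, [f"i{k}" for k in range(n)])
        gm = genomic_relationship(g, allele_frequencies(g))
        assert np.diag(gm.values).mean() == pytest.approx(1.0, abs=0.02)

    def test_missing_dosages_impute_to_zero_contribution(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 0.0]])
        g = GenotypeMatrix(d, ["a", "b", "c"])
        freqs = AlleleFrequencies(np.array([0.5, 0.25]), np.zeros(2, dtype=bool))
        gm = genomic_relationship(g, freqs)
        assert gm.centered_z[0, 1] == 0.0

    def test_monomorphic_only_is_error(self):
        g = GenotypeMatrix(np.zeros((2, 2)), ["a", "b"])
        freqs = AlleleFrequencies(np.array([0.0, 1.0]), np.zeros(2, dtype=bool))
        with pytest.raises(ValueError):
            genomic_relationship(g, freqs)


class TestTuneAndBlend:
    def _toy(self, seed=8, n=30, m=200):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, size=m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        g = GenotypeMatrix(d, [f"i{k}" for k in range(n)])
        return genomic_relationship(g, allele_frequencies(g))

    def test_fixed_point_when_moments_match(self):
        # G built from external (non-sample) frequencies is PD here
        rng = np.random.default_rng(8)
        b = rng.standard_normal((30, 60)) / np.sqrt(60)
        g = b @ b.T + 0.5 * np.eye(30)
        gw, alpha, beta = tune_and_blend(g, g.copy(), blend_weight=0.95)
        assert alpha == pytest.approx(0.0, abs=1e-10)
        assert beta == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(gw, g, atol=1e-10)

    def test_moments_match_a22_after_tuning(self):
        gm = self._toy(seed=9)
        n = gm.values.shape[0]
        rng = np.random.default_rng(10)
        base = rng.standard_normal((n, n)) * 0.05
        a22 = np.eye(n) * 1.05 + 0.5 * (base + base.T)
        gw, alpha, beta = tune_and_blend(gm, a22, blend_weight=1.0)
        assert np.diag(gw).mean() == pytest.approx(np.diag(a22).mean(), abs=1e-8)
        off = ~np.eye(n, dtype=bool)
        assert gw[off].mean() == pytest.approx(a22[off].mean(), abs=1e-8)

    def test_singular_unblended_matrix_errors(self):
        # more individuals than markers cannot give full-rank ZDZ'
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.5, size=(30, 5)).astype(float)
        g = GenotypeMatrix(d, [f"i{k}" for k in range(30)])
        gm = genomic_relationship(g, allele_frequencies(g))
        with pytest.raises(np.linalg.LinAlgError):
            tune_and_blend(gm, np.eye(30), blend_weight=1.0)


class TestHInverse:
    def test_no_genotyped_equals_a_inverse(self, trio_pedigree):
        ainv = a_inverse(trio_pedigree)
        h = h_inverse(ainv, np.empty((0, 0)), np.empty((0, 0)), [], list(trio_pedigree.animals))
        np.testing.assert_allclose(h.toarray(), ainv.toarray())

    def test_all_genotyped_reduces_to_gw_inverse(self):
        ped = PedigreeTable(["a", "b", "c"], [None] * 3, [None] * 3)
        ainv = a_inverse(ped)
        a22 = np.eye(3)
        rng = np.random.default_rng(12)
        b = rng.standard_normal((3, 3))
        gw = b @ b.T + np.eye(3)
        h = h_inverse(ainv, a22, gw, ["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_allclose(h.toarray(), np.linalg.inv(gw), atol=1e-10)

    def test_block_structure_against_dense_oracle(self):
        ped = _random_pedigree(40, 3, 13)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped, a.inbreeding)
        rng = np.random.default_rng(14)
        genotyped = sorted(rng.choice(ped.animals, size=30, replace=False).tolist())
        a22 = subset_a22(a, genotyped)
        b = rng.standard_normal((30, 30)) * 0.1
        gw = a22 + b @ b.T + 0.05 * np.eye(30)
        h = h_inverse(ainv, a22, gw, genotyped, list(ped.animals))
        # non-genotyped rows/cols equal A^-1 exactly
        gset = set(ped.index_of(genotyped))
        non = [i for i in range(len(ped)) if i not in gset]
        hm, am = h.toarray(), ainv.toarray()
        np.testing.assert_array_equal(hm[np.ix_(non, non)], am[np.ix_(non, non)])
        np.testing.assert_array_equal(hm[non, :][:, sorted(gset)], am[non, :][:, sorted(gset)])
        # genotyped block of H = inv(H^-1) must equal Gw (single-step identity)
        hdense = np.linalg.inv(hm)
        gidx = ped.index_of(genotyped)
        np.testing.assert_allclose(hdense[np.ix_(gidx, gidx)], gw, atol=1e-8)
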