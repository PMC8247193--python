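import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sswool.data_io import GeneAnnotation, GenotypeMatrix, MarkerMap, PhenotypeTable
from sswool.genotype_qc import AlleleFrequencies, allele_frequencies
from sswool.relationships import a_inverse, genomic_relationship, numerator_relationship
from sswool.variance_components import ModelSpec, VarianceComponents, build_design
from sswool.wssgwas import (
    backsolve_snp_effects,
    normalize_weights,
    run_wssgwas,
    solve_mme,
    top_percent_snps,
    top_windows,
    update_weights,
    window_variances,
)
from conftest import small_single_trait_sim


def pedigree_blup_oracle(y, x, z, a, sigma2_a, sigma2_e):
    """Dense GLS: beta = (X'V^-1X)^-1 X'V^-1 y, a_hat = s2a A Z' V^-1 (y - X beta)."""
    v = sigma2_a * z @ a @ z.T + sigma2_e * np.eye(len(y))
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    ahat = sigma2_a * a @ z.T @ vi @ (y - x @ beta)
    return beta, ahat


def _vc(sa=0.3, se=0.7):
    return VarianceComponents(["T"], np.array([[sa]]), np.array([[se]]))


class TestSolveMme:
    def test_matches_dense_gls_oracle_pedigree_only(self):
        cfg, ped, mm, geno, phen, truth = small_single_trait_sim(41, n_founders=50)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped, a.inbreeding)
        vc = _vc()
        sol = solve_mme(ModelSpec(["T"]), phen, ainv, vc, animals=list(ped.animals))
        data = phen.data.loc[phen.data["T"].notna()].reset_index(drop=True)
        x, _ = build_design(data, ["flock", "birth_year", "season"])
        y = data["T"].to_numpy()
        z = np.zeros((len(y), len(ped)))
        z[np.arange(len(y)), ped.index_of(data["animal"])] = 1.0
        beta_o, ahat_o = pedigree_blup_oracle(y, x, z, a.values, vc.sigma2_a, vc.sigma2_e)
        np.testing.assert_allclose(sol.beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(sol.breeding_values.to_numpy(), ahat_o, atol=1e-8)

    def test_shrinkage_limit_gives_ols(self):
        cfg, ped, mm, geno, phen, truth = small_single_trait_sim(42, n_founders=40)
        a = numerator_relationship(ped)
        ainv = a_inverse(ped, a.inbreeding)
        vc = _vc(sa=1e-8, se=1.0)
        sol = solve_mme(ModelSpec(["T"]), phen, ainv, vc, animals=list(ped.animals))
        data = phen.data.loc[phen.data["T"].notna()].reset_index(drop=True)
        x, _ = build_design(data, ["flock", "birth_year", "season"])
        y = data["T"].to_numpy()
        beta_ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.abs(sol.breeding_values.to_numpy()).max() < 1e-4
        np.testing.assert_allclose(sol.beta, beta_ols, atol=1e-4)

    def test_residual_of_normal_equations_small(self):
        cfg, ped, mm, geno, phen, truth = small_single_trait_sim(43, n_founders=40)
        ainv = a_inverse(ped)
        sol = solve_mme(ModelSpec(["T"]), phen, ainv, _vc(), animals=list(ped.animals))
        assert sol.residual_ratio < 1e-8

    def test_nonpositive_variances_rejected(self):
        cfg, ped, mm, geno, phen, truth = small_single_trait_sim(44, n_founders=40)
        ainv = a_inverse(ped)
        with pytest.raises(ValueError):
            solve_mme(ModelSpec(["T"]), phen, ainv, _vc(sa=0.0), animals=list(ped.animals))


class TestBacksolve:
    def _toy(self, seed=45, n=10, m=30):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, size=m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        g = GenotypeMatrix(d, [f"i{k}" for k in range(n)])
        freqs = AlleleFrequencies(p, np.zeros(m, dtype=bool))  # external freqs: G full rank
        return genomic_relationship(g, freqs)

    def test_reconstruction_identity(self):
        gm = self._toy()
        rng = np.random.default_rng(46)
        a_g = rng.standard_normal(10)
        u = backsolve_snp_effects(gm, a_g)
        recon = gm.centered_z @ u
        assert np.abs(recon - a_g).max() < 1e-6

    def test_zero_and_linearity(self):
        gm = self._toy(seed=47)
        assert np.allclose(backsolve_snp_effects(gm, np.zeros(10)), 0.0)
        rng = np.random.default_rng(48)
        a_g = rng.standard_normal(10)
        np.testing.assert_allclose(
            backsolve_snp_effects(gm, 2 * a_g), 2 * backsolve_snp_effects(gm, a_g), atol=1e-10
        )

    def test_variance_preserved_under_identity(self):
        gm = self._toy(seed=49)
        rng = np.random.default_rng(50)
        a_g = rng.standard_normal(10)
        u = backsolve_snp_effects(gm, a_g)
        assert np.var(gm.centered_z @ u, ddof=1) == pytest.approx(np.var(a_g, ddof=1), rel=1e-6)


class TestWeights:
    @pytest.mark.parametrize(
        "u, p, expected",
        [(2.0, 0.5, 2.0), (0.0, 0.3, 0.0), (3.0, 0.0, 0.0)],
    )
    def test_update_examples(self, u, p, expected):
        assert update_weights(np.array([u]), np.array([p]))[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "d, expected",
        [([2.0, 2.0], [1.0, 1.0]), ([3.0, 1.0], [1.5, 0.5])],
    )
    def test_normalize_examples(self, d, expected):
        np.testing.assert_allclose(normalize_weights(np.array(d)), expected)

    def test_normalize_zero_weights_error(self):
        with pytest.raises(ValueError):
            normalize_weights(np.zeros(3))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=50))
    def test_normalize_trace_property(self, d):
        out = normalize_weights(np.array(d))
        assert out.sum() == pytest.approx(len(d), abs=1e-10)


class TestRunWssgwas:
    def test_zero_reweight_keeps_identity_weights(self, medium_sim):
        vc = _vc(medium_sim["truth"].sigma2_a["T"], medium_sim["truth"].sigma2_e["T"])
        state, sol = run_wssgwas(
            ModelSpec(["T"]), medium_sim["phen"], medium_sim["ped"], medium_sim["geno"], vc, n_reweight=0
        )
        np.testing.assert_array_equal(state.weights, np.ones(medium_sim["geno"].n_markers))
        assert len(state.history) == 1

    def test_one_reweight_weights_follow_squared_effects(self):
        # d = u^2 * 2p(1-p): ranks of d track ranks of u^2 tightly when the
        # heterozygosity spread is bounded (founder MAF well off zero)
        from scipy.stats import spearmanr

        cfg, ped, mm, geno, phen, truth = small_single_trait_sim(
            61,
            n_founders=200,
            founder_maf_range=(0.2, 0.5),
            n_qtl=5,
            qtl_variance_fraction=0.5,
            genotyped_fraction=0.8,
        )
        from sswool.synthetic_data import sample_genotyped_ids

        gids = sample_genotyped_ids(phen, cfg)
        sub = GenotypeMatrix(geno.dosage[ped.index_of(gids)].copy(), gids)
        vc = _vc(truth.sigma2_a["T"], truth.sigma2_e["T"])
        state, _ = run_wssgwas(ModelSpec(["T"]), phen, ped, sub, vc, n_reweight=1)
        u1 = state.history[0]["u_hat"]
        d2 = state.history[1]["weights"]
        rho, _ = spearmanr(d2, u1**2)
        assert rho >= 0.99


class TestWindows:
    def _state(self, u_hat, z, p):
        from sswool.wssgwas import SnpEffectState

        return SnpEffectState(
            iteration=1,
            u_hat=u_hat,
            weights=np.ones_like(u_hat),
            lam=1.0,
            p=p,
            centered_z=z,
        )

    def test_zero_effects_zero_percent(self):
        z = np.random.default_rng(51).standard_normal((6, 10))
        mm = MarkerMap(
            np.array([f"s{j}" for j in range(10)], dtype=object),
            np.array(["1"] * 10, dtype=object),
            np.arange(1, 11) * 100,
        )
        st_ = self._state(np.zeros(10), z, np.full(10, 0.5))
        win = window_variances(st_, mm, _vc(), window_size=3)
        assert (win["pct_variance"] == 0).all()

    def test_single_snp_window_arithmetic(self):
        # dosages (0,1,2) at p=0.5 -> centered (-1,0,1); u=0.4
        z = np.array([[-1.0], [0.0], [1.0]])
        mm = MarkerMap(np.array(["s0"], dtype=object), np.array(["1"], dtype=object), np.array([500]))
        u = np.array([0.4])
        st_ = self._state(u, z, np.array([0.5]))
        vc = _vc(sa=0.3)
        win = window_variances(st_, mm, vc, window_size=1)
        expected = np.var([-0.4, 0.0, 0.4], ddof=1) / 0.3 * 100
        assert win["pct_variance"].iloc[0] == pytest.approx(expected)

    def test_short_chromosome_truncated_and_excluded_from_ranking(self):
        rng = np.random.default_rng(52)
        z = rng.standard_normal((5, 7))
        mm = MarkerMap(
            np.array([f"s{j}" for j in range(7)], dtype=object),
            np.array(["1"] * 5 + ["2"] * 2, dtype=object),
            np.array([100, 200, 300, 400, 500, 100, 200]),
        )
        st_ = self._state(rng.standard_normal(7), z, np.full(7, 0.4))
        win = window_variances(st_, mm, _vc(), window_size=3)
        trunc = win.loc[win["truncated"]]
        assert len(trunc) == 1 and trunc["chromosome"].iloc[0] == "2"
        assert trunc["rank"].isna().all()

    def test_window_count_sliding(self):
        rng = np.random.default_rng(53)
        z = rng.standard_normal((5, 10))
        mm = MarkerMap(
            np.array([f"s{j}" for j in range(10)], dtype=object),
            np.array(["1"] * 10, dtype=object),
            np.arange(1, 11) * 10,
        )
        st_ = self._state(rng.standard_normal(10), z, np.full(10, 0.4))
        win = window_variances(st_, mm, _vc(), window_size=4)
        assert len(win) == 10 - 4 + 1


class TestTopWindows:
    def _results(self, rows):
        df = pd.DataFrame(
            rows, columns=["chromosome", "first_snp", "last_snp", "start_bp", "end_bp", "truncated", "pct_variance"]
        )
        ranked = df.loc[~df["truncated"]].sort_values(
            by=["pct_variance", "chromosome", "start_bp"], ascending=[False, True, True]
        )
        df["rank"] = pd.NA
        df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
        return df

    def test_k_one_picks_max(self):
        res = self._results(
            [("1", 0, 2, 100, 300, False, 1.0), ("1", 3, 5, 400, 600, False, 5.0)]
        )
        top = top_windows(res, k=1)
        assert len(top) == 1 and top["start_bp"].iloc[0] == 400

    def test_overlapping_windows_merge(self):
        res = self._results(
            [("1", 0, 19, 100, 2000, False, 5.0), ("1", 1, 20, 150, 2100, False, 4.0)]
        )
        top = top_windows(res, k=2)
        assert len(top) == 1
        assert top["start_bp"].iloc[0] == 100 and top["end_bp"].iloc[0] == 2100
        assert top["n_windows"].iloc[0] == 2

    def test_tie_break_genome_order(self):
        res = self._results(
            [("2", 0, 1, 100, 200, False, 1.0), ("1", 0, 1, 500, 600, False, 1.0), ("1", 5, 6, 100, 200, False, 1.0)]
        )
        top = top_windows(res, k=2)
        assert list(top["chromosome"]) == ["1", "1"]
        assert list(top["start_bp"]) == [100, 500]

    def test_k_larger_than_windows_returns_all(self):
        res = self._results([("1", 0, 1, 100, 200, False, 1.0)])
        assert len(top_windows(res, k=10)) == 1


class TestTopPercentGenes:
    def _ann(self):
        return GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["gA", "gB"],
                    "chromosome": ["1", "2"],
                    "start_bp": [150, 1000],
                    "end_bp": [250, 2000],
                    "strand": ["+", "+"],
                }
            )
        )

    def test_ceiling_and_overlap(self):
        rows = [("1", 0, 1, 100 * j, 100 * j + 99, False, float(100 - j)) for j in range(100)]
        df = TestTopWindows()._results(rows)
        genes = top_percent_snps(df, self._ann(), fraction=0.01)
        # top window is [0, 99]: no overlap with gA [150,250]
        assert genes == []
        genes2 = top_percent_snps(df, self._ann(), fraction=0.02)
        # second window [100,199] overlaps gA
        assert genes2 == ["gA"]

    def test_gene_containing_window_included(self):
        rows = [("2", 0, 1, 1200, 1300, False, 9.0)]
        df = TestTopWindows()._results(rows)
        assert top_percent_snps(df, self._ann(), fraction=1.0) == ["gB"]

    def test_empty_annotation(self):
        rows = [("1", 0, 1, 100, 200, False, 1.0)]
        df = TestTopWindows()._results(rows)
        empty = GeneAnnotation(
            pd.DataFrame(columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"])
        )
        assert top_percent_snps(df, empty, fraction=1.0) == []
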