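"""GRM construction and AI-REML variance components against oracles."""

import numpy as np
import pandas as pd
import pytest

import latentgen as lg
from latentgen.genotype_io import GRM, MISSING, GenotypeMatrix

from conftest import dense_reml_loglik


def _geno_from_dosages(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        snp_meta=pd.DataFrame(
            {
                "chrom": ["1"] * m,
                "snp_id": [f"s{i}" for i in range(m)],
                "pos": np.arange(1, m + 1),
                "a1": ["A"] * m,
                "a2": ["C"] * m,
            }
        ),
        sample_ids=pd.DataFrame(
            {"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)]}
        ),
    )


class TestComputeGrm:
    def test_hand_fixture_standardization(self):
        # dosages ind1=(0,2), ind2=(2,0); in-sample p=(0.5,0.5)
        geno = _geno_from_dosages([[0, 2], [2, 0]])
        grm = lg.compute_grm(geno, maf_min=0.0)
        assert np.allclose(grm.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-10)
        assert grm.m_used == 2

    def test_duplicated_individual_off_diagonal_equals_diagonal(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        d[1] = d[0]
        grm = lg.compute_grm(_geno_from_dosages(d), maf_min=0.0)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-8)

    def test_hwe_moments(self):
        geno = lg.simulate_genotypes(1000, 5000, seed=14)
        grm = lg.compute_grm(geno, maf_min=0.0)
        off = grm.matrix[np.triu_indices(1000, 1)]
        assert 0.95 < grm.matrix.diagonal().mean() < 1.05
        assert abs(off.mean()) < 3e-3
        assert abs(off.var() * 5000 - 1.0) < 0.2
        assert np.linalg.eigvalsh(grm.matrix).min() > -1e-8

    def test_maf_filter_and_empty_error(self):
        geno = lg.simulate_genotypes(200, 100, maf_range=(0.02, 0.4), seed=3)
        maf = np.minimum(geno.allele_freq, 1 - geno.allele_freq)
        grm = lg.compute_grm(geno, maf_min=0.1)
        assert grm.m_used == int((maf >= 0.1).sum())
        with pytest.raises(ValueError, match="no SNPs survive"):
            lg.compute_grm(geno, maf_min=0.6)

    def test_missing_dosages_mean_imputed_with_pair_counts(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        grm = lg.compute_grm(_geno_from_dosages(d), maf_min=0.0, max_missing=0.5)
        assert grm.pair_counts.min() > 0
        assert grm.pair_counts.max() <= grm.m_used
        assert np.allclose(grm.matrix, grm.matrix.T)


class TestUnivariateAireml:
    def test_matches_dense_grid_search_on_toy_problem(self):
        """AI-REML equals a brute-force grid search over the explicit dense
        REML log-likelihood (n = 40) within the 0.005 grid resolution."""
        geno = lg.simulate_genotypes(40, 800, seed=1)
        grm = lg.compute_grm(geno, maf_min=0.0)
        rng = np.random.default_rng(51)
        C = 0.7 * grm.matrix + 0.3 * np.eye(40) + 1e-8 * np.eye(40)
        y = np.linalg.cholesky(C) @ rng.standard_normal(40)
        res = lg.fit_aireml_univariate(grm, y)
        grid = np.arange(0.005, 1.5, 0.01)
        best = (-np.inf, None, None)
        for sg in grid:
            ll = [dense_reml_loglik(grm.matrix, y, sg, se) for se in grid]
            j = int(np.argmax(ll))
            if ll[j] > best[0]:
                best = (ll[j], sg, grid[j])
        assert res.loglik >= best[0] - 1e-6
        assert abs(res.components["sigma2_g"] - best[1]) <= 0.01
        assert abs(res.components["sigma2_e"] - best[2]) <= 0.01

    def test_loglik_trace_non_decreasing(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(grm.n)
        res = lg.fit_aireml_univariate(grm, y)
        diffs = np.diff(res.loglik_trace)
        assert (diffs > -1e-8).all()

    def test_null_permuted_phenotype_centered_near_zero(self, small_geno):
        """With the phenotype permuted against the GRM the h2 estimates pile
        up at the zero boundary: the replicate mean must not exceed the
        half-normal expectation implied by the per-replicate SE (the
        variance floor truncates negative estimates at zero)."""
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(2)
        base = rng.standard_normal(grm.n)
        h2s = []
        for _ in range(30):
            y = rng.permutation(base)
            h2s.append(lg.fit_aireml_univariate(grm, y).h2["trait"])
        per_rep_se = np.sqrt(2.0 / (grm.n**2 / grm.m_used))
        mc_se = np.std(h2s, ddof=1) / np.sqrt(len(h2s))
        # E[max(N(0, se), 0)] = se / sqrt(2 pi)
        assert np.mean(h2s) < per_rep_se / np.sqrt(2 * np.pi) + 2 * mc_se

    def test_h2_recovery_at_half(self):
        h2s = []
        for seed in range(1, 9):
            geno = lg.simulate_genotypes(800, 2000, seed=seed)
            params = lg.GenerativeParams(
                n=800, m=2000, h2_per_latent=0.5, latent_structure="two_factor",
                genetic_corr=0.0, factor_corr=0.0, seed=seed,
            )
            truth = lg.simulate_latent_structure(geno, params, seed=seed + 500)
            grm = lg.compute_grm(geno, maf_min=0.0)
            h2s.append(lg.fit_aireml_univariate(grm, truth.factor_values[:, 0]).h2["trait"])
        assert 0.42 < np.mean(h2s) < 0.58

    def test_identity_grm_reported_non_identifiable(self):
        n = 80
        ids = pd.DataFrame({"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)]})
        grm = GRM(matrix=np.eye(n), pair_counts=np.full((n, n), 100.0), ids=ids, m_used=100)
        y = np.random.default_rng(0).standard_normal(n)
        res = lg.fit_aireml_univariate(grm, y)
        assert "non_identifiable" in res.flags or not res.converged

    def test_zero_variance_phenotype_rejected(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        with pytest.raises(ValueError, match="variance"):
            lg.fit_aireml_univariate(grm, np.ones(grm.n))

    def test_missing_phenotypes_subset_the_grm(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(grm.n)
        y[:50] = np.nan
        res = lg.fit_aireml_univariate(grm, y)
        assert res.n_used == grm.n - 50


class TestBivariateAireml:
    def test_identical_traits_hit_rg_boundary(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(3)
        C = 0.5 * grm.matrix + 0.5 * np.eye(grm.n)
        y = np.linalg.cholesky(C + 1e-8 * np.eye(grm.n)) @ rng.standard_normal(grm.n)
        res = lg.fit_aireml_bivariate(grm, y, y.copy())
        assert res.rg >= 0.99

    def test_null_rg_centered_at_zero(self):
        rgs = []
        for seed in range(1, 26):
            geno = lg.simulate_genotypes(500, 1000, seed=seed)
            params = lg.GenerativeParams(
                n=500, m=1000, h2_per_latent=0.4, genetic_corr=0.0,
                factor_corr=0.0, seed=seed,
            )
            truth = lg.simulate_latent_structure(geno, params, seed=seed + 300)
            grm = lg.compute_grm(geno, maf_min=0.0)
            res = lg.fit_aireml_bivariate(
                grm, truth.factor_values[:, 0], truth.factor_values[:, 1]
            )
            rgs.append(res.rg)
        mc_se = np.std(rgs, ddof=1) / np.sqrt(len(rgs))
        assert abs(np.mean(rgs)) < 2 * mc_se

    def test_marginals_match_univariate_when_second_trait_is_noise(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(9)
        C = 0.5 * grm.matrix + 0.5 * np.eye(grm.n)
        y1 = np.linalg.cholesky(C + 1e-8 * np.eye(grm.n)) @ rng.standard_normal(grm.n)
        y2 = rng.standard_normal(grm.n)
        uni = lg.fit_aireml_univariate(grm, y1)
        bi = lg.fit_aireml_bivariate(grm, y1, y2)
        assert abs(bi.components["sigma2_g1"] - uni.components["sigma2_g"]) < 1e-3

    def test_rg_recovery_at_07(self):
        rgs = []
        for seed in range(1, 9):
            geno = lg.simulate_genotypes(800, 2000, seed=seed)
            params = lg.GenerativeParams(
                n=800, m=2000, h2_per_latent=0.5, genetic_corr=0.7,
                factor_corr=0.5, seed=seed,
            )
            truth = lg.simulate_latent_structure(geno, params, seed=seed + 700)
            grm = lg.compute_grm(geno, maf_min=0.0)
            rgs.append(
                lg.fit_aireml_bivariate(
                    grm, truth.factor_values[:, 0], truth.factor_values[:, 1]
                ).rg
            )
        assert 0.6 < np.mean(rgs) < 0.8

    def test_loglik_trace_non_decreasing(self, small_geno):
        grm = lg.compute_grm(small_geno, maf_min=0.0)
        rng = np.random.default_rng(12)
        y1, y2 = rng.standard_normal((2, grm.n))
        res = lg.fit_aireml_bivariate(grm, y1, y2)
        assert (np.diff(res.loglik_trace) > -1e-8).all()


class TestEndToEnd:
    def test_factor_score_greml_recovers_attenuated_latent_h2(self):
        """Generate from the bifactor structure, extract general-factor
        scores by FIML CFA, run GREML on the scores: the mean estimate over
        replicates matches the genetic share of the score variance computed
        from the ground truth (determinacy attenuation included)."""
        from latentgen.sem import ConfirmatoryFactorModel, make_model_spec

        ests, expects = [], []
        for seed in range(1, 11):
            params = lg.GenerativeParams(
                n=1200, m=2500, h2_per_latent=0.25, latent_structure="residual",
                taf_binary=False, missing_rate=0.0, seed=seed,
            )
            sim = lg.simulate_dataset(params)
            table = lg.residualize(sim.table)
            model = ConfirmatoryFactorModel(
                make_model_spec("residual"), compute_se=False
            ).fit(table)
            if not model.converged_:
                continue
            scores = model.transform(table.df)
            s = scores["general"].to_numpy()
            grm = lg.compute_grm(sim.geno, maf_min=0.0)
            ests.append(lg.fit_aireml_univariate(grm, s).h2["trait"])
            # ground-truth genetic share of this replicate's score variance
            _, _, lam, _, _, _ = params.resolved()
            w = np.linalg.lstsq(
                table.df[model.spec.indicators].to_numpy() - model.means_,
                s, rcond=None,
            )[0]
            g_score = (sim.truth.genetic_values @ lam.T) @ w
            expects.append(g_score.var() / s.var())
        assert len(ests) >= 8
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - np.mean(expects)) < 3 * se
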