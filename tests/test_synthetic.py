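"""Generator ground truth: frequencies, latent structure, item covariances."""

import numpy as np
import pytest

import latentgen as lg
from latentgen.synthetic import structure_defaults


class TestSimulateGenotypes:
    def test_same_seed_identical(self):
        a = lg.simulate_genotypes(50, 40, seed=3)
        b = lg.simulate_genotypes(50, 40, seed=3)
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, lg.simulate_genotypes(50, 40, seed=4).dosages)

    def test_degenerate_maf_range_hits_half(self):
        g = lg.simulate_genotypes(10000, 30, maf_range=(0.5, 0.5), seed=1)
        se = np.sqrt(0.25 / (2 * 10000))
        assert np.abs(g.allele_freq - 0.5).max() < 4.5 * se

    def test_mean_dosage_within_binomial_error(self):
        g = lg.simulate_genotypes(5000, 1, maf_range=(0.3, 0.3), seed=2)
        se = np.sqrt(2 * 0.3 * 0.7 / 5000)
        assert abs(g.dosages.mean() - 0.6) < 3 * se

    def test_no_monomorphic_snps(self):
        g = lg.simulate_genotypes(30, 200, maf_range=(0.01, 0.05), seed=5)
        assert (g.dosages.max(axis=0) > g.dosages.min(axis=0)).all()

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            lg.simulate_genotypes(10, 5, maf_range=(0.0, 0.6))


class TestLatentStructure:
    def test_zero_heritability_gives_zero_genetic_values(self):
        params = lg.GenerativeParams(n=500, m=10, h2_per_latent=0.0, seed=1)
        truth = lg.simulate_latent_structure(None, params)
        assert np.all(truth.genetic_values == 0.0)
        assert np.allclose(truth.factor_values.var(axis=0), 1.0, atol=0.02)

    def test_identity_genetic_corr_gives_uncorrelated_genetic_values(self):
        g = lg.simulate_genotypes(2000, 3000, seed=8)
        params = lg.GenerativeParams(
            n=2000, m=3000, h2_per_latent=0.5, genetic_corr=0.0, factor_corr=0.0, seed=8
        )
        truth = lg.simulate_latent_structure(g, params)
        r = np.corrcoef(truth.genetic_values.T)[0, 1]
        assert abs(r) < 0.08

    def test_generative_rg_recovered_in_true_genetic_values(self):
        """Mean empirical correlation of the true genetic components across
        replicates stays inside [rG - 0.05, rG + 0.05] for rG = 0.7."""
        rs = []
        for seed in range(1, 16):
            g = lg.simulate_genotypes(1000, 2000, seed=seed)
            params = lg.GenerativeParams(
                n=1000, m=2000, h2_per_latent=0.4, genetic_corr=0.7,
                factor_corr=0.5, seed=seed,
            )
            truth = lg.simulate_latent_structure(g, params, seed=seed + 999)
            rs.append(np.corrcoef(truth.genetic_values.T)[0, 1])
        assert 0.65 < np.mean(rs) < 0.75

    def test_latent_variance_partition_is_exact(self):
        g = lg.simulate_genotypes(800, 1000, seed=2)
        params = lg.GenerativeParams(n=800, m=1000, h2_per_latent=0.35, seed=2)
        truth = lg.simulate_latent_structure(g, params)
        assert np.allclose(truth.genetic_values.var(axis=0), 0.35, atol=1e-10)
        assert np.allclose(truth.env_values.var(axis=0), 0.65, atol=1e-10)

    def test_unreachable_factor_corr_rejected(self):
        g = lg.simulate_genotypes(100, 50, seed=1)
        params = lg.GenerativeParams(
            n=100, m=50, h2_per_latent=0.9, genetic_corr=-0.9, factor_corr=0.9, seed=1
        )
        with pytest.raises(ValueError, match="positive semidefinite|unreachable"):
            lg.simulate_latent_structure(g, params)

    def test_invalid_genetic_corr_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            lg.GenerativeParams(
                genetic_corr=np.array([[1.0, 1.2], [1.2, 1.0]])
            ).resolved()


class TestObservedItems:
    def test_empirical_covariance_matches_lambda_phi_lambda_plus_theta(self):
        """At n = 50,000 every entry of the indicator covariance matches the
        model-implied Lambda Phi Lambda' + Theta within 3 standard errors."""
        params = lg.GenerativeParams(
            n=50000, m=10, h2_per_latent=0.0, latent_structure="two_factor",
            taf_binary=False, missing_rate=0.0, covariate_betas={}, seed=31,
        )
        sim = lg.simulate_dataset(params)
        _, _, lam, phi, _, _ = params.resolved()
        implied = lam @ phi @ lam.T + np.diag(1 - np.einsum("pk,kl,pl->p", lam, phi, lam))
        cols = sim.table.analysis_cols
        emp = np.cov(sim.table.df[cols].to_numpy().T)
        n = params.n
        se = np.sqrt(
            (np.outer(np.diag(implied), np.diag(implied)) + implied**2) / n
        )
        assert np.all(np.abs(emp - implied) < 3 * se)

    def test_zero_loading_indicator_is_pure_noise(self):
        lam = np.zeros((6, 2))
        lam[1:3, 0] = 0.7
        lam[3:6, 1] = 0.7  # AN row stays zero
        params = lg.GenerativeParams(
            n=20000, m=10, h2_per_latent=0.0, latent_structure="two_factor",
            true_loadings=lam, taf_binary=False, missing_rate=0.0,
            covariate_betas={}, seed=13,
        )
        sim = lg.simulate_dataset(params)
        an = sim.table.df["AN_score"]
        for j in range(2):
            assert abs(np.corrcoef(an, sim.truth.factor_values[:, j])[0, 1]) < 0.03

    def test_indicator_factor_correlation_equals_loading(self):
        lam = np.zeros((6, 2))
        lam[0, 0] = 0.8
        lam[1:3, 0] = 0.6
        lam[3:6, 1] = 0.6
        params = lg.GenerativeParams(
            n=20000, m=10, h2_per_latent=0.0, latent_structure="two_factor",
            true_loadings=lam, factor_corr=0.0, taf_binary=False,
            missing_rate=0.0, covariate_betas={}, seed=17,
        )
        sim = lg.simulate_dataset(params)
        r = np.corrcoef(sim.table.df["AN_score"], sim.truth.factor_values[:, 0])[0, 1]
        assert 0.78 < r < 0.82

    def test_taf_prevalence_controls_endorsement(self):
        params = lg.GenerativeParams(
            n=10000, m=10, h2_per_latent=0.0, taf_prevalence=(0.5, 0.5, 0.5),
            taf_binary=True, missing_rate=0.0, seed=3,
        )
        sim = lg.simulate_dataset(params)
        rates = sim.table.df[["TAF1", "TAF2", "TAF3"]].mean()
        assert np.allclose(rates, 0.5, atol=0.02)

    def test_items_sum_to_score(self):
        params = lg.GenerativeParams(
            n=500, m=10, h2_per_latent=0.0, missing_rate=0.0, seed=4, taf_binary=False
        )
        sim = lg.simulate_dataset(params)
        items = [c for c in sim.table.item_cols if c.startswith("AN_item")]
        assert np.allclose(
            sim.table.df[items].sum(axis=1), sim.table.df["AN_score"], atol=1e-9
        )

    def test_excess_communality_rejected(self):
        lam = np.zeros((6, 2))
        lam[0, 0] = 1.2
        lam[1:3, 0] = 0.7
        lam[3:6, 1] = 0.7
        params = lg.GenerativeParams(
            n=100, m=10, h2_per_latent=0.0, true_loadings=lam, seed=1
        )
        truth = lg.simulate_latent_structure(None, params)
        with pytest.raises(ValueError, match="communality"):
            lg.generate_observed_items(truth, params)

    def test_psychopathology_variant_adds_phq_gad(self):
        params = lg.GenerativeParams(
            n=300, m=10, h2_per_latent=0.0, with_psychopathology=True,
            missing_rate=0.0, seed=6,
        )
        sim = lg.simulate_dataset(params)
        assert {"PHQ8", "GAD7"} <= set(sim.table.df.columns)


class TestMissingness:
    def _table(self, n=10000):
        params = lg.GenerativeParams(
            n=n, m=10, h2_per_latent=0.0, missing_rate=0.0, taf_binary=False, seed=9
        )
        return lg.simulate_dataset(params).table

    def test_zero_rate_is_identity(self):
        t = self._table(200)
        out = lg.inject_missingness(t, 0.0, seed=1)
        assert out.df.equals(t.df)

    def test_rate_recovered_within_binomial_error(self):
        t = self._table()
        out = lg.inject_missingness(t, 0.2, seed=2)
        cells = out.df[out.analysis_cols].to_numpy()
        frac = np.isnan(cells).mean()
        se = np.sqrt(0.2 * 0.8 / cells.size)
        assert abs(frac - 0.2) < 3 * se

    def test_same_seed_same_mask(self):
        t = self._table(500)
        a = lg.inject_missingness(t, 0.3, seed=7)
        b = lg.inject_missingness(t, 0.3, seed=7)
        assert a.df.equals(b.df)

    def test_ids_and_covariates_never_masked(self):
        t = self._table(500)
        out = lg.inject_missingness(t, 0.5, seed=1)
        assert not out.df[["FID", "IID"] + out.covariate_cols].isna().any().any()
        with pytest.raises(ValueError, match="refusing"):
            lg.inject_missingness(t, 0.1, columns=["age"])

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            lg.inject_missingness(self._table(50), 1.0)


class TestStructureDefaults:
    @pytest.mark.parametrize(
        "structure,k", [("two_factor", 2), ("hierarchical", 2), ("residual", 3), ("four_factor", 4)]
    )
    def test_shapes_and_valid_correlations(self, structure, k):
        inds, lats, lam, phi, gcorr = structure_defaults(structure)
        assert len(lats) == k and lam.shape == (6, k)
        for mat in (phi, gcorr):
            assert np.allclose(mat, mat.T)
            assert np.linalg.eigvalsh(mat).min() > -1e-10
        comm = np.einsum("pk,kl,pl->p", lam, phi, lam)
        assert (comm < 1.0).all()
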