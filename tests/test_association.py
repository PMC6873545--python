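"""β→M transform, genotype PCA and the y = PC1 + PC2 + Meth regression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from methvar import (
    SimulationConfig,
    associate,
    beta_to_m,
    genotype_pca,
    m_to_beta,
    simulate_dataset,
)
from methvar.synthetic import simulate_sample_levels


class TestBetaToM:
    @pytest.mark.parametrize("beta, m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_exact_at_dyadic_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.01, 0.99, size=100)
        np.testing.assert_allclose(beta_to_m(b), -beta_to_m(1 - b), atol=1e-10)

    def test_eps_clipping_keeps_extremes_finite(self):
        assert np.isfinite(beta_to_m(0.0)) and np.isfinite(beta_to_m(1.0))
        assert beta_to_m(0.0) == pytest.approx(-beta_to_m(1.0))

    def test_inverse_transform(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.01, 0.99, size=50)
        np.testing.assert_allclose(m_to_beta(beta_to_m(b)), b, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(1.2)
        with pytest.raises(ValueError):
            beta_to_m(-0.1)


class TestGenotypePca:
    def _frame(self, arr):
        return pd.DataFrame(
            arr,
            index=[f"S{i}" for i in range(arr.shape[0])],
            columns=[f"snp{j}" for j in range(arr.shape[1])],
        )

    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, size=30)
        geno = self._frame(np.vstack([row, row, row + rng.integers(0, 2, 30)]))
        scores = genotype_pca(geno, n_components=2)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[1], atol=1e-10)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(4)
        geno = self._frame(rng.integers(0, 3, size=(20, 50)))
        scores = genotype_pca(geno, 2).to_numpy()
        assert abs(scores[:, 0] @ scores[:, 1]) < 1e-8

    def test_structure_axis_recovered_on_pc1(self):
        """A planted two-cluster allele-frequency tilt separates on PC1."""
        from sklearn.metrics import silhouette_score

        from methvar.synthetic import simulate_genotypes

        cfg = SimulationConfig(seed=5, n_snps=400, confound_strength=1.0)
        geno, _, u = simulate_genotypes(cfg, np.random.default_rng(5))
        scores = genotype_pca(geno, 2).to_numpy()
        assert silhouette_score(scores[:, :1], (u > 0).astype(int)) > 0.8

    def test_deterministic_sign_convention(self, default_dataset):
        a = genotype_pca(default_dataset.genotypes, 2)
        b = genotype_pca(default_dataset.genotypes, 2)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_components_rejected(self):
        geno = self._frame(np.array([[0, 1], [2, 1]]))
        with pytest.raises(ValueError):
            genotype_pca(geno, 3)


def _random_inputs(rng, n=19, n_regions=4, n_traits=2):
    samples = [f"S{i}" for i in range(n)]
    m = pd.DataFrame(
        rng.normal(size=(n_regions, n)),
        index=[f"r{i}" for i in range(n_regions)],
        columns=samples,
    )
    pheno = pd.DataFrame(
        rng.normal(size=(n, n_traits)),
        index=samples,
        columns=[f"t{j}" for j in range(n_traits)],
    )
    cov = pd.DataFrame(
        rng.normal(size=(n, 2)), index=samples, columns=["PC1", "PC2"]
    )
    return m, pheno, cov


class TestAssociate:
    def test_matches_statsmodels_ols(self):
        """Frisch–Waugh implementation == full OLS fit, coefficient and p."""
        rng = np.random.default_rng(11)
        m, pheno, cov = _random_inputs(rng)
        results = associate(m, pheno, cov)
        for r in results:
            x = np.column_stack(
                [np.ones(19), cov.to_numpy(), m.loc[r.region].to_numpy()]
            )
            fit = sm.OLS(pheno[r.trait].to_numpy(), x).fit()
            assert r.effect == pytest.approx(fit.params[-1], rel=1e-10)
            assert r.se == pytest.approx(fit.bse[-1], rel=1e-10)
            assert r.p == pytest.approx(fit.pvalues[-1], rel=1e-10)
            assert fit.df_resid == 19 - 4

    def test_zero_covariates_reduce_to_simple_regression(self):
        rng = np.random.default_rng(12)
        m, pheno, _ = _random_inputs(rng)
        results = associate(m, pheno, None)
        for r in results:
            x = sm.add_constant(m.loc[r.region].to_numpy())
            fit = sm.OLS(pheno[r.trait].to_numpy(), x).fit()
            assert r.p == pytest.approx(fit.pvalues[-1], rel=1e-10)

    def test_invariant_to_sample_reordering_and_covariate_rescaling(self):
        rng = np.random.default_rng(13)
        m, pheno, cov = _random_inputs(rng)
        base = {(r.region, r.trait): r.p for r in associate(m, pheno, cov)}
        perm = rng.permutation(m.columns)
        shuffled = associate(m[perm], pheno.loc[perm], cov.loc[perm])
        for r in shuffled:
            assert r.p == pytest.approx(base[(r.region, r.trait)], rel=1e-9)
        rescaled = associate(m, pheno, cov * 7.5 + 3.0)
        for r in rescaled:
            assert r.p == pytest.approx(base[(r.region, r.trait)], rel=1e-9)

    def test_missing_values_dropped_listwise(self):
        rng = np.random.default_rng(14)
        m, pheno, cov = _random_inputs(rng)
        m.iloc[0, 3] = np.nan
        pheno.iloc[5, 0] = np.nan
        results = associate(m, pheno, cov)
        r = next(x for x in results if x.region == "r0" and x.trait == "t0")
        assert r.n == 17

    def test_constant_m_reported_untestable(self):
        rng = np.random.default_rng(15)
        m, pheno, cov = _random_inputs(rng)
        m.loc["r0"] = 0.7
        r = next(
            x for x in associate(m, pheno, cov) if x.region == "r0" and x.trait == "t0"
        )
        assert np.isnan(r.p) and r.tier == "none"

    def test_bonferroni_tiers_use_region_count(self):
        rng = np.random.default_rng(16)
        n = 30
        samples = [f"S{i}" for i in range(n)]
        m = pd.DataFrame(
            rng.normal(size=(2, n)), index=["ra", "rb"], columns=samples
        )
        # make ra strongly predictive of the trait
        pheno = pd.DataFrame(
            {"t": m.loc["ra"] * 2 + rng.normal(0, 0.1, n)}, index=samples
        )
        results = associate(m, pheno, None)
        ra = next(r for r in results if r.region == "ra")
        assert ra.p < 0.05 / 2 and ra.tier == "significant"


class TestPlantedTraitEffects:
    def test_sign_recovery_and_null_uniformity(self):
        """Planted b/σ = 1.5 at n = 19 recovers the effect sign; null traits
        give calibrated p-values."""
        sign_ok = total = 0
        null_ps = []
        for seed in range(200, 212):
            cfg = SimulationConfig(
                seed=seed, n_samples=19, trait_effect=1.5, n_trait_pairs=2,
                n_traits=4,
                n_blocks_per_class={"HVMR": 4, "hypoCMR": 0, "hyperCMR": 0,
                                    "neutral": 4},
                chrom_length=20_000, n_meqtl=0,
            )
            ds = simulate_dataset(cfg)
            truth_m = pd.DataFrame(
                {b.name: beta_to_m(b.pi) for b in ds.truth.blocks}
            ).T
            truth_m.columns = ds.samples
            pcs = genotype_pca(ds.genotypes, 2)
            results = associate(truth_m, ds.phenotypes, pcs)
            planted = {(r, t): e for r, t, e in ds.truth.trait_pairs}
            for r in results:
                if (r.region, r.trait) in planted:
                    total += 1
                    sign_ok += np.sign(r.effect) == np.sign(planted[(r.region, r.trait)])
                else:
                    null_ps.append(r.p)
        assert total >= 20
        assert sign_ok / total >= 0.95
        # null p-values must not pile up near zero
        assert np.mean(np.array(null_ps) < 0.05) < 0.15
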