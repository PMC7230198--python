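"""Genotype posteriors, trait transform, kinship, the sparse LMM sampler,
QTL regression, GEBV correlations and family variance components."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hostadapt import gwa, simdata


class TestGenotypePosteriorMean:
    def test_certain_heterozygote_overrides_prior(self):
        lik = np.zeros((3, 2, 3))
        lik[:, :, 1] = 1.0
        ghat = gwa.genotype_posterior_mean(
            lik, np.full(3, 0.1), np.full(3, 0.9), ancestry_weight_q=0.75
        )
        assert np.allclose(ghat, 1.0)

    def test_flat_likelihood_returns_prior_mean(self):
        lik = np.full((1, 1, 3), 1.0)
        # p* = 0.6 -> prior mean genotype 1.2
        ghat = gwa.genotype_posterior_mean(
            lik, np.array([0.6]), np.array([0.6]), ancestry_weight_q=0.5
        )
        assert ghat[0, 0] == pytest.approx(1.2)

    def test_single_site_bayes_arithmetic(self):
        lik = np.array([[[0.1, 0.6, 0.3]]])
        p = 0.5  # prior (0.25, 0.5, 0.25)
        w = np.array([0.1 * 0.25, 0.6 * 0.5, 0.3 * 0.25])
        expect = (w[1] + 2 * w[2]) / w.sum()
        ghat = gwa.genotype_posterior_mean(
            lik, np.array([p]), np.array([p]), ancestry_weight_q=0.5
        )
        assert ghat[0, 0] == pytest.approx(expect)

    def test_invalid_ancestry_weight_rejected(self):
        with pytest.raises(ValueError):
            gwa.genotype_posterior_mean(
                np.ones((1, 1, 3)), np.array([0.5]), np.array([0.5]), 1.5
            )


class TestNormalQuantileTransform:
    def test_idempotent_on_quantile_scale(self):
        n = 25
        y = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert np.allclose(gwa.normal_quantile_transform(y), y, atol=1e-12)

    def test_rank_order_preserved(self, rng):
        y = rng.gamma(2.0, size=60)
        z = gwa.normal_quantile_transform(y)
        assert stats.spearmanr(y, z).statistic == pytest.approx(1.0)

    def test_ties_get_average_rank_quantile(self):
        z = gwa.normal_quantile_transform(np.array([1.0, 2.0, 2.0, 9.0]))
        assert z[1] == pytest.approx(0.0, abs=1e-12)
        assert z[2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            gwa.normal_quantile_transform(np.full(5, 3.0))


class TestKinship:
    def test_identical_rows_share_kinship_entries(self):
        G = np.array([[0.0, 2.0, 1.0], [0.0, 2.0, 1.0], [2.0, 0.0, 1.0]])
        K = gwa.compute_kinship(G)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 0] == pytest.approx(K[1, 1])

    def test_symmetric_positive_semidefinite(self, rng):
        G = rng.integers(0, 3, size=(15, 40)).astype(float)
        K = gwa.compute_kinship(G)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_three_individual_hand_computation(self):
        G = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        Gc = G - G.mean(axis=0)
        expect = Gc @ Gc.T / 2
        assert np.allclose(gwa.compute_kinship(G), expect)


def _bc_dataset(seed, n_fam=12, per_fam=25, m=800, pve=0.4, n_causal=8):
    rng = np.random.default_rng(seed)
    eff = np.zeros((m, 2))
    causal = rng.choice(m, n_causal, replace=False)
    eff[causal, 0] = 0.5 * np.sign(rng.standard_normal(n_causal))
    truth = simdata.SimTruth(qtl_effects=eff, target_pve=pve)
    bc = simdata.simulate_backcross(n_fam, per_fam, m, truth, seed=seed + 1)
    return bc, causal


class TestSparseLmm:
    SETTINGS = dict(chains=2, burn_in=2000, n_iter=6000, thin=5)

    def test_null_trait_has_low_pve_and_sparse_inclusion(self):
        m = 500
        prior_pi_mean = (1 - 1 / m) / np.log(m)  # uniform-on-log prior mean
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            X = 1.0 + rng.binomial(1, 0.5, size=(300, m))
            z = rng.standard_normal(300)  # independent of genotypes
            fit = gwa.fit_sparse_lmm(z, X, seed=seed, **self.SETTINGS)
            assert fit.pve_draws.mean() < 0.15
            assert fit.pip.mean() < 2 * prior_pi_mean

    def test_large_effect_snp_gets_high_pip_despite_ld_duplicate(self):
        rng = np.random.default_rng(2)
        n, m = 400, 200
        X = 1.0 + rng.binomial(1, 0.5, size=(n, m))
        X[:, 101] = X[:, 100]  # perfect-LD duplicate
        g = X[:, 100] - X[:, 100].mean()
        g *= np.sqrt(1.0 / g.var())
        z = g + rng.standard_normal(n)  # SNP explains 50% of variance
        fit = gwa.fit_sparse_lmm(z, X, seed=3, **self.SETTINGS)
        assert fit.pip[[100, 101]].max() > 0.5

    def test_posterior_draw_ranges_and_gebv_variance_bound(self):
        bc, _ = _bc_dataset(seed=30, m=300, per_fam=15)
        z = bc["traits"][:, 0]
        fit = gwa.fit_sparse_lmm(
            z, bc["genotypes"].astype(float), seed=4, **self.SETTINGS
        )
        assert np.all((fit.pve_draws >= 0) & (fit.pve_draws <= 1))
        assert np.all((fit.pge_draws >= 0) & (fit.pge_draws <= 1))
        assert np.all(fit.n_gamma_draws >= 0)
        assert np.all(fit.n_gamma_draws == np.round(fit.n_gamma_draws))
        assert np.all((fit.pip >= 0) & (fit.pip <= 1))
        assert fit.gebv.var() <= 1.1 * z.var()

    def test_seeded_runs_reproduce_posterior_summaries(self):
        bc, _ = _bc_dataset(seed=31, m=200, per_fam=10)
        z = bc["traits"][:, 0]
        X = bc["genotypes"].astype(float)
        small = dict(chains=2, burn_in=500, n_iter=1000, thin=5)
        a = gwa.fit_sparse_lmm(z, X, seed=5, **small)
        b = gwa.fit_sparse_lmm(z, X, seed=5, **small)
        assert np.array_equal(a.pip, b.pip)
        assert np.array_equal(a.pve_draws, b.pve_draws)
        assert np.array_equal(a.gebv, b.gebv)

    def test_negatively_correlated_architecture_gives_negative_gebv_r(self):
        rng = np.random.default_rng(6)
        m = 400
        eff = np.zeros((m, 2))
        e = rng.normal(0, 0.4, 20)
        eff[:20, 0] = e
        eff[:20, 1] = -e
        truth = simdata.SimTruth(qtl_effects=eff, target_pve=0.5)
        bc = simdata.simulate_backcross(12, 25, m, truth, seed=7)
        X = bc["genotypes"].astype(float)
        fw = gwa.fit_sparse_lmm(bc["traits"][:, 0], X, seed=8, **self.SETTINGS)
        fd = gwa.fit_sparse_lmm(bc["traits"][:, 1], X, seed=9, **self.SETTINGS)
        res = gwa.gebv_correlation(fw.gebv, fd.gebv)
        assert res["r"] < 0

    def test_non_psd_kinship_rejected(self):
        X = np.random.default_rng(1).random((10, 5))
        K = -np.eye(10)
        with pytest.raises(ValueError):
            gwa.fit_sparse_lmm(np.zeros(10), X, K=K, chains=1, burn_in=10,
                               n_iter=10, thin=1)


class TestQtlScaffoldRegression:
    def test_constant_pip_is_exactly_proportional(self):
        scaff = np.repeat([f"s{i}" for i in range(10)], [5 * (i + 1) for i in range(10)])
        pip = np.full(scaff.size, 0.01)
        res = gwa.qtl_scaffold_regression(pip, scaff)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.01)

    def test_concentrated_pip_mass_is_top_residual(self):
        scaff = np.repeat(["s0", "s1", "s2", "s3"], [2, 10, 20, 30])
        pip = np.zeros(scaff.size)
        pip[0] = 0.9  # all mass on one SNP of the smallest scaffold
        res = gwa.qtl_scaffold_regression(pip, scaff)
        per = res["per_scaffold"]
        resid = per["qtl"] - (res["intercept"] + res["slope"] * per["n_snps"])
        assert resid.idxmax() == "s0"

    def test_r2_matches_independent_ols(self, rng):
        scaff = np.repeat([f"s{i}" for i in range(20)], rng.integers(3, 30, 20))
        pip = rng.random(scaff.size) * 0.05
        res = gwa.qtl_scaffold_regression(pip, scaff)
        per = res["per_scaffold"]
        x = per["n_snps"].to_numpy(dtype=float)
        y = per["qtl"].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        yhat = X @ bhat
        r2 = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert res["r2"] == pytest.approx(r2, abs=1e-10)

    def test_single_scaffold_rejected(self):
        with pytest.raises(ValueError):
            gwa.qtl_scaffold_regression(np.ones(5), np.repeat("s1", 5))


class TestGebvCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        res = gwa.gebv_correlation(x, -x)
        assert res["r"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert gwa.gebv_correlation(x, y)["r"] == pytest.approx(r_hand)

    def test_fisher_z_interval_covers_at_nominal_rate(self):
        rho, n, reps = -0.6, 250, 500
        rng = np.random.default_rng(99)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ L.T
            res = gwa.gebv_correlation(xy[:, 0], xy[:, 1])
            hits += res["ci_low"] <= rho <= res["ci_high"]
        assert 0.93 <= hits / reps <= 0.97

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gwa.gebv_correlation(np.ones(10), np.arange(10.0))


class TestFamilyVariance:
    def test_null_trait_gives_small_fraction_and_uniformish_p(self):
        rng = np.random.default_rng(11)
        fam = np.repeat(np.arange(12), 20)
        fracs, ps = [], []
        for seed in range(50):
            y = rng.standard_normal(240)
            vc = gwa.family_variance_test(y, fam, n_sim=400, seed=seed)
            fracs.append(vc.fraction)
            ps.append(vc.p)
        assert np.mean(fracs) < 0.05
        assert 0.25 < np.mean(ps)  # no systematic anti-conservatism
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_icc_recovery_and_power(self):
        fam = np.repeat(np.arange(12), 20)
        fracs, sig = [], 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            y = rng.normal(0, np.sqrt(0.2), 12)[fam] + rng.normal(
                0, np.sqrt(0.8), 240
            )
            vc = gwa.family_variance_test(y, fam, n_sim=400, seed=seed)
            fracs.append(vc.fraction)
            sig += vc.p < 0.05
        assert 0.1 < np.mean(fracs) < 0.3
        assert sig >= 16  # power >= 80%

    def test_distinct_family_constants_saturate_fraction(self):
        fam = np.repeat(np.arange(6), 8)
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])[fam]
        vc = gwa.family_variance_test(y, fam, n_sim=500, seed=1)
        assert vc.fraction > 0.99
        assert vc.p == pytest.approx(1 / 501)

    def test_reml_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(13)
        fam = np.repeat(np.arange(10), 15)
        y = rng.normal(0, 0.6, 10)[fam] + rng.standard_normal(150)
        vc = gwa.family_variance_test(y, fam, n_sim=10, seed=1)
        df = pd.DataFrame({"y": y, "fam": fam})
        md = smf.mixedlm("y ~ 1", df, groups=df["fam"]).fit(reml=True)
        assert vc.sigma_family == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=0.05)
        assert vc.sigma_resid == pytest.approx(float(md.scale), rel=0.05)

    def test_single_family_rejected(self):
        with pytest.raises(ValueError):
            gwa.family_variance_test(np.arange(5.0), np.zeros(5), n_sim=10, seed=1)
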