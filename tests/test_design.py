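"""Design analyses: biased density and MCMC, partial-phenotype prediction,
constraint profiles, local correlations, and enrichment tests."""

import numpy as np
import pytest

import crlatent as cr
from crlatent.design import (
    BiasSpec,
    MCMCConfig,
    biased_log_density,
    enrichment_test,
    local_correlations,
    phenotype_constraint_profile,
    predict_from_partial_phenotypes,
    sample_biased,
)
from crlatent.mixture import GeneratedCohort, LatentGaussianMixture


def _scalar_model(loading=0.8):
    """Minimal fitted model with a 1-d latent space and one phenotype."""
    model = cr.LatentCompositionModel(n_latent=1)
    model.preferences_ = np.array([[0.5, -0.5]])
    model.loadings_ = np.array([[loading]])
    model.phenotype_ids_ = ["ph"]
    model.phenotype_mean_ = np.zeros(1)
    model.phenotype_sd_ = np.ones(1)
    model.taxon_ids_ = None
    model.sample_ids_ = None
    return model


@pytest.fixture(scope="module")
def scalar_mixture():
    rng = np.random.default_rng(0)
    Z = rng.normal(0.5, 1.2, size=(2000, 1))
    return LatentGaussianMixture(max_components=1, n_restarts=3, random_state=0).fit(Z)


class TestBiasedLogDensity:
    def test_gamma_zero_equals_unbiased_likelihood(self, scalar_mixture, rng):
        model = _scalar_model()
        z = rng.normal(size=(20, 1))
        spec = BiasSpec(targets={"ph": 2.0}, gamma=0.0)
        out = biased_log_density(scalar_mixture, model.loadings_, spec, z, ["ph"])
        assert np.allclose(out, scalar_mixture.score_samples(z))

    def test_zero_penalty_when_prediction_hits_target(self, scalar_mixture):
        model = _scalar_model(loading=0.8)
        target = 1.2
        z = np.array([[target / 0.8]])  # predicted phenotype equals the target
        spec = BiasSpec(targets={"ph": target}, gamma=5.0)
        out = biased_log_density(scalar_mixture, model.loadings_, spec, z, ["ph"])
        assert out[0] == pytest.approx(scalar_mixture.score_samples(z)[0])

    def test_penalty_linear_in_gamma(self, scalar_mixture, rng):
        model = _scalar_model()
        z = rng.normal(size=(5, 1))
        base = scalar_mixture.score_samples(z)
        one = biased_log_density(
            scalar_mixture, model.loadings_, BiasSpec({"ph": 2.0}, gamma=1.0), z, ["ph"]
        )
        two = biased_log_density(
            scalar_mixture, model.loadings_, BiasSpec({"ph": 2.0}, gamma=2.0), z, ["ph"]
        )
        assert np.allclose(two - base, 2 * (one - base))

    def test_unknown_phenotype_id(self, scalar_mixture):
        model = _scalar_model()
        with pytest.raises(KeyError):
            biased_log_density(
                scalar_mixture, model.loadings_, BiasSpec({"nope": 1.0}), np.zeros((1, 1)),
                ["ph"],
            )

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            BiasSpec(targets={"ph": 1.0}, gamma=-0.5)


class TestBiasedSampling:
    def test_matches_gaussian_product_posterior(self, scalar_mixture):
        # closed form: N(m0, s0^2) x exp(-gamma (l z - t)^2) is Gaussian with
        # precision 1/s0^2 + 2 gamma l^2
        model = _scalar_model(loading=0.8)
        gamma, target, loading = 2.0, 1.5, 0.8
        mu0 = scalar_mixture.means_[0, 0]
        var0 = scalar_mixture.covariances_[0, 0, 0]
        prec = 1 / var0 + 2 * gamma * loading**2
        post_mean = (mu0 / var0 + 2 * gamma * loading * target) / prec
        post_sd = prec**-0.5
        cfg = MCMCConfig(n_chains=100, n_steps=2000, burn_in=500, thin=10, seed=0,
                         proposal_scale=0.8)
        cohort = sample_biased(scalar_mixture, model, BiasSpec({"ph": target}, gamma), cfg)
        z = cohort.Z[:, 0]
        chains = z.reshape(-1, cfg.n_chains)
        se_mean = chains.mean(axis=0).std(ddof=1) / np.sqrt(cfg.n_chains)
        assert abs(z.mean() - post_mean) < 3 * se_mean
        se_sd = chains.std(axis=0, ddof=1).std(ddof=1) / np.sqrt(cfg.n_chains)
        assert abs(z.std(ddof=1) - post_sd) < 3 * se_sd

    def test_bias_direction(self, scalar_mixture):
        model = _scalar_model()
        cfg = MCMCConfig(n_chains=50, n_steps=800, burn_in=200, thin=10, seed=1,
                         proposal_scale=0.8)
        biased = sample_biased(scalar_mixture, model, BiasSpec({"ph": 3.0}, 2.0), cfg)
        unbiased = sample_biased(scalar_mixture, model, BiasSpec({"ph": 3.0}, 0.0), cfg)
        assert biased.phenotypes_z.mean() > unbiased.phenotypes_z.mean()

    def test_unbiased_chain_matches_direct_sampling(self, scalar_mixture):
        model = _scalar_model()
        cfg = MCMCConfig(n_chains=100, n_steps=1500, burn_in=500, thin=10, seed=2,
                         proposal_scale=0.8)
        cohort = sample_biased(scalar_mixture, model, BiasSpec({"ph": 0.0}, 0.0), cfg)
        z = cohort.Z[:, 0]
        chains = z.reshape(-1, cfg.n_chains)
        se = chains.mean(axis=0).std(ddof=1) / np.sqrt(cfg.n_chains)
        assert abs(z.mean() - scalar_mixture.means_[0, 0]) < 3 * se

    def test_low_acceptance_warns(self, scalar_mixture):
        model = _scalar_model()
        cfg = MCMCConfig(n_chains=10, n_steps=60, burn_in=10, thin=5, seed=3,
                         proposal_scale=500.0)
        with pytest.warns(UserWarning, match="acceptance rate"):
            sample_biased(scalar_mixture, model, BiasSpec({"ph": 0.0}, 2.0), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(burn_in=500, n_steps=100)


class TestPartialPrediction:
    def test_prediction_sums_to_one(self, fitted_joint):
        model, mixture = fitted_joint
        pred, n = predict_from_partial_phenotypes(
            mixture, model, [("p0", 0.0)], n_draws=5000, random_state=0
        )
        assert pred.sum() == pytest.approx(1.0, abs=1e-10)
        assert n > 0

    def test_infinite_tolerance_recovers_cohort_mean(self, fitted_joint):
        model, mixture = fitted_joint
        pred, n = predict_from_partial_phenotypes(
            mixture, model, [("p0", 0.0, np.inf)], n_draws=5000, random_state=0
        )
        cohort = cr.sample_cohort(mixture, model, 5000, random_state=0)
        expected = cohort.compositions.mean(axis=0)
        assert n == 5000
        assert np.allclose(pred, expected / expected.sum(), atol=1e-12)

    def test_zero_matches_raise_with_advice(self, fitted_joint):
        model, mixture = fitted_joint
        with pytest.raises(ValueError, match="n_draws"):
            predict_from_partial_phenotypes(
                mixture, model, [("p0", 50.0, 0.01)], n_draws=200, random_state=0
            )

    def test_own_phenotypes_beat_random_pairs(self, joint_cohort, fitted_joint):
        model, mixture = fitted_joint
        rng = np.random.default_rng(5)
        Zh = rng.normal(size=(10, 3))
        Xh = cr.compose(Zh, joint_cohort.Theta)
        Ph = (Zh @ joint_cohort.L - joint_cohort.phenotypes.mean) / joint_cohort.phenotypes.sd
        gen = cr.sample_cohort(mixture, model, 300, random_state=6)
        wins = 0
        for h in range(10):
            cons = [(f"p{j}", Ph[h, j]) for j in range(3)]
            pred, _ = predict_from_partial_phenotypes(
                mixture, model, cons, n_draws=30_000, random_state=7 + h
            )
            baseline = np.median(
                [cr.bray_curtis(g, Xh[h]) for g in gen.compositions[:100]]
            )
            wins += cr.bray_curtis(pred, Xh[h]) < baseline
        assert wins >= 9


@pytest.fixture(scope="module")
def planted_cohort():
    """Antagonistic-pair community whose log-ratio phenotype pins the
    dominant latent axis; second phenotype is independent noise."""
    rng = np.random.default_rng(2)
    S, K, O = 20_000, 2, 15
    Z = rng.normal(size=(S, K)) * np.array([2.0, 1.0])
    Theta = np.zeros((K, O))
    Theta[0, 0], Theta[0, 1] = -1.2, 1.2
    Theta[1, 2:] = rng.normal(scale=0.5, size=O - 2)
    Theta[0, 2:] = rng.normal(scale=0.2, size=O - 2)
    X = cr.compose(Z, Theta)
    log_ratio = np.log(X[:, 0] / X[:, 1])
    tied = (log_ratio - log_ratio.mean()) / log_ratio.std()
    indep = rng.normal(size=S)
    return GeneratedCohort(
        Z=Z, compositions=X,
        phenotypes_z=np.column_stack([tied, indep]),
        phenotype_ids=["tied", "indep"],
    )


class TestConstraintProfile:
    def test_composition_tied_phenotype_constrains_extremes(self, planted_cohort):
        df = phenotype_constraint_profile(planted_cohort, "tied", random_state=0)
        vals = df["normalized_bc"].to_numpy()
        assert vals[0] < 0.5 and vals[-1] < 0.5

    def test_independent_phenotype_stays_at_one(self, planted_cohort):
        df = phenotype_constraint_profile(planted_cohort, "indep", random_state=0)
        dev = np.abs(df["normalized_bc"] - 1.0) / df["se"]
        assert np.nanmax(dev.to_numpy()) < 3.0

    def test_profile_stable_under_subsampling(self, planted_cohort):
        full = phenotype_constraint_profile(
            planted_cohort, "tied", pairs_per_bin=500, random_state=1
        )
        half = GeneratedCohort(
            Z=planted_cohort.Z[::2],
            compositions=planted_cohort.compositions[::2],
            phenotypes_z=planted_cohort.phenotypes_z[::2],
            phenotype_ids=planted_cohort.phenotype_ids,
        )
        sub = phenotype_constraint_profile(half, "tied", pairs_per_bin=500, random_state=2)
        joint_se = np.sqrt(full["se"] ** 2 + sub["se"] ** 2).to_numpy()
        gap = np.abs(full["normalized_bc"] - sub["normalized_bc"]).to_numpy()
        assert np.all(gap < 5 * joint_se)

    def test_sparse_bins_reported_missing(self):
        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(4), size=30)
        phen = np.concatenate([np.zeros(29), [100.0]])  # one extreme outlier
        cohort = GeneratedCohort(
            Z=np.zeros((30, 1)), compositions=X, phenotypes_z=phen[:, None],
            phenotype_ids=["p"],
        )
        df = phenotype_constraint_profile(cohort, "p", n_bins=5, pairs_per_bin=50,
                                          random_state=0)
        assert df["normalized_bc"].isna().any()


class TestLocalCorrelations:
    def test_homogeneous_effect_gives_slope_near_one(self):
        # phenotype globally linear in one taxon with homogeneous noise
        rng = np.random.default_rng(4)
        S, O = 6000, 8
        X = rng.dirichlet(np.ones(O) * 2, size=S)
        phen = 5 * X[:, 0] + rng.normal(scale=0.02, size=S)
        phen = (phen - phen.mean()) / phen.std()
        cohort = GeneratedCohort(
            Z=np.zeros((S, 1)), compositions=X, phenotypes_z=phen[:, None],
            phenotype_ids=["p"],
        )
        hosts = rng.dirichlet(np.ones(O) * 2, size=12)
        res = local_correlations(cohort, hosts, "p", neighborhood_size=500, random_state=0)
        taxon0_local = res.local[:, 0]
        assert res.global_[0] > 0.8
        assert np.all(taxon0_local > 0.5)

    def test_planted_context_dependence_flips_sign(self):
        # association sign flips between two latent clusters; global ~ 0
        rng = np.random.default_rng(5)
        S, O = 6000, 6
        cluster = rng.integers(0, 2, size=S)
        alpha0 = np.array([2.0, 8.0, 1.0, 1.0, 1.0, 1.0])  # cluster hallmark: taxon 1
        alpha1 = np.array([2.0, 1.0, 8.0, 1.0, 1.0, 1.0])  # cluster hallmark: taxon 2
        X = np.where(
            cluster[:, None] == 0,
            rng.dirichlet(alpha0, size=S),
            rng.dirichlet(alpha1, size=S),
        )
        sign = np.where(cluster == 0, 1.0, -1.0)
        phen = sign * (X[:, 0] - X[:, 0].mean()) * 20 + rng.normal(scale=0.05, size=S)
        phen = (phen - phen.mean()) / phen.std()
        cohort = GeneratedCohort(
            Z=np.zeros((S, 1)), compositions=X, phenotypes_z=phen[:, None],
            phenotype_ids=["p"],
        )
        # hosts anchored inside each cluster
        hosts = np.vstack([X[cluster == 0][:3], X[cluster == 1][:3]])
        res = local_correlations(cohort, hosts, "p", neighborhood_size=300, random_state=0)
        assert abs(res.global_[0]) < 0.3
        assert res.local[:, 0].max() > 0.3 and res.local[:, 0].min() < -0.3

    def test_constant_taxon_flagged_as_zero(self):
        rng = np.random.default_rng(6)
        S = 600
        X = rng.dirichlet(np.ones(3), size=S)
        X = np.column_stack([X * 0.8, np.full(S, 0.2)])  # last taxon constant
        phen = rng.normal(size=S)
        cohort = GeneratedCohort(
            Z=np.zeros((S, 1)), compositions=X, phenotypes_z=phen[:, None],
            phenotype_ids=["p"],
        )
        res = local_correlations(cohort, X[:3], "p", neighborhood_size=100, random_state=0)
        assert np.all(res.local[:, -1] == 0.0)
        assert np.all(res.constant_flags[:, -1])

    def test_neighborhood_size_validation(self, fitted_joint):
        model, mixture = fitted_joint
        cohort = cr.sample_cohort(mixture, model, 100, random_state=0)
        with pytest.raises(ValueError):
            local_correlations(cohort, cohort.compositions[:2], "p0", neighborhood_size=5)


class TestEnrichment:
    def test_zero_hits_gives_one(self):
        assert enrichment_test(0, 10, 5, 100) == pytest.approx(1.0)

    def test_exhaustive_small_case(self):
        # all 5 draws in a 5-member category of a 10-member population:
        # exactly 1 / C(10,5) = 1/252
        assert enrichment_test(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_monotone_in_hits(self):
        ps = [enrichment_test(h, 20, 30, 200) for h in range(0, 10)]
        assert np.all(np.diff(ps) < 0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(6, 5, 10, 100)
        with pytest.raises(ValueError):
            enrichment_test(2, 5, 200, 100)
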