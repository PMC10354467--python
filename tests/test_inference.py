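import math

import numpy as np
import pytest

from tissuefit.inference import (
    PARAM_NAMES,
    ChainSet,
    ExpansionLikelihood,
    PriorBox,
    default_priors,
    gelman_rubin,
    mcmc_sample,
    ml_fit,
    posterior_summary,
)
from tissuefit.observations import ObservationSet, expansion_protocol


@pytest.fixture(scope="module")
def noisy_experiment(porous_modes):
    """Small low-noise synthetic expansion for optimization tests."""
    return expansion_protocol(
        porous_modes,
        sigma=20.0,
        seed=6,
        times=(16.0, 26.0),
        domain_radius_mm=2.6,
        solver_h_mm=0.04,
    )


@pytest.fixture(scope="module")
def wide_priors():
    return PriorBox({n: (1e-2, 1e2) for n in PARAM_NAMES})


class TestLogLikelihood:
    def test_zero_residuals_closed_form(self, coarse_experiment, porous_modes):
        lik = ExpansionLikelihood(
            coarse_experiment.observations, coarse_experiment.initial_state, "porous"
        )
        sigma = 300.0
        n = coarse_experiment.observations.n_obs
        expected = -(n / 2) * math.log(2 * math.pi * sigma**2)
        got = lik.loglike([porous_modes.D, porous_modes.r, porous_modes.K, sigma])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_observation_unit_residual(self, coarse_experiment, porous_modes):
        init = coarse_experiment.initial_state
        probe = ObservationSet(
            positions=[[0.2, 0.0]], times=[16.0], values=[[0.0]], voxel=115.0
        )
        pred = ExpansionLikelihood(probe, init, "porous").predict(porous_modes)[0, 0]
        sigma = 150.0
        obs = ObservationSet(
            positions=[[0.2, 0.0]], times=[16.0], values=[[pred + sigma]], voxel=115.0
        )
        got = ExpansionLikelihood(obs, init, "porous").loglike(
            [porous_modes.D, porous_modes.r, porous_modes.K, sigma]
        )
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi * sigma**2) - 0.5)

    def test_matches_term_by_term_oracle(self, coarse_experiment, porous_modes):
        rng = np.random.default_rng(1)
        full = coarse_experiment.observations
        pick = rng.choice(len(full.positions), 30, replace=False)
        obs = ObservationSet(
            positions=full.positions[pick],
            times=full.times,
            values=full.values[:, pick] + rng.normal(0, 200, (len(full.times), 30)),
            voxel=full.voxel,
        )
        lik = ExpansionLikelihood(obs, coarse_experiment.initial_state, "porous")
        theta = [porous_modes.D, porous_modes.r, porous_modes.K, 250.0]
        pred = lik.predict(porous_modes)
        manual = 0.0
        for j in range(len(obs.times)):
            for i in range(len(obs.positions)):
                manual += math.log(2 * math.pi * 250.0**2)
                manual += ((pred[j, i] - obs.values[j, i]) / 250.0) ** 2
        assert lik.loglike(theta) == pytest.approx(-0.5 * manual, rel=1e-12)

    def test_invariant_under_observation_permutation(
        self, coarse_experiment, porous_modes
    ):
        full = coarse_experiment.observations
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(full.positions))
        shuffled = ObservationSet(
            positions=full.positions[perm],
            times=full.times,
            values=full.values[:, perm],
            voxel=full.voxel,
        )
        theta = [porous_modes.D, porous_modes.r, porous_modes.K, 120.0]
        a = ExpansionLikelihood(full, coarse_experiment.initial_state, "porous").loglike(theta)
        b = ExpansionLikelihood(
            shuffled, coarse_experiment.initial_state, "porous"
        ).loglike(theta)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_observations_rejected(self, coarse_experiment):
        empty = ObservationSet(
            positions=np.zeros((0, 2)), times=[16.0], values=np.zeros((1, 0)), voxel=115.0
        )
        with pytest.raises(ValueError):
            ExpansionLikelihood(empty, coarse_experiment.initial_state, "porous")


class TestMLFit:
    def test_optimum_beats_truth_and_recovers(self, noisy_experiment, porous_modes):
        lik = ExpansionLikelihood(
            noisy_experiment.observations, noisy_experiment.initial_state, "porous"
        )
        fit = ml_fit(lik, default_priors("porous"), n_starts=4, seed=0)
        theta_true = [porous_modes.D, porous_modes.r, porous_modes.K, 20.0]
        assert fit.loglike >= lik.loglike(theta_true)
        for i in range(3):  # D, r, K recovered on low-noise data
            assert fit.theta[i] == pytest.approx(theta_true[i], rel=0.05)
        assert list(fit.table["loglike"]) == sorted(fit.table["loglike"], reverse=True)

    def test_equivalent_to_least_squares(self, noisy_experiment, porous_modes):
        # with sigma fixed the ML argmax minimizes the mean squared error
        lik = ExpansionLikelihood(
            noisy_experiment.observations, noisy_experiment.initial_state, "porous"
        )
        fit = ml_fit(lik, default_priors("porous"), n_starts=2, seed=1)

        def ssr(params):
            return np.sum((lik.predict(params) - noisy_experiment.observations.values) ** 2)

        from tissuefit.params import ModelParams

        best = ModelParams("porous", *fit.theta[:3])
        assert ssr(best) <= ssr(porous_modes)

    def test_rejects_zero_starts(self, wide_priors):
        with pytest.raises(ValueError):
            ml_fit(lambda t: 0.0, wide_priors, n_starts=0)


def _gaussian_target(mu, sd):
    mu, sd = np.asarray(mu), np.asarray(sd)

    def ll(theta):
        x = np.log10(np.asarray(theta, float))
        return float(-0.5 * np.sum(((x - mu) / sd) ** 2))

    return ll


class TestMCMC:
    def test_gaussian_toy_target_moments(self, wide_priors):
        mu = np.array([0.0, 0.3, -0.5, 0.2])
        sd = np.array([0.3, 0.2, 0.4, 0.25])
        chains = mcmc_sample(
            _gaussian_target(mu, sd), wide_priors, n_iter=6000, n_chains=3, seed=3
        )
        import arviz as az

        x = np.log10(chains.pooled())
        x_chains = np.log10(chains.samples[:, -chains.retain :, :])
        for p in range(4):
            ess = float(az.ess(x_chains[:, :, p]))
            se = sd[p] / math.sqrt(ess)
            assert abs(x[:, p].mean() - mu[p]) < 3 * se
            assert x[:, p].std(ddof=1) == pytest.approx(sd[p], rel=0.15)

    def test_prior_only_target_matches_uniform_moments(self, wide_priors):
        # empty data: posterior = prior, uniform on log10 inside the box
        chains = mcmc_sample(
            lambda t: 0.0, wide_priors, n_iter=6000, n_chains=3, seed=4, init_step=0.5
        )
        import arviz as az

        lo, hi = -2.0, 2.0
        x_chains = np.log10(chains.samples[:, -chains.retain :, :])
        x = x_chains.reshape(-1, 4)
        sd_u = (hi - lo) / math.sqrt(12)
        for p in range(4):
            ess = float(az.ess(x_chains[:, :, p]))
            assert abs(x[:, p].mean() - (lo + hi) / 2) < 3 * sd_u / math.sqrt(ess)
            assert x[:, p].std(ddof=1) == pytest.approx(sd_u, rel=0.2)

    def test_same_seed_gives_identical_chains(self, wide_priors):
        ll = _gaussian_target([0.0] * 4, [0.3] * 4)
        a = mcmc_sample(ll, wide_priors, n_iter=500, n_chains=2, seed=7)
        b = mcmc_sample(ll, wide_priors, n_iter=500, n_chains=2, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_rejects_zero_probability_start(self, wide_priors):
        with pytest.raises(ValueError):
            mcmc_sample(
                lambda t: -math.inf,
                wide_priors,
                n_iter=200,
                seed=0,
                start=[1.0, 1.0, 1.0, 1.0],
            )
        with pytest.raises(ValueError):
            mcmc_sample(
                lambda t: 0.0, wide_priors, n_iter=200, seed=0, start=[1e5] * 4
            )

    def test_out_of_box_proposals_rejected(self, wide_priors):
        chains = mcmc_sample(
            lambda t: 0.0, wide_priors, n_iter=2000, n_chains=2, seed=5, init_step=1.0
        )
        x = np.log10(chains.samples)
        assert x.min() >= -2.0 and x.max() <= 2.0


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        one = rng.normal(0, 1, (2000, 4))
        arr = np.stack([one, one, one])
        rhat = gelman_rubin(arr)
        for v in rhat.values():
            assert v == pytest.approx(1.0, abs=0.01)

    def test_independent_draws_converged_and_matches_arviz(self):
        import arviz as az

        rng = np.random.default_rng(1)
        arr = rng.normal(5, 2, (4, 2000, 1))
        rhat = gelman_rubin(arr)["D"]
        assert rhat < 1.05
        ref = float(az.rhat(arr[:, :, 0], method="split"))
        assert rhat == pytest.approx(ref, abs=1e-6)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (1, 2000, 1))
        b = rng.normal(10, 1, (1, 2000, 1))
        arr = np.concatenate([a, b])
        rhat = gelman_rubin(arr)["D"]
        assert rhat > 1.5
        # brute-force split-Rhat formula, written independently
        seqs = np.concatenate([arr[:, :1000, 0], arr[:, 1000:, 0]])
        n = seqs.shape[1]
        W = np.mean([s.var(ddof=1) for s in seqs])
        B_n = np.var([s.mean() for s in seqs], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B_n) / W)
        assert rhat == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 4)))


class TestPosteriorSummary:
    def _chainset(self, samples):
        c, n, d = samples.shape
        return ChainSet(
            samples,
            np.zeros((c, n)),
            np.ones((c, n), dtype=bool),
            retain=n,
            param_names=PARAM_NAMES[:d],
        )

    def test_constant_chain(self):
        arr = np.full((2, 500, 4), 3.7)
        df = posterior_summary(self._chainset(arr))
        assert np.allclose(df["mode"], 3.7)
        assert np.allclose(df["sd"], 0.0)

    def test_gaussian_draws_recovered(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(10.0, 2.0, (3, 3000, 4))
        df = posterior_summary(self._chainset(arr))
        n = 9000
        assert np.allclose(df["mean"], 10.0, atol=3 * 2.0 / math.sqrt(n))
        assert np.allclose(df["sd"], 2.0, rtol=0.05)
        assert np.allclose(df["mode"], 10.0, atol=0.3)
        assert np.all(df["ci_2.5%"] < 10.0) and np.all(df["ci_97.5%"] > 10.0)

    def test_insufficient_retained_draws(self):
        arr = np.zeros((2, 100, 4))
        with pytest.raises(ValueError):
            posterior_summary(self._chainset(arr), retain=500)


class TestPriorBox:
    def test_default_boxes_contain_published_modes(self):
        lin = default_priors("linear").bounds
        por = default_priors("porous").bounds
        assert lin["D"][0] < 1073.0 < lin["D"][1]
        assert por["D"][0] < 1.18 < por["D"][1]
        for fam, K in ((lin, 5113.0), (por, 5319.0)):
            assert fam["K"][0] < K < fam["K"][1]

    def test_rejects_malformed_bounds(self):
        with pytest.raises(ValueError):
            PriorBox({"D": (10.0, 1.0), "r": (1, 2), "K": (1, 2), "sigma": (1, 2)})
        with pytest.raises(ValueError):
            PriorBox({"r": (1, 2), "K": (1, 2), "sigma": (1, 2)})
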