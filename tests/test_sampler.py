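"""Metropolis-within-Gibbs chain: proposals, acceptance ratio, chain law."""

import math

import numpy as np
import pytest
import scipy.stats

from cellmix import (
    EPS_N,
    AggregateObservation,
    CellLineProfile,
    InvalidStateError,
    PriorConfig,
    SamplerConfig,
    acceptance_ratio,
    aggregate_log_likelihood,
    initial_counts,
    propose,
    run_chain,
)


@pytest.fixture
def toy_1d():
    """n = m = 1 system: one line with mu = 100, sigma = 100, e_sum = 50000."""
    profile = CellLineProfile(["A"], [[100.0]], [[100.0]], ["x"])
    obs = AggregateObservation([50000.0], ["x"])
    return obs, profile


class TestPropose:
    def test_degenerate_limit_returns_current(self, rng):
        assert propose(42.0, 1e-12, rng) == pytest.approx(42.0, abs=1e-10)

    def test_empirical_mean_matches_uniform_moments(self, rng):
        delta, current, n = 5.0, 100.0, 100_000
        draws = np.array([propose(current, delta, rng) for _ in range(n)])
        # uniform on (c-d, c+d): mean c, sd d/sqrt(3)
        assert abs(draws.mean() - current) < 3 * delta / math.sqrt(3 * n)
        assert draws.min() >= current - delta and draws.max() <= current + delta

    def test_proposal_increment_is_symmetric(self, rng):
        draws = np.array([propose(0.0, 2.0, rng) for _ in range(50_000)])
        # distribution of (proposal - current) matches that of (current - proposal)
        ks = scipy.stats.ks_2samp(draws, -draws)
        assert ks.pvalue > 0.01


class TestAcceptanceRatio:
    def test_identical_states_give_unit_ratio(self, small_obs, small_profile):
        c = np.array([100.0, 200.0, 300.0])
        r = acceptance_ratio(c, c, small_obs, small_profile, PriorConfig())
        assert r == pytest.approx(1.0)

    def test_exactly_independent_of_prior_bound(self, small_obs, small_profile):
        cur = np.array([100.0, 200.0, 300.0])
        prop = np.array([100.0, 230.0, 300.0])
        r_small = acceptance_ratio(prop, cur, small_obs, small_profile,
                                   PriorConfig(upper_bound=1e4))
        r_large = acceptance_ratio(prop, cur, small_obs, small_profile,
                                   PriorConfig(upper_bound=1e8))
        assert r_small == r_large  # bitwise equal, not approximately

    def test_matches_brute_force_likelihood_ratio(self):
        # independent oracle: ratio of products of scipy normal pdfs (n=2, m=2)
        profile = CellLineProfile(
            ["A", "B"], [[100.0, 300.0], [400.0, 150.0]], [[20.0, 30.0], [40.0, 15.0]],
            ["x", "y"],
        )
        obs = AggregateObservation([30000.0, 25000.0], ["x", "y"])
        cur = np.array([60.0, 40.0])
        prop = np.array([60.0, 55.0])

        def density(counts):
            val = 1.0
            for j in range(2):
                m = counts @ profile.mu_hat[:, j]
                s = math.sqrt(counts @ profile.sigma_hat[:, j] ** 2)
                val *= scipy.stats.norm.pdf(obs.e_sum[j], m, s)
            return val

        r = acceptance_ratio(prop, cur, obs, profile, PriorConfig())
        assert r == pytest.approx(density(prop) / density(cur), rel=1e-9)

    def test_out_of_support_proposal_rejected(self, small_obs, small_profile):
        cur = np.array([100.0, 200.0, 300.0])
        prop = np.array([-5.0, 200.0, 300.0])
        assert acceptance_ratio(prop, cur, small_obs, small_profile, PriorConfig()) == 0.0

    def test_corrupt_current_state_raises(self, small_obs, small_profile):
        cur = np.array([-100.0, 200.0, 300.0])
        with pytest.raises(InvalidStateError):
            acceptance_ratio(cur.copy(), cur, small_obs, small_profile, PriorConfig())


class TestInitialCounts:
    def test_nnls_recovers_exact_mean_solution(self, small_profile, small_obs):
        # the observation sits exactly at counts [100, 200, 300]
        start = initial_counts(small_obs, small_profile, PriorConfig())
        e_fit = start @ small_profile.mu_hat
        assert np.allclose(e_fit, small_obs.e_sum, rtol=1e-4)

    def test_flat_fallback_matches_total_signal(self, small_profile, small_obs):
        start = initial_counts(small_obs, small_profile, PriorConfig(), strategy="flat")
        expected = small_obs.e_sum.sum() / small_profile.mu_hat.sum()
        assert np.allclose(start, expected)


class TestRunChain:
    def test_same_seed_identical_chains(self, toy_1d):
        obs, profile = toy_1d
        config = SamplerConfig(n_burnin=100, n_samples=200, seed=5)
        c1 = run_chain(obs, profile, config)
        c2 = run_chain(obs, profile, config)
        assert np.array_equal(c1.samples, c2.samples)
        assert np.array_equal(c1.acceptance_rate, c2.acceptance_rate)

    def test_samples_respect_support(self, toy_1d):
        obs, profile = toy_1d
        config = SamplerConfig(n_burnin=200, n_samples=500, seed=3,
                               prior=PriorConfig(upper_bound=2000.0))
        chain = run_chain(obs, profile, config)
        assert np.all(chain.samples >= EPS_N)
        assert np.all(chain.samples <= 2000.0)
        assert chain.samples.shape == (500, 1)

    def test_thinning_keeps_every_kth_sweep(self, toy_1d):
        obs, profile = toy_1d
        config = SamplerConfig(n_burnin=50, n_samples=100, thin=5, seed=9)
        chain = run_chain(obs, profile, config)
        assert chain.n_retained == 100

    def test_chain_is_exact_metropolis_replay(self, toy_1d):
        # replay the RNG stream and re-derive every retained state from the
        # public propose/acceptance_ratio operations: accept iff u < min(r,1)
        obs, profile = toy_1d
        config = SamplerConfig(delta=30.0, n_burnin=20, n_samples=50, seed=11,
                               init="flat")
        chain = run_chain(obs, profile, config)
        rng = np.random.default_rng(11)
        state = initial_counts(obs, profile, config.prior, "flat")
        expected = []
        for sweep in range(70):
            prop_val = propose(state[0], 30.0, rng)
            u = rng.random()
            if EPS_N <= prop_val <= config.prior.upper_bound:
                r = acceptance_ratio(
                    np.array([prop_val]), state, obs, profile, config.prior
                )
                if u < min(r, 1.0):
                    state = np.array([prop_val])
            if sweep >= 20:
                expected.append(state[0])
        assert np.allclose(chain.samples[:, 0], expected, rtol=1e-12)

    def test_marginal_matches_grid_posterior(self, toy_1d):
        # exhaustive oracle: normalize exp(log-likelihood) on a fine grid and
        # compare with the chain histogram in total variation
        obs, profile = toy_1d
        config = SamplerConfig(n_burnin=2000, n_samples=20000, seed=17)
        chain = run_chain(obs, profile, config)
        edges = np.linspace(250.0, 850.0, 121)
        centers = 0.5 * (edges[:-1] + edges[1:])
        logs = np.array(
            [aggregate_log_likelihood(obs, [n], profile) for n in centers]
        )
        post = np.exp(logs - logs.max())
        post /= post.sum()
        hist, _ = np.histogram(chain.samples[:, 0], bins=edges)
        emp = hist / chain.n_retained
        tv = 0.5 * np.abs(post - emp).sum()
        assert tv < 0.05

    def test_adaptive_acceptance_rate_is_sane(self):
        # 10-line / 10-attribute cyclic design: post-burn-in acceptance per
        # component should be neither tiny nor near-certain
        from cellmix import SimulationConfig, simulate_dataset

        _, profile, obs = simulate_dataset(SimulationConfig(seed=12))
        chain = run_chain(obs, profile, SamplerConfig(n_burnin=1500, n_samples=2000,
                                                      seed=12))
        assert np.all(chain.acceptance_rate >= 0.1)
        assert np.all(chain.acceptance_rate <= 0.7)
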