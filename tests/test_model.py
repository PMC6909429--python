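"""Core Bayes-hypergeometric model: likelihood, posterior, N2 probability."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nodalstage import (
    InferenceError,
    InputDomainError,
    ModelConfig,
    Observation,
    accuracy,
    feasible_range,
    hypergeom_pmf,
    point_prior,
    posterior,
    prob_at_least,
    uniform_prior,
)

from conftest import random_prior
from oracles import brute_posterior, brute_pmf


class TestHypergeomPmf:
    @pytest.mark.parametrize(
        ("n", "m", "N", "M", "expected"),
        [
            (15, 3, 15, 3, 1.0),  # complete sampling observes every node
            (1, 1, 15, 3, 3 / 15),  # one draw hits one of 3 involved nodes
            (4, 2, 15, 2, 78 / 1365),  # frozen from brute-force enumeration
            (2, 2, 15, 1, 0.0),  # cannot observe more positives than exist
            (5, 0, 15, 11, 0.0),  # 4 uninvolved nodes cannot fill 5 draws
            (15, 15, 15, 15, 1.0),
            (4, 0, 15, 0, 1.0),
        ],
    )
    def test_examples(self, n, m, N, M, expected):
        assert hypergeom_pmf(n, m, N, M) == pytest.approx(expected, abs=1e-15)

    def test_infeasible_combinations_are_exactly_zero(self):
        assert hypergeom_pmf(2, 2, 15, 1) == 0.0
        assert hypergeom_pmf(13, 1, 15, 4) == 0.0

    @pytest.mark.parametrize(
        "bad_args",
        [(5, 1, 4, 2), (3, 4, 15, 5), (2, 1, 15, 16), (-1, 0, 15, 3), (2, -1, 15, 3)],
    )
    def test_out_of_domain_arguments_raise(self, bad_args):
        with pytest.raises(InputDomainError):
            hypergeom_pmf(*bad_args)

    def test_matches_subset_enumeration_and_scipy(self):
        """Exhaustive cross-check of every (n, m, M) combination at N=7
        against subset counting and scipy's hypergeometric pmf."""
        N = 7
        for n in range(N + 1):
            for M in range(N + 1):
                for m in range(n + 1):
                    ours = hypergeom_pmf(n, m, N, M)
                    assert ours == pytest.approx(brute_pmf(n, m, N, M), abs=1e-12)
                    theirs = scipy.stats.hypergeom.pmf(m, N, M, n)
                    assert ours == pytest.approx(float(theirs), abs=1e-12)


class TestPosterior:
    def test_degenerate_prior_is_returned_unchanged(self, config):
        post = posterior(point_prior(5), Observation(n=6, m=2), config)
        assert post.prob(5) == 1.0

    def test_support_is_truncated_by_unexamined_count(self, config):
        # 13 of 15 examined: at most 2 hidden involved nodes remain
        post = posterior(uniform_prior(config), Observation(n=13, m=1), config)
        for M in range(4, 16):
            assert post.prob(M) == 0.0
        assert post.prob(0) == 0.0  # below the observed count

    def test_hand_computed_two_point_prior(self, config):
        # q uniform on {1, 2}; a single draw hitting a positive node weighs
        # the M=2 hypothesis twice as heavily (2/15 vs 1/15)
        prior = {1: 0.5, 2: 0.5}
        post = posterior(prior, Observation(n=1, m=1), config)
        assert post.prob(1) == pytest.approx(1 / 3, abs=1e-12)
        assert post.prob(2) == pytest.approx(2 / 3, abs=1e-12)

    def test_incompatible_prior_raises_naming_observation(self, config):
        with pytest.raises(InferenceError, match=r"n=5, m=2"):
            posterior(point_prior(1), Observation(n=5, m=2), config)

    def test_observation_beyond_pool_raises(self, config):
        with pytest.raises(InputDomainError):
            posterior(uniform_prior(config), Observation(n=16, m=1), config)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 15),
        data=st.data(),
    )
    def test_normalization_and_truncation_properties(self, seed, n, data, config):
        """For any prior and feasible observation: probabilities sum to 1
        within 1e-12 and vanish exactly outside [m, m + N - n]."""
        m = data.draw(st.integers(0, min(n, 3)))
        prior = random_prior(np.random.default_rng(seed))
        obs = Observation(n=n, m=m)
        try:
            post = posterior(prior, obs, config)
        except InferenceError:
            return  # prior mass happened to miss the feasible window
        assert abs(sum(post.probs) - 1.0) < 1e-12
        lo, hi = feasible_range(obs, config)
        for M in range(16):
            if M < lo or M > hi:
                assert post.prob(M) == 0.0

    def test_matches_exhaustive_enumeration_for_small_pools(self, rng):
        """Oracle equivalence: posterior equals full (M, subset) enumeration
        for pool sizes up to 8, to 1e-12."""
        for N in (5, 6, 8):
            config = ModelConfig(total_nodes=N, n2_cutoff=min(4, N))
            for trial in range(3):
                prior = random_prior(rng, total_nodes=N)
                n = int(rng.integers(1, N + 1))
                for m in range(n + 1):
                    obs = Observation(n=n, m=m)
                    try:
                        post = posterior(prior, obs, config)
                    except InferenceError:
                        continue
                    expected = brute_posterior(prior.probs, n, m, N)
                    np.testing.assert_allclose(post.probs, expected, atol=1e-12)


class TestAccuracyAndProbAtLeast:
    def test_complete_dissection_accuracy_is_exactly_one(self, config, rng):
        prior = random_prior(rng)
        for m in range(4):
            if prior.probs[m] > 0:
                assert accuracy(prior, Observation(n=15, m=m), config) == 1.0

    def test_point_prior_accuracy_is_one(self, config):
        assert accuracy(point_prior(2), Observation(n=5, m=2), config) == 1.0

    def test_n2_impossible_when_too_few_nodes_unexamined(self, config, rng):
        """prob_at_least(k=4) is exactly 0 when m + (N - n) < 4, whatever
        the prior — the key analytic zeros at (13, 1) and (14, 2)."""
        for _ in range(5):
            prior = random_prior(rng, support=(0, 15))
            assert prob_at_least(prior, Observation(13, 1), 4, config) == 0.0
            assert prob_at_least(prior, Observation(14, 2), 4, config) == 0.0
            assert prob_at_least(prior, Observation(15, 3), 4, config) == 0.0

    def test_complement_identity_for_three_observed_positives(self, config, rng):
        """With m=3, {true count is exactly 3} and {true count >= 4} are
        complementary events; the identity must be bitwise exact."""
        for n in range(3, 16):
            prior = random_prior(rng, support=(1, 15))
            obs = Observation(n=n, m=3)
            assert prob_at_least(prior, obs, 4, config) == 1.0 - accuracy(prior, obs, config)

    def test_prior_confined_below_cutoff_rules_out_n2_everywhere(self, config, rng):
        prior = random_prior(rng, support=(0, 3))
        for n in range(1, 16):
            for m in range(min(n, 3) + 1):
                try:
                    assert prob_at_least(prior, Observation(n, m), 4, config) == 0.0
                except InferenceError:
                    pass

    def test_small_pool_cumulative_matches_enumeration(self):
        """prob_at_least against exhaustive joint enumeration on a 6-node
        pool with a uniform prior."""
        N, n, m, k = 6, 2, 1, 2
        config = ModelConfig(total_nodes=N, n2_cutoff=k)
        prior = np.full(N + 1, 1 / (N + 1))
        expected = brute_posterior(prior, n, m, N)[k:].sum()
        got = prob_at_least(prior, Observation(n, m), k, config)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_default_cutoff_is_n2(self, config, rng):
        prior = random_prior(rng, support=(1, 15))
        obs = Observation(n=8, m=2)
        assert prob_at_least(prior, obs, config=config) == prob_at_least(
            prior, obs, 4, config
        )
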