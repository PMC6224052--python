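"""Mixture EM: E/M steps, monotonicity, determinism, dual-route consistency."""

import numpy as np
import pytest

from trajmix.hmm import HMMParams, forward_backward, log_likelihood
from trajmix.mixture import (
    MHMMParams,
    assign_clusters,
    e_step,
    fit_em,
    m_step,
    total_log_likelihood,
)

from oracles import random_hmm


def random_mhmm(rng, M, N, K, weights=None):
    comps = tuple(
        HMMParams(*random_hmm(rng, N, K)) for _ in range(M)
    )
    w = np.asarray(weights) if weights is not None else rng.dirichlet(np.ones(M) * 2)
    return MHMMParams(weights=w, components=comps)


def random_series(rng, n, K, tmin=2, tmax=12):
    return [
        rng.integers(0, K, size=rng.integers(tmin, tmax + 1)) for _ in range(n)
    ]


class TestEStep:
    def test_single_component_posterior_is_one(self, rng):
        mhmm = random_mhmm(rng, 1, 2, 4)
        assignments, _ = e_step(random_series(rng, 10, 4), mhmm)
        for a in assignments:
            assert a.posterior.tolist() == [1.0]

    def test_identical_components_posterior_equals_weights(self, rng):
        comp = HMMParams(*random_hmm(rng, 2, 4))
        mhmm = MHMMParams(weights=[0.7, 0.3], components=(comp, comp))
        assignments, _ = e_step(random_series(rng, 8, 4), mhmm)
        for a in assignments:
            np.testing.assert_allclose(a.posterior, [0.7, 0.3], atol=1e-12)

    def test_disjoint_supports_give_hard_posteriors(self):
        lo = HMMParams([1.0], [[1.0]], [[0.5, 0.5, 0.0, 0.0]])
        hi = HMMParams([1.0], [[1.0]], [[0.0, 0.0, 0.5, 0.5]])
        mhmm = MHMMParams(weights=[0.5, 0.5], components=(lo, hi))
        assignments, _ = e_step([[0, 1, 0], [3, 2, 2]], mhmm)
        np.testing.assert_allclose(assignments[0].posterior, [1, 0], atol=1e-12)
        np.testing.assert_allclose(assignments[1].posterior, [0, 1], atol=1e-12)

    def test_impossible_series_raises_with_position(self, rng):
        comp = HMMParams([1.0], [[1.0]], [[0.5, 0.5, 0.0]])
        mhmm = MHMMParams(weights=[1.0], components=(comp,))
        with pytest.raises(ValueError, match="positions \\[1\\]"):
            e_step([[0, 1], [2, 0]], mhmm)

    def test_cluster_posteriors_match_per_sequence_likelihoods(self, rng):
        """Batched scaled-linear route agrees with the log-space engine."""
        mhmm = random_mhmm(rng, 3, 3, 5)
        series = random_series(rng, 20, 5)
        assignments, _ = e_step(series, mhmm)
        for x, a in zip(series, assignments):
            logj = np.log(mhmm.weights) + np.array(
                [log_likelihood(x, c) for c in mhmm.components]
            )
            expected = np.exp(logj - np.logaddexp.reduce(logj))
            np.testing.assert_allclose(a.posterior, expected, atol=1e-9)

    def test_suffstats_match_forward_backward_route(self, rng):
        """Expected emission/transition counts equal gamma/xi sums weighted by
        cluster responsibilities, computed independently per sequence."""
        mhmm = random_mhmm(rng, 2, 2, 4)
        series = random_series(rng, 6, 4)
        assignments, stats = e_step(series, mhmm)
        M, N, K = 2, 2, 4
        init = np.zeros((M, N))
        trans = np.zeros((M, N, N))
        emis = np.zeros((M, N, K))
        for x, a in zip(series, assignments):
            for m in range(M):
                gamma, xi, _ = forward_backward(x, mhmm.components[m])
                r = a.posterior[m]
                init[m] += r * gamma[0]
                trans[m] += r * xi.sum(axis=0)
                for t, v in enumerate(x):
                    emis[m, :, v] += r * gamma[t]
        np.testing.assert_allclose(stats.initial, init, atol=1e-8)
        np.testing.assert_allclose(stats.transition, trans, atol=1e-8)
        np.testing.assert_allclose(stats.emission, emis, atol=1e-8)


class TestMStep:
    def test_supervised_single_sequence_recovers_frequencies(self, rng):
        from trajmix.mixture import SuffStats

        # hard statistics along a known path: B rows = empirical frequencies
        stats = SuffStats(
            resp_sum=np.array([1.0]),
            initial=np.array([[1.0, 0.0]]),
            transition=np.array([[[2.0, 1.0], [1.0, 1.0]]]),
            emission=np.array([[[3.0, 1.0, 0.0], [0.0, 1.0, 1.0]]]),
            loglik=0.0,
        )
        params = m_step(stats)
        np.testing.assert_allclose(
            params.components[0].emission[0], [0.75, 0.25, 0.0], atol=1e-6
        )
        np.testing.assert_allclose(
            params.components[0].transition, [[2 / 3, 1 / 3], [0.5, 0.5]]
        )

    def test_em_step_does_not_decrease_likelihood(self, rng):
        series = random_series(rng, 15, 4)
        mhmm = random_mhmm(rng, 2, 2, 4)
        before = total_log_likelihood(series, mhmm)
        _, stats = e_step(series, mhmm)
        after = total_log_likelihood(series, m_step(stats))
        assert after >= before - 1e-6

    def test_empty_statistics_raise(self):
        from trajmix.mixture import SuffStats

        stats = SuffStats(
            resp_sum=np.zeros(1),
            initial=np.zeros((1, 2)),
            transition=np.zeros((1, 2, 2)),
            emission=np.zeros((1, 2, 3)),
            loglik=0.0,
        )
        with pytest.raises(ValueError):
            m_step(stats)


class TestTotalLogLikelihood:
    def test_single_component_reduces_to_sum(self, rng):
        comp = HMMParams(*random_hmm(rng, 2, 4))
        mhmm = MHMMParams(weights=[1.0], components=(comp,))
        series = random_series(rng, 5, 4)
        expected = sum(log_likelihood(x, comp) for x in series)
        assert total_log_likelihood(series, mhmm) == pytest.approx(expected, abs=1e-8)

    def test_two_series_toy_matches_hand_logsumexp(self):
        lo = HMMParams([1.0], [[1.0]], [[0.8, 0.2]])
        hi = HMMParams([1.0], [[1.0]], [[0.2, 0.8]])
        mhmm = MHMMParams(weights=[0.6, 0.4], components=(lo, hi))
        series = [[0, 0], [1, 1]]
        expected = np.log(0.6 * 0.64 + 0.4 * 0.04) + np.log(0.6 * 0.04 + 0.4 * 0.64)
        assert total_log_likelihood(series, mhmm) == pytest.approx(expected, abs=1e-10)

    def test_zero_weight_component_is_ignored(self, rng):
        comp = HMMParams(*random_hmm(rng, 2, 3))
        impossible = HMMParams([1.0, 0.0], [[1, 0], [0, 1]], [[1.0, 0, 0], [1.0, 0, 0]])
        series = [[1, 2], [2, 1]]
        alone = MHMMParams(weights=[1.0], components=(comp,))
        padded = MHMMParams(weights=[1.0, 0.0], components=(comp, impossible))
        assert total_log_likelihood(series, padded) == pytest.approx(
            total_log_likelihood(series, alone), abs=1e-10
        )

    def test_permutation_invariance(self, rng):
        mhmm = random_mhmm(rng, 3, 2, 4)
        series = random_series(rng, 10, 4)
        perm = [2, 0, 1]
        permuted = MHMMParams(
            weights=mhmm.weights[perm],
            components=tuple(mhmm.components[i] for i in perm),
        )
        assert total_log_likelihood(series, permuted) == pytest.approx(
            total_log_likelihood(series, mhmm), abs=1e-9
        )


class TestFitEM:
    def test_single_cluster_trace_monotone_and_converged(self, rng):
        comp = HMMParams(*random_hmm(rng, 2, 5))
        series = random_series(rng, 40, 5, tmin=3, tmax=15)
        res = fit_em(series, 1, 2, support_size=5, restarts=2, seed=1)
        assert res.converged
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_same_seed_identical_result(self, rng):
        series = random_series(rng, 30, 4, tmin=3, tmax=10)
        a = fit_em(series, 2, 2, support_size=4, restarts=2, seed=7)
        b = fit_em(series, 2, 2, support_size=4, restarts=2, seed=7)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
        for ca, cb in zip(a.params.components, b.params.components):
            np.testing.assert_array_equal(ca.emission, cb.emission)

    def test_clusters_ordered_by_descending_size(self, rng):
        from trajmix.synthetic import default_scenario, sample_mhmm

        series, _, _ = sample_mhmm(default_scenario(), 150, seed=5)
        res = fit_em(series, 2, 2, support_size=25, restarts=2, seed=5)
        hard = np.array([a.hard_label for a in res.assignments])
        sizes = np.bincount(hard, minlength=2)
        assert sizes[0] >= sizes[1]

    def test_requires_enough_series(self):
        with pytest.raises(ValueError):
            fit_em([[1, 2]], 2, 2, support_size=3)


class TestAssignClusters:
    def test_matches_e_step_posteriors(self, rng):
        mhmm = random_mhmm(rng, 2, 2, 4)
        series = random_series(rng, 10, 4)
        a1 = assign_clusters(series, mhmm)
        a2, _ = e_step(series, mhmm)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.posterior, y.posterior)
            assert x.hard_label == y.hard_label
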