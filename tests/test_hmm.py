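"""Core HMM machinery against closed forms and brute-force enumeration."""

import math

import numpy as np
import pytest

from zfsleep.hmm import (HMMParams, PoissonHMM, emission_logpmf,
                         log_likelihood, posteriors, sample,
                         stationary_distribution, viterbi)

from _oracles import (enumerate_loglik, enumerate_posteriors,
                      enumerate_viterbi, random_instance)


def _params(pi, A, lam, w=None):
    return HMMParams(np.asarray(pi, float), np.asarray(A, float),
                     np.asarray(lam, float),
                     None if w is None else np.asarray(w, float))


class TestEmission:
    def test_poisson_zero_count(self):
        assert emission_logpmf(0, 1.0) == pytest.approx(math.log(0.367879441), abs=1e-8)

    def test_zip_zero_count(self):
        # w + (1-w) e^{-1} with w = 0.5
        assert emission_logpmf(0, 1.0, 0.5) == pytest.approx(math.log(0.6839397206), abs=1e-9)

    def test_matches_direct_factorial_evaluation(self):
        lam = 4.07
        direct = math.log(math.exp(-lam) * lam**3 / math.factorial(3))
        assert emission_logpmf(3, lam) == pytest.approx(direct, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            emission_logpmf(-1, 1.0)

    def test_zip_with_zero_weight_is_plain_poisson(self, rng):
        for x in range(0, 20):
            assert emission_logpmf(x, 2.3, 0.0) == pytest.approx(
                emission_logpmf(x, 2.3), abs=1e-12)


class TestLogLikelihood:
    def test_single_state_closed_form(self):
        p = _params([1.0], [[1.0]], [1.0])
        # ln e^{-1} + ln(e^{-1} * 1) = -2
        assert log_likelihood(p, np.array([0, 1])) == pytest.approx(-2.0, abs=1e-10)

    def test_matches_path_enumeration(self, rng):
        for _ in range(5):
            p, obs = random_instance(rng, 2, 6)
            assert log_likelihood(p, obs) == pytest.approx(
                enumerate_loglik(p, obs), abs=1e-10)

    def test_absorbing_initial_state(self):
        p = _params([1.0, 0.0], [[1.0, 0.0], [0.0, 1.0]], [0.5, 5.0])
        obs = np.array([0, 2, 1])
        expected = sum(emission_logpmf(x, 0.5) for x in obs)
        assert log_likelihood(p, obs) == pytest.approx(expected, abs=1e-10)


class TestPosteriors:
    def test_single_state_all_ones(self):
        p = _params([1.0], [[1.0]], [2.0])
        gamma = posteriors(p, np.array([1, 2, 3]))
        assert np.allclose(gamma, 1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(5):
            p, obs = random_instance(rng, 2, 6)
            assert np.allclose(posteriors(p, obs), enumerate_posteriors(p, obs),
                               atol=1e-10)

    def test_separated_rates_give_confident_posterior(self):
        p = _params([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [0.01, 50.0])
        gamma = posteriors(p, np.array([0]))
        assert gamma[0, 0] > 0.999

    def test_rows_sum_to_one(self, rng):
        p, obs = random_instance(rng, 3, 40)
        assert np.allclose(posteriors(p, obs).sum(axis=1), 1.0, atol=1e-9)


class TestViterbi:
    def test_single_state(self):
        p = _params([1.0], [[1.0]], [2.0])
        assert viterbi(p, np.array([4, 4])).tolist() == [0, 0]

    def test_matches_enumeration(self, rng):
        for _ in range(5):
            p, obs = random_instance(rng, 3, 6)
            assert np.array_equal(viterbi(p, obs), enumerate_viterbi(p, obs))

    def test_near_identity_transitions_follow_nearest_rate(self):
        eps = 1e-3  # switch cost ln(eps) is cheaper than emitting 0 at rate 10
        A = np.array([[1 - eps, eps], [eps, 1 - eps]])
        p = _params([0.5, 0.5], A / A.sum(1, keepdims=True), [0.5, 10.0])
        obs = np.array([0, 0, 12, 11, 0])
        path = viterbi(p, obs)
        assert path.tolist() == [0, 0, 1, 1, 0]
        assert np.array_equal(path, enumerate_viterbi(p, obs))


class TestSample:
    def test_absorbing_chain_constant_path(self):
        p = _params([1.0, 0.0], np.eye(2), [1.0, 5.0])
        _, states, _ = sample(p, 50, seed=0)
        assert np.all(states == 0)

    def test_floored_rate_emits_near_zero(self):
        p = _params([1.0], [[1.0]], [1e-3])
        obs, _, _ = sample(p, 2000, seed=1)
        assert obs.mean() < 0.01

    def test_reproducible_and_clipped(self, wt_gen):
        o1, s1, c1 = sample(wt_gen, 500, seed=42)
        o2, s2, c2 = sample(wt_gen, 500, seed=42)
        assert np.array_equal(o1, o2) and np.array_equal(s1, s2) and c1 == c2
        assert o1.max() <= 60

    def test_empirical_transition_frequencies(self):
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        p = _params([0.5, 0.5], A, [1.0, 5.0])
        _, states, _ = sample(p, 100_000, seed=7)
        for i in range(2):
            mask = states[:-1] == i
            n = int(mask.sum())
            freq = np.mean(states[1:][mask] == 0)
            se = math.sqrt(A[i, 0] * (1 - A[i, 0]) / n)
            assert abs(freq - A[i, 0]) < 3 * se


class TestStationary:
    def test_symmetric_chain(self):
        assert np.allclose(stationary_distribution([[0.9, 0.1], [0.1, 0.9]]),
                           [0.5, 0.5])

    def test_balance_equations(self):
        assert np.allclose(stationary_distribution([[0.5, 0.5], [0.25, 0.75]]),
                           [1 / 3, 2 / 3], atol=1e-12)

    def test_matches_power_iteration(self, rng):
        A = rng.dirichlet(np.ones(4), size=4)
        P = np.linalg.matrix_power(A, 4096)
        assert np.allclose(stationary_distribution(A), P[0], atol=1e-8)

    def test_reducible_chain_needs_fallback(self):
        I = np.eye(2)
        with pytest.raises(ValueError, match="simple"):
            stationary_distribution(I)
        freq = stationary_distribution(I, states=np.array([0, 0, 0, 1]))
        assert np.allclose(freq, [0.75, 0.25])

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution([[0.5, 0.2], [0.3, 0.7]])


class TestFit:
    def test_single_state_recovers_sample_mean(self, rng):
        obs = rng.poisson(3.7, size=400)
        res = PoissonHMM(obs, 1).fit(seed=0)
        assert res.params.lambdas[0] == pytest.approx(obs.mean(), rel=1e-6)

    def test_two_state_recovery_within_3se(self):
        truth = _params([0.5, 0.5], [[0.95, 0.05], [0.05, 0.95]], [0.5, 6.0])
        obs, states, _ = sample(truth, 5000, seed=3)
        res = PoissonHMM(obs, 2).fit(seed=5, n_restarts=5)
        lam = np.sort(res.params.lambdas)
        for k, lam_k in enumerate(np.sort(truth.lambdas)):
            n_k = (states == k).sum()
            se = math.sqrt(lam_k / n_k)
            assert abs(lam[k] - lam_k) < 3 * se

    def test_loglik_trail_nondecreasing_on_random_instances(self, rng):
        for i in range(20):
            p, _ = random_instance(rng, 2, 3)
            obs, _, _ = sample(p, 200, seed=100 + i)
            res = PoissonHMM(obs, 2).fit(seed=i)
            assert np.all(np.diff(res.loglik_trail) >= -1e-8)

    def test_multisequence_pools_without_cross_transitions(self, rng):
        truth = _params([1.0, 0.0], [[0.9, 0.1], [0.1, 0.9]], [0.5, 6.0])
        seqs = [sample(truth, 800, seed=s)[0] for s in range(4)]
        res = PoissonHMM(seqs, 2).fit(seed=0, n_restarts=3)
        assert np.sort(res.params.lambdas) == pytest.approx([0.5, 6.0], abs=0.4)

    def test_zip_with_zero_weight_matches_poisson_likelihood(self, rng):
        obs = rng.poisson(2.0, 300)
        p_pois = _params([0.6, 0.4], [[0.8, 0.2], [0.3, 0.7]], [1.0, 4.0])
        p_zip = _params([0.6, 0.4], [[0.8, 0.2], [0.3, 0.7]], [1.0, 4.0], [0.0, 0.0])
        assert log_likelihood(p_zip, obs) == pytest.approx(
            log_likelihood(p_pois, obs), abs=1e-12)

    def test_zip_fit_recovers_inflation(self):
        truth = _params([1.0], [[1.0]], [4.0], [0.4])
        obs, _, _ = sample(truth, 8000, seed=9)
        res = PoissonHMM(obs, 1, emission="zip").fit(seed=2, n_restarts=3)
        assert res.params.lambdas[0] == pytest.approx(4.0, abs=0.15)
        assert res.params.zero_weights[0] == pytest.approx(0.4, abs=0.05)

    def test_four_state_round_trip(self, wt_gen):
        obs, states, _ = sample(wt_gen, 2880, seed=21)
        res = PoissonHMM(obs, 4).fit(seed=4, n_restarts=10)
        lam = np.sort(res.params.lambdas)
        for k, lam_k in enumerate(np.sort(wt_gen.lambdas)):
            n_k = max((states == k).sum(), 1)
            se = math.sqrt(lam_k / n_k)
            assert abs(lam[k] - lam_k) < 3 * se + 1e-3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            PoissonHMM([], 2)


class TestParamsJson:
    def test_round_trip_exact(self, tmp_path, wt_gen):
        path = tmp_path / "p.json"
        wt_gen.to_json(path)
        back = HMMParams.from_json(path)
        assert np.allclose(back.startprob, wt_gen.startprob, atol=1e-12)
        assert np.allclose(back.transmat, wt_gen.transmat, atol=1e-12)
        assert np.allclose(back.lambdas, wt_gen.lambdas, atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            _params([0.5, 0.6], [[1, 0], [0, 1]], [1, 2])
        with pytest.raises(ValueError):
            _params([0.5, 0.5], [[0.9, 0.2], [0, 1]], [1, 2])


class TestAgainstHmmlearn:
    def test_likelihood_matches_hmmlearn_scoring(self, wt_gen):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        obs, _, _ = sample(wt_gen, 1500, seed=13)
        ref = hmmlearn.PoissonHMM(n_components=4, init_params="")
        ref.startprob_ = wt_gen.startprob
        ref.transmat_ = wt_gen.transmat
        ref.lambdas_ = wt_gen.lambdas.reshape(-1, 1)
        assert log_likelihood(wt_gen, obs) == pytest.approx(
            ref.score(obs.reshape(-1, 1)), abs=1e-6)

    def test_em_reaches_hmmlearn_solution_quality(self, wt_gen):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        obs, _, _ = sample(wt_gen, 2880, seed=17)
        ours = PoissonHMM(obs, 4).fit(seed=3, n_restarts=10)
        ref = hmmlearn.PoissonHMM(n_components=4, n_iter=500, tol=1e-4,
                                  random_state=3)
        ref.fit(obs.reshape(-1, 1))
        # best-of-10 restarts should do at least as well as one hmmlearn fit
        assert ours.llf >= ref.score(obs.reshape(-1, 1)) - 1.0
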