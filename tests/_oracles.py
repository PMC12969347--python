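"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (path enumeration, direct formulas)
and shares no code with the package's inference routines.
"""

import itertools
import math

import numpy as np


def poisson_pmf(x: int, lam: float) -> float:
    return math.exp(-lam) * lam**x / math.factorial(x)


def path_probability(params, path, obs) -> float:
    p = params.startprob[path[0]] * poisson_pmf(obs[0], params.lambdas[path[0]])
    for a, b, x in zip(path, path[1:], obs[1:]):
        p *= params.transmat[a, b] * poisson_pmf(x, params.lambdas[b])
    return p


def enumerate_loglik(params, obs) -> float:
    K, T = params.n_states, len(obs)
    total = sum(
        path_probability(params, path, obs)
        for path in itertools.product(range(K), repeat=T)
    )
    return math.log(total)


def enumerate_posteriors(params, obs) -> np.ndarray:
    K, T = params.n_states, len(obs)
    gamma = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = path_probability(params, path, obs)
        total += p
        for t, s in enumerate(path):
            gamma[t, s] += p
    return gamma / total


def enumerate_viterbi(params, obs) -> np.ndarray:
    """Best path by exhaustive search; lexicographically smallest on ties."""
    K, T = params.n_states, len(obs)
    best_p, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):  # lexicographic order
        p = path_probability(params, path, obs)
        if p > best_p:
            best_p, best_path = p, path
    return np.array(best_path)


def random_instance(rng, K: int, T: int):
    """A random HMM instance with well-spread rates (no Viterbi ties)."""
    from zfsleep.hmm import HMMParams

    pi = rng.dirichlet(np.ones(K))
    A = np.vstack([rng.dirichlet(np.ones(K)) for _ in range(K)])
    lam = np.sort(rng.uniform(0.2, 9.0, K)) * rng.uniform(0.9, 1.1)
    params = HMMParams(pi, A, lam)
    obs = rng.poisson(rng.choice(lam, size=T))
    return params, np.minimum(obs, 60).astype(np.int64)


def bh_reference(pvalues) -> np.ndarray:
    """Textbook step-up Benjamini-Hochberg adjustment."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def wilcoxon_exact_reference(diffs) -> float:
    """Two-sided signed-rank p by exhaustive sign-flip enumeration."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    w_min_obs = min(w_plus, n * (n + 1) / 2 - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, n * (n + 1) / 2 - w) <= w_min_obs + 1e-12:
            count += 1
    return count / 2**n
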