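"""Numba kernels for the scaled forward-backward recursion and Viterbi.

The recursions use per-step scaling (normalised forward variables) rather
than log-space sums; the caller row-max-normalises the emission likelihood
matrix so at least one entry per time step equals 1, which keeps the scaled
recursion finite even for very unlikely observations.
"""

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def forward_loglik(B, A, pi):
    """Scaled forward pass; returns log-likelihood in the scaled domain.

    B must be row-max-normalised emission likelihoods; the caller adds back
    the sum of the per-row log offsets.
    """
    T, K = B.shape
    prev = np.empty(K)
    cur = np.empty(K)
    ll = 0.0
    s = 0.0
    for k in range(K):
        prev[k] = pi[k] * B[0, k]
        s += prev[k]
    if s < _TINY:
        s = _TINY
    for k in range(K):
        prev[k] /= s
    ll += np.log(s)
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += prev[i] * A[i, j]
            cur[j] = acc * B[t, j]
            s += cur[j]
        if s < _TINY:
            s = _TINY
        for j in range(K):
            prev[j] = cur[j] / s
        ll += np.log(s)
    return ll


@njit(cache=True)
def forward_backward(B, A, pi):
    """Scaled forward-backward pass.

    Returns (scaled-domain log-likelihood, posterior matrix gamma (T, K),
    expected transition-count matrix xi_sum (K, K)).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    if s < _TINY:
        s = _TINY
    for k in range(K):
        alpha[0, k] /= s
    c[0] = s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[t, j]
            s += alpha[t, j]
        if s < _TINY:
            s = _TINY
        for j in range(K):
            alpha[t, j] /= s
        c[t] = s

    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]

    xi = np.zeros((K, K))
    for t in range(T - 1):
        inv = 1.0 / c[t + 1]
        for i in range(K):
            ai = alpha[t, i]
            if ai == 0.0:
                continue
            for j in range(K):
                xi[i, j] += ai * A[i, j] * B[t + 1, j] * beta[t + 1, j] * inv

    gamma = np.empty((T, K))
    for t in range(T):
        tot = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            tot += gamma[t, k]
        if tot > 0.0:
            for k in range(K):
                gamma[t, k] /= tot

    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return ll, gamma, xi


@njit(cache=True)
def viterbi_path(logB, logA, logpi):
    """Most probable state path; ties broken toward the lower state index."""
    T, K = logB.shape
    delta = np.empty(K)
    psi = np.empty((T, K), dtype=np.int64)
    for k in range(K):
        delta[k] = logpi[k] + logB[0, k]
    nxt = np.empty(K)
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            nxt[j] = best + logB[t, j]
            psi[t, j] = arg
        for j in range(K):
            delta[j] = nxt[j]
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def poisson_em(obs, seq_starts, pi0, A0, lam0, lam_floor, tol, max_iter):
    """Full Baum-Welch loop for plain Poisson emissions (multi-sequence).

    obs is the concatenation of all sequences; seq_starts holds the start
    index of each sequence plus a final sentinel.  Returns the updated
    parameters, the per-iteration log-likelihood trail, a convergence flag
    and the final per-state posterior mass (for collapse detection).
    """
    K = lam0.size
    n_seq = seq_starts.size - 1
    max_obs = 0
    for i in range(obs.size):
        if obs[i] > max_obs:
            max_obs = obs[i]
    pi = pi0.copy()
    A = A0.copy()
    lam = lam0.copy()
    trail = np.empty(max_iter)
    converged = False
    prev = -np.inf
    n_it = 0
    gamma_sum = np.zeros(K)
    for it in range(max_iter):
        logtab = np.empty((max_obs + 1, K))
        for k in range(K):
            l = lam[k]
            logl = np.log(l)
            for v in range(max_obs + 1):
                lg = 0.0
                for m in range(2, v + 1):  # log(v!)
                    lg += np.log(m)
                logtab[v, k] = v * logl - l - lg
        gamma_first = np.zeros(K)
        gsum = np.zeros(K)
        gx = np.zeros(K)
        xi_tot = np.zeros((K, K))
        ll = 0.0
        for s in range(n_seq):
            a = seq_starts[s]
            b = seq_starts[s + 1]
            T = b - a
            B = np.empty((T, K))
            for t in range(T):
                v = obs[a + t]
                mx = -1e308
                for k in range(K):
                    if logtab[v, k] > mx:
                        mx = logtab[v, k]
                for k in range(K):
                    B[t, k] = np.exp(logtab[v, k] - mx)
                ll += mx
            ll_s, gamma, xs = forward_backward(B, A, pi)
            ll += ll_s
            for k in range(K):
                gamma_first[k] += gamma[0, k]
            for t in range(T):
                v = obs[a + t]
                for k in range(K):
                    gsum[k] += gamma[t, k]
                    gx[k] += gamma[t, k] * v
            for i in range(K):
                for j in range(K):
                    xi_tot[i, j] += xs[i, j]
        trail[it] = ll
        n_it = it + 1
        if it > 0 and ll - prev < tol:
            converged = True
            break
        prev = ll
        if it < max_iter - 1:
            # M-step
            tot = 0.0
            for k in range(K):
                pi[k] = gamma_first[k] / n_seq
                if pi[k] < 0.0:
                    pi[k] = 0.0
                tot += pi[k]
            for k in range(K):
                pi[k] /= tot
            for i in range(K):
                rs = 0.0
                for j in range(K):
                    rs += xi_tot[i, j]
                if rs > 0.0:
                    for j in range(K):
                        A[i, j] = xi_tot[i, j] / rs
                else:
                    for j in range(K):
                        A[i, j] = 1.0 / K
            for k in range(K):
                d = gsum[k]
                if d < 1e-300:
                    d = 1e-300
                lam[k] = gx[k] / d
                if lam[k] < lam_floor:
                    lam[k] = lam_floor
            gamma_sum = gsum
    return pi, A, lam, trail[:n_it], converged, gamma_sum
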