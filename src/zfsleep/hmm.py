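"""Poisson hidden Markov models for binned locomotor activity.

The model: a fish moves between K hidden behavioural states following a
first-order Markov chain with row-stochastic transition matrix A and initial
distribution pi; while in state k it emits, each minute, an activity count
(seconds active per minute) drawn from a Poisson distribution with mean
lambda_k, optionally zero-inflated with weight w_k:

    P(x | k) = w_k * [x == 0] + (1 - w_k) * Poisson(x; lambda_k)

Fitting is by Baum-Welch EM on one or more observation sequences (sufficient
statistics pooled across sequences, no transitions across sequence
boundaries).  The public surface follows the statsmodels convention: build a
:class:`PoissonHMM` from data, call :meth:`PoissonHMM.fit`, and work with the
returned :class:`PoissonHMMResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .data import ActivityTrace

LAMBDA_FLOOR = 1e-3  # far below the data scale (smallest reported rate ~0.02 s/min)

__all__ = [
    "HMMParams",
    "StateSequence",
    "PoissonHMM",
    "PoissonHMMResults",
    "emission_logpmf",
    "log_likelihood",
    "posteriors",
    "viterbi",
    "sample",
    "stationary_distribution",
]


@dataclass(frozen=True)
class HMMParams:
    """Parameters of a K-state Poisson (or zero-inflated Poisson) HMM."""

    startprob: np.ndarray  # pi, length K
    transmat: np.ndarray  # A, K x K row-stochastic
    lambdas: np.ndarray  # per-state Poisson mean, s/min
    zero_weights: np.ndarray | None = None  # per-state ZIP weight in [0, 1)

    def __post_init__(self):
        pi = np.asarray(self.startprob, dtype=float)
        A = np.asarray(self.transmat, dtype=float)
        lam = np.asarray(self.lambdas, dtype=float)
        K = lam.size
        if pi.shape != (K,) or A.shape != (K, K):
            raise ValueError("inconsistent parameter shapes")
        if np.any(pi < 0) or np.any(A < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(lam < LAMBDA_FLOOR):
            raise ValueError(f"state rates must be >= {LAMBDA_FLOOR}")
        w = self.zero_weights
        if w is not None:
            w = np.asarray(w, dtype=float)
            if w.shape != (K,) or np.any(w < 0) or np.any(w >= 1):
                raise ValueError("zero-inflation weights must lie in [0, 1)")
        object.__setattr__(self, "startprob", pi)
        object.__setattr__(self, "transmat", A)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "zero_weights", w)

    @property
    def n_states(self) -> int:
        return self.lambdas.size

    @property
    def emission(self) -> str:
        return "poisson" if self.zero_weights is None else "zip"

    @property
    def n_free_parameters(self) -> int:
        """(K-1) initial + K(K-1) transition + K rates (+ K ZIP weights)."""
        K = self.n_states
        p = (K - 1) + K * (K - 1) + K
        if self.zero_weights is not None:
            p += K
        return p

    def to_json(self, path=None) -> str:
        obj = {
            "K": self.n_states,
            "initial": self.startprob.tolist(),
            "transitions": self.transmat.tolist(),
            "lambdas": self.lambdas.tolist(),
            "zero_weights": None if self.zero_weights is None else self.zero_weights.tolist(),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HMMParams":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            np.array(obj["initial"]),
            np.array(obj["transitions"]),
            np.array(obj["lambdas"]),
            None if obj.get("zero_weights") is None else np.array(obj["zero_weights"]),
        )


@dataclass
class StateSequence:
    """A decoded path with its posterior state probabilities."""

    states: np.ndarray  # length-T state indices
    posteriors: np.ndarray  # T x K gamma matrix
    labeling: dict | None = None  # optional state index -> semantic label

    def labels(self) -> np.ndarray:
        if self.labeling is None:
            raise ValueError("no semantic labeling attached")
        return np.array([self.labeling[s] for s in self.states], dtype=object)


# ---------------------------------------------------------------------------
# emission probabilities
# ---------------------------------------------------------------------------

def emission_logpmf(x, lam, w=None):
    """Log emission probability of count(s) x under Poisson / ZIP."""
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    lam = float(lam)
    if lam < LAMBDA_FLOOR:
        raise ValueError(f"rate must be >= {LAMBDA_FLOOR}")
    logp = x * np.log(lam) - lam - gammaln(x + 1.0)
    if w is None:
        return logp
    w = float(w)
    if not 0 <= w < 1:
        raise ValueError("zero-inflation weight must lie in [0, 1)")
    p = (1 - w) * np.exp(logp)
    p = np.where(x == 0, w + p, p)
    return np.log(p)


def _log_emission_table(params: HMMParams, max_count: int) -> np.ndarray:
    """(max_count+1, K) table of log P(x | state); observations are small ints."""
    x = np.arange(max_count + 1, dtype=float)[:, None]
    lam = params.lambdas[None, :]
    logp = x * np.log(lam) - lam - gammaln(x + 1.0)
    if params.zero_weights is not None:
        w = params.zero_weights[None, :]
        p = (1 - w) * np.exp(logp)
        p[0] = w[0] + p[0]
        logp = np.log(np.maximum(p, 1e-300))
    return logp


def _as_observations(x) -> np.ndarray:
    if isinstance(x, ActivityTrace):
        return x.values
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("observations must be a non-empty 1-d sequence")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("observations must be integer counts")
        arr = np.rint(arr).astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("observations must be non-negative counts")
    return arr.astype(np.int64)


def _as_sequences(data) -> list:
    if isinstance(data, (ActivityTrace, np.ndarray)):
        return [_as_observations(data)]
    if isinstance(data, (list, tuple)):
        if len(data) == 0:
            raise ValueError("no observation sequences given")
        if all(np.isscalar(v) or isinstance(v, (int, np.integer)) for v in data):
            return [_as_observations(np.asarray(data))]
        return [_as_observations(x) for x in data]
    return [_as_observations(data)]


def _scaled_B(params: HMMParams, obs: np.ndarray):
    table = _log_emission_table(params, int(obs.max()))
    logB = table[obs]
    offsets = logB.max(axis=1)
    B = np.exp(logB - offsets[:, None])
    return np.ascontiguousarray(B), offsets.sum()


# ---------------------------------------------------------------------------
# inference primitives
# ---------------------------------------------------------------------------

def log_likelihood(params: HMMParams, data) -> float:
    """Exact marginal log-likelihood via the scaled forward recursion."""
    total = 0.0
    for obs in _as_sequences(data):
        B, off = _scaled_B(params, obs)
        total += _kernels.forward_loglik(B, params.transmat, params.startprob) + off
    return float(total)


def posteriors(params: HMMParams, data) -> np.ndarray:
    """Posterior state probabilities gamma_{t,k} = P(state_t = k | x_{1:T})."""
    obs = _as_observations(data)
    B, _ = _scaled_B(params, obs)
    _, gamma, _ = _kernels.forward_backward(B, params.transmat, params.startprob)
    return gamma


def viterbi(params: HMMParams, data) -> np.ndarray:
    """Jointly most probable state path (ties toward the lower state index)."""
    obs = _as_observations(data)
    table = _log_emission_table(params, int(obs.max()))
    logB = np.ascontiguousarray(table[obs])
    with np.errstate(divide="ignore"):
        logA = np.log(params.transmat)
        logpi = np.log(params.startprob)
    return _kernels.viterbi_path(logB, logA, logpi)


def sample(params: HMMParams, T: int, seed, clip: int = 60):
    """Draw (observations, hidden path, n_clipped) of length T from the model."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    K = params.n_states
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(K, p=params.startprob)
    for t in range(1, T):
        states[t] = rng.choice(K, p=params.transmat[states[t - 1]])
    obs = rng.poisson(params.lambdas[states])
    if params.zero_weights is not None:
        zero = rng.random(T) < params.zero_weights[states]
        obs[zero] = 0
    n_clipped = int((obs > clip).sum())
    return np.minimum(obs, clip).astype(np.int64), states, n_clipped


def stationary_distribution(A, states=None) -> np.ndarray:
    """Long-run state distribution: dominant left eigenvector of A.

    If the unit eigenvalue is not simple (reducible or periodic chain), falls
    back to empirical frequencies of a supplied decoded path; with no path it
    raises.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("transition matrix must be row-stochastic")
    K = A.shape[0]
    if K == 1:
        return np.ones(1)
    eigval, eigvec = np.linalg.eig(A.T)
    close = np.where(np.abs(eigval - 1.0) < 1e-8)[0]
    if close.size != 1:
        if states is not None:
            states = np.asarray(states)
            return np.bincount(states, minlength=K) / states.size
        raise ValueError(
            "unit eigenvalue is not simple (reducible/periodic chain); "
            "supply a decoded path for an empirical fallback"
        )
    v = np.real(eigvec[:, close[0]])
    v = np.abs(v)
    return v / v.sum()


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PoissonHMM:
    """K-state Poisson HMM bound to one or more observation sequences.

    Parameters
    ----------
    endog : ActivityTrace, int sequence, or list of either
        Observation sequence(s) of activity counts.
    n_states : int
        Number of hidden states K (>= 1).
    emission : {"poisson", "zip"}
        Plain or zero-inflated Poisson emissions.
    """

    def __init__(self, endog, n_states: int, emission: str = "poisson",
                 lambda_floor: float = LAMBDA_FLOOR):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if emission not in ("poisson", "zip"):
            raise ValueError("emission must be 'poisson' or 'zip'")
        self.sequences = _as_sequences(endog)
        self.n_states = int(n_states)
        self.emission = emission
        self.lambda_floor = float(lambda_floor)
        self.n_obs = int(sum(s.size for s in self.sequences))
        if self.n_obs < self.n_states:
            raise ValueError("need at least as many observations as states")

    # -- initialization ----------------------------------------------------
    def _initial_params(self, rng: np.random.Generator) -> HMMParams:
        """Rate init from K quantiles of the pooled data with multiplicative
        jitter; near-diagonal transition init with Dirichlet jitter."""
        K = self.n_states
        allobs = np.concatenate(self.sequences)
        qs = np.quantile(allobs, (np.arange(K) + 1) / (K + 1))
        lam = np.maximum(qs, 0.1) * np.exp(rng.normal(0.0, 0.5, K))
        lam = np.maximum(lam, self.lambda_floor)
        if K == 1:
            A = np.ones((1, 1))
        else:
            base = np.full((K, K), 0.2 / (K - 1))
            np.fill_diagonal(base, 0.8)
            A = np.vstack([rng.dirichlet(50.0 * row) for row in base])
            A = np.maximum(A, 1e-6)
            A /= A.sum(axis=1, keepdims=True)
        pi = np.full(K, 1.0 / K)
        w = np.full(K, 0.1) if self.emission == "zip" else None
        return HMMParams(pi, A, lam, w)

    # -- EM ----------------------------------------------------------------
    def _e_step(self, params: HMMParams):
        K = self.n_states
        ll = 0.0
        gamma_first = np.zeros(K)
        gamma_sum = np.zeros(K)
        gamma_x = np.zeros(K)
        gamma_zero = np.zeros(K)
        xi_sum = np.zeros((K, K))
        for obs in self.sequences:
            B, off = _scaled_B(params, obs)
            ll_s, gamma, xi = _kernels.forward_backward(B, params.transmat, params.startprob)
            ll += ll_s + off
            gamma_first += gamma[0]
            gamma_sum += gamma.sum(axis=0)
            gamma_x += gamma.T @ obs
            zero_mask = obs == 0
            if zero_mask.any():
                gamma_zero += gamma[zero_mask].sum(axis=0)
            xi_sum += xi
        return ll, (gamma_first, gamma_sum, gamma_x, gamma_zero, xi_sum)

    def _m_step(self, params: HMMParams, stats) -> tuple[HMMParams, np.ndarray]:
        gamma_first, gamma_sum, gamma_x, gamma_zero, xi_sum = stats
        K = self.n_states
        pi = gamma_first / len(self.sequences)
        pi = np.maximum(pi, 0.0)
        pi /= pi.sum()
        rowsum = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rowsum > 0, xi_sum / np.maximum(rowsum, 1e-300), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        collapsed = gamma_sum < 1e-6
        if self.emission == "zip":
            lam_old, w_old = params.lambdas, params.zero_weights
            u = w_old / (w_old + (1 - w_old) * np.exp(-lam_old))  # P(structural zero | x=0)
            zero_mass = u * gamma_zero
            denom = np.maximum(gamma_sum - zero_mass, 1e-300)
            lam = gamma_x / denom
            w = np.clip(zero_mass / np.maximum(gamma_sum, 1e-300), 0.0, 1.0 - 1e-9)
        else:
            lam = gamma_x / np.maximum(gamma_sum, 1e-300)
            w = None
        lam = np.maximum(lam, self.lambda_floor)
        return HMMParams(pi, A, lam, w), collapsed

    def _em(self, rng: np.random.Generator, tol: float, max_iter: int,
            init_params: HMMParams | None):
        params = init_params if init_params is not None else self._initial_params(rng)
        if self.emission == "poisson":
            obs = np.concatenate(self.sequences)
            starts = np.concatenate(
                ([0], np.cumsum([s.size for s in self.sequences]))
            ).astype(np.int64)
            pi, A, lam, trail, converged, gamma_sum = _kernels.poisson_em(
                obs, starts, params.startprob, params.transmat, params.lambdas,
                self.lambda_floor, tol, max_iter,
            )
            return (HMMParams(pi, A, lam), trail, bool(converged), gamma_sum < 1e-6)
        trail = []
        converged = False
        collapsed = np.zeros(self.n_states, dtype=bool)
        prev = -np.inf
        for it in range(1, max_iter + 1):
            ll, stats = self._e_step(params)
            trail.append(ll)
            if it > 1 and ll - prev < tol:
                converged = True
                break
            prev = ll
            if it < max_iter:
                params, collapsed = self._m_step(params, stats)
        return params, np.array(trail), converged, collapsed

    def fit(self, seed: int = 0, n_restarts: int = 1, tol: float = 1e-4,
            max_iter: int = 500, init_params: HMMParams | None = None
            ) -> "PoissonHMMResults":
        """Fit by (multi-restart) EM; best restart by log-likelihood.

        Restart seeds derive deterministically from ``seed``; the winning
        restart index is recorded on the results object.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        children = np.random.SeedSequence(seed).spawn(n_restarts)
        best = None
        for r in range(n_restarts):
            rng = np.random.default_rng(children[r])
            params, trail, converged, collapsed = self._em(
                rng, tol, max_iter, init_params if r == 0 and init_params is not None else None
            )
            llf = trail[-1]
            if best is None or llf > best[0]:
                best = (llf, params, trail, converged, collapsed, r)
        llf, params, trail, converged, collapsed, r = best
        return PoissonHMMResults(
            model=self, params=params, llf=float(llf), loglik_trail=trail,
            n_iter=len(trail), converged=converged, seed=seed,
            restart_index=r, n_restarts=n_restarts,
            collapsed_states=np.flatnonzero(collapsed).tolist(),
        )

    def loglike(self, params: HMMParams) -> float:
        return log_likelihood(params, self.sequences)


@dataclass
class PoissonHMMResults:
    """Fit results: parameter estimates, likelihood trail and diagnostics."""

    model: PoissonHMM
    params: HMMParams
    llf: float
    loglik_trail: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    restart_index: int
    n_restarts: int
    collapsed_states: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.llf

    @property
    def bic(self) -> float:
        """p * ln(n) - 2 * loglik with the free-parameter count of the model."""
        return self.params.n_free_parameters * np.log(self.model.n_obs) - 2.0 * self.llf

    def posteriors(self, data=None):
        seqs = self.model.sequences if data is None else [_as_observations(data)]
        out = [posteriors(self.params, s) for s in seqs]
        return out[0] if (data is not None or len(out) == 1) else out

    def decode(self, data=None, labeling: dict | None = None):
        """Viterbi path + posteriors per sequence as :class:`StateSequence`."""
        seqs = self.model.sequences if data is None else [_as_observations(data)]
        out = [
            StateSequence(viterbi(self.params, s), posteriors(self.params, s), labeling)
            for s in seqs
        ]
        return out[0] if (data is not None or len(out) == 1) else out

    def occupancy(self) -> np.ndarray:
        paths = self.decode()
        fallback = np.concatenate([p.states for p in (paths if isinstance(paths, list) else [paths])])
        return stationary_distribution(self.params.transmat, states=fallback)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Poisson HMM fit",
            "=" * 46,
            f"states:        {p.n_states}   emission: {p.emission}",
            f"n obs:         {self.model.n_obs}  (sequences: {len(self.model.sequences)})",
            f"log-likelihood: {self.llf:.3f}",
            f"BIC:           {self.bic:.3f}",
            f"iterations:    {self.n_iter}   converged: {self.converged}",
            f"restarts:      {self.n_restarts} (winner {self.restart_index}, seed {self.seed})",
            "-" * 46,
            "state   lambda (s/min)" + ("   zero-weight" if p.emission == "zip" else ""),
        ]
        for k in range(p.n_states):
            row = f"{k:5d}   {p.lambdas[k]:13.4f}"
            if p.emission == "zip":
                row += f"   {p.zero_weights[k]:10.4f}"
            lines.append(row)
        lines.append("-" * 46)
        lines.append("transition matrix:")
        for k in range(p.n_states):
            lines.append("   " + "  ".join(f"{v:.4f}" for v in p.transmat[k]))
        occ = stationary_distribution_safe(p.transmat)
        if occ is not None:
            lines.append("stationary occupancy: " + "  ".join(f"{v:.4f}" for v in occ))
        if self.collapsed_states:
            lines.append(f"WARNING: collapsed states (rate floored): {self.collapsed_states}")
        return "\n".join(lines)


def stationary_distribution_safe(A):
    try:
        return stationary_distribution(A)
    except ValueError:
        return None
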