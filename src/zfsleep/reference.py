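"""Reference wild-type parameter values used for labeling and simulation.

The group-level 4-state fit for wild-type fish has emission means of roughly
0.02, 1.18, 4.07 and 7.49 s/min for states S2 (deep-sleep-like), S1
(light-sleep-like), W1 and W2 (wake).  The group-average transition diagram
reports the sleep-to-wake and wake-to-sleep off-diagonal probabilities; the
remaining off-diagonal entries (within-sleep and within-wake exchanges) are
not reported and are set to a small common value, with each diagonal
absorbing the remainder.  The resulting matrix is strongly self-persistent,
as fitted transition matrices for these data are.
"""

from __future__ import annotations

import numpy as np

from .hmm import HMMParams, stationary_distribution

#: semantic state labels in ascending activity order
LABELS4 = ("S2", "S1", "W1", "W2")
LABELS3 = ("S2", "S1", "W")

#: reference per-state emission means, s/min (wild-type group fit)
REFERENCE_LAMBDAS = {"S2": 0.02, "S1": 1.18, "W1": 4.07, "W2": 7.49}

#: reported group-average transition probabilities (row -> column)
REPORTED_TRANSITIONS = {
    ("S2", "W1"): 0.03,
    ("S2", "W2"): 0.01,
    ("S1", "W1"): 0.07,
    ("S1", "W2"): 0.07,
    ("W1", "S1"): 0.09,
    ("W1", "S2"): 0.09,
    ("W2", "S1"): 0.04,
    ("W2", "S2"): 0.01,
}

#: value assigned to the unreported off-diagonal entries
UNREPORTED_OFFDIAGONAL = 0.05


def reference_transition_matrix(unreported: float = UNREPORTED_OFFDIAGONAL) -> np.ndarray:
    """4x4 wild-type transition matrix (rows/cols ordered S2, S1, W1, W2)."""
    K = len(LABELS4)
    A = np.zeros((K, K))
    for i, a in enumerate(LABELS4):
        for j, b in enumerate(LABELS4):
            if i == j:
                continue
            A[i, j] = REPORTED_TRANSITIONS.get((a, b), unreported)
        A[i, i] = 1.0 - A[i].sum()
    if np.any(np.diag(A) <= 0):
        raise ValueError("unreported off-diagonal value too large; diagonal not positive")
    return A


def reference_wt_params(unreported: float = UNREPORTED_OFFDIAGONAL) -> HMMParams:
    """Homogeneous 4-state wild-type generator; initial = stationary."""
    A = reference_transition_matrix(unreported)
    lam = np.array([REFERENCE_LAMBDAS[l] for l in LABELS4])
    pi = stationary_distribution(A)
    return HMMParams(pi, A, lam)
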