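"""Inferential statistics for group comparisons of sleep architecture.

Group differences in HMM parameters (occupancies, rates, transition
probabilities) are tested with a two-sided permutation test on the
difference of group means, with a bootstrap confidence interval on that
difference reported alongside, and Bonferroni correction by parameter
family (factor 4 for occupancies and rates, 16 for the transition entries
of a 4-state model).  Within-fish day/night contrasts use the Wilcoxon
signed-rank test and between-group state-amount contrasts use Welch
t-tests, both with Benjamini-Hochberg correction across states.  Response
fractions may be arcsine-transformed before testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_ENUMERATION_LIMIT = 20_000

FAMILY_FACTORS = {"occupancy_lambda": 4, "transitions": 16}
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationTest:
    pvalue: float
    observed: float  # |mean(A) - mean(B)|
    exact: bool
    n_perm: int
    seed: int | None


@lru_cache(maxsize=64)
def _combination_indices(n: int, k: int) -> np.ndarray:
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), k)),
        dtype=np.int64,
    )
    return idx.reshape(-1, k)


def perm_test(values_a, values_b, n_perm: int = 10_000, seed: int = 0) -> PermutationTest:
    """Two-sided permutation test on the absolute difference of group means.

    Enumerates all label assignments exactly when their number is at most
    20,000; otherwise Monte-Carlo with +1 smoothing (so p > 0 always).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    total = pooled.sum()
    observed = abs(a.mean() - b.mean())
    n_splits = comb(n, na)
    if n_splits <= EXACT_ENUMERATION_LIMIT:
        idx = _combination_indices(n, na)
        sums_a = pooled[idx].sum(axis=1)
        stats = np.abs(sums_a / na - (total - sums_a) / (n - na))
        p = float(np.mean(stats >= observed - 1e-12))
        return PermutationTest(p, observed, True, n_splits, None)
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perms = rng.permuted(np.broadcast_to(pooled, (m, n)).copy(), axis=1)
        sums_a = perms[:, :na].sum(axis=1)
        stats = np.abs(sums_a / na - (total - sums_a) / (n - na))
        count += int(np.sum(stats >= observed - 1e-12))
        done += m
    p = (1 + count) / (1 + n_perm)
    return PermutationTest(float(p), observed, False, n_perm, seed)


def bootstrap_diff_ci(values_a, values_b, n_boot: int = 2000, seed: int = 0,
                      alpha: float = 0.05):
    """Percentile bootstrap CI for mean(A) - mean(B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rng = np.random.default_rng(seed)
    ra = rng.integers(0, a.size, size=(n_boot, a.size))
    rb = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ra].mean(axis=1) - b[rb].mean(axis=1)
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# multiple-comparison corrections
# ---------------------------------------------------------------------------

def _family_factor(family) -> int:
    if isinstance(family, (int, np.integer)):
        if family < 1:
            raise ValueError("correction factor must be >= 1")
        return int(family)
    try:
        return FAMILY_FACTORS[family]
    except KeyError:
        raise ValueError(
            f"unknown test family {family!r}; known: {sorted(FAMILY_FACTORS)} "
            "or pass an explicit integer factor"
        ) from None


def bonferroni(p_values, family) -> pd.DataFrame:
    """Bonferroni flags at 0.05 / 0.01 / 0.001 with three-tier stars.

    ``family`` is 'occupancy_lambda' (factor 4), 'transitions' (factor 16),
    or an explicit integer factor.
    """
    factor = _family_factor(family)
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    corrected = p * factor
    stars = []
    for c in corrected:
        tier = ""
        for thr, sym in STAR_THRESHOLDS:
            if c < thr:
                tier = sym
                break
        stars.append(tier)
    return pd.DataFrame(
        {
            "p": p,
            "p_bonferroni": np.minimum(corrected, 1.0),
            "sig_05": corrected < 0.05,
            "sig_01": corrected < 0.01,
            "sig_001": corrected < 0.001,
            "stars": stars,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def paired_wilcoxon(day_values, night_values):
    """Two-sided Wilcoxon signed-rank test on paired per-fish values.

    Zero differences are dropped; exact null for n <= 25 pairs, normal
    approximation above.  All-zero differences give p = 1 with a warning.
    """
    d = np.asarray(night_values, dtype=float) - np.asarray(day_values, dtype=float)
    if d.size != np.asarray(day_values).size:
        raise ValueError("paired samples must have equal length")
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_ttest(values_a, values_b):
    """Two-sided Welch (unequal-variance) t-test; returns (statistic, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate t-test (zero variance, unequal means)")
    return float(stat), float(p)


def arcsine_fraction(f):
    """Variance-stabilising transform asin(sqrt(f)) for fractions in [0, 1]."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("fractions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(f) else out


@dataclass(frozen=True)
class IdentityFit:
    r: float | None
    pvalue: float | None
    mean_deviation: float  # mean of y - x


def pearson_identity_fit(x, y) -> IdentityFit:
    """Pearson correlation plus mean signed deviation from the line y = x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    dev = float(np.mean(y - x))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return IdentityFit(None, None, dev)
    r, p = sps.pearsonr(x, y)
    return IdentityFit(float(r), float(p), dev)


# ---------------------------------------------------------------------------
# cohort-level HMM parameter comparison
# ---------------------------------------------------------------------------

def compare_cohort_parameters(fits_a, fits_b, n_perm: int = 10_000, seed: int = 0,
                              n_boot: int = 2000) -> pd.DataFrame:
    """Permutation tests on every labeled HMM parameter between two cohorts.

    ``fits_a`` / ``fits_b`` are per-fish results objects; states are labeled
    by rate and parameters compared per label: occupancy and rate (family
    factor 4), and each transition entry (factor 16 for 4-state fits).
    """
    from .architecture import label_states, occupancy  # deferred: avoid cycle

    def extract(fits):
        values = {}
        for fit in fits:
            labeling = label_states(fit.params)
            occ = occupancy(fit.params, labeling,
                            states=np.concatenate([s.states for s in _decoded(fit)]))
            for label in labeling.label_set:
                values.setdefault(("occupancy", label), []).append(occ[label])
                values.setdefault(("lambda", label), []).append(
                    fit.params.lambdas[labeling.index_of(label)]
                )
            for la in labeling.label_set:
                for lb in labeling.label_set:
                    values.setdefault(("transition", f"{la}->{lb}"), []).append(
                        fit.params.transmat[labeling.index_of(la), labeling.index_of(lb)]
                    )
        return values

    def _decoded(fit):
        dec = fit.decode()
        return dec if isinstance(dec, list) else [dec]

    va, vb = extract(fits_a), extract(fits_b)
    if set(va) != set(vb):
        raise ValueError("cohorts have different labeled parameter sets (mismatched K?)")
    ss = np.random.SeedSequence(seed)
    rows = []
    for key in va:
        kind, name = key
        a = np.asarray(va[key])
        b = np.asarray(vb[key])
        child = ss.spawn(1)[0]
        s1, s2 = (int(v % (2**31)) for v in child.generate_state(2))
        test = perm_test(a, b, n_perm=n_perm, seed=s1)
        lo, hi = bootstrap_diff_ci(a, b, n_boot=n_boot, seed=s2)
        family = "occupancy_lambda" if kind in ("occupancy", "lambda") else "transitions"
        rows.append(
            {
                "parameter": f"{kind}[{name}]",
                "family": family,
                "group_a_mean": float(a.mean()),
                "group_b_mean": float(b.mean()),
                "diff": float(a.mean() - b.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
                "p": test.pvalue,
            }
        )
    df = pd.DataFrame(rows)
    # family sizes scale with K: 4 and 16 for 4-state fits, K and K^2 otherwise
    n_labels = int(round(np.sqrt(sum(k[0] == "transition" for k in va))))
    factors = {"occupancy_lambda": n_labels, "transitions": n_labels**2}
    flags = []
    for family, factor in factors.items():
        sub = df[df["family"] == family]
        flags.append(bonferroni(sub["p"].to_numpy(), factor).set_index(sub.index))
    fl = pd.concat(flags).sort_index()
    return pd.concat([df, fl[["p_bonferroni", "sig_05", "stars"]]], axis=1)
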