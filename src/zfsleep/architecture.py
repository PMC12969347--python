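"""Sleep-architecture summaries of fitted and decoded state sequences.

States are given semantic labels by ascending emission rate — S2 (deep
sleep, rate near 0 s/min), S1 (light sleep, ~1 s/min), and the wake states
W1 (~4) and W2 (~8); free-running 3-state fits use (S2, S1, W).  On top of
the labeling this module computes long-run occupancies, day/night state
proportions, bout-duration statistics, smoothed posterior time courses, the
comparison with conventionally defined sleep (zero-activity minutes), and
activity-conditioned state-assignment tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DAY, NIGHT, ActivityTrace, conventional_sleep
from .hmm import HMMParams, StateSequence, stationary_distribution
from .reference import LABELS3, LABELS4, REFERENCE_LAMBDAS
from .stats import pearson_identity_fit

PERIODS = (DAY, NIGHT)


@dataclass(frozen=True)
class StateLabeling:
    """Map from state index to semantic label, plus the reference rates used."""

    labels: tuple  # index -> label
    reference: dict  # label -> reference rate
    mismatch: bool = False  # ordering vs nearest-reference disagreement (K=3)

    def __getitem__(self, idx):
        return self.labels[idx]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def label_set(self) -> tuple:
        return tuple(self.labels)

    def as_dict(self) -> dict:
        return dict(enumerate(self.labels))


def label_states(params: HMMParams) -> StateLabeling:
    """Assign semantic labels to fitted states.

    K=4: ascending rate -> (S2, S1, W1, W2).  K=3: ascending rate ->
    (S2, S1, W), cross-checked against the reference rates by nearest match;
    a disagreement is recorded as a warning, not an error.  Other K get
    generic rank labels with a warning.  Rate ties (within 1e-6) are
    ambiguous and raise.
    """
    lam = params.lambdas
    order = np.argsort(lam, kind="stable")
    if np.any(np.diff(lam[order]) < 1e-6):
        raise ValueError("emission rates tie within 1e-6; supply manual labels")
    K = params.n_states
    labels = [None] * K
    mismatch = False
    if K == 4:
        for rank, idx in enumerate(order):
            labels[idx] = LABELS4[rank]
    elif K == 3:
        for rank, idx in enumerate(order):
            labels[idx] = LABELS3[rank]
        # nearest-reference cross-check; both wake references map to W
        ref_items = [("S2", 0.02), ("S1", 1.18), ("W", 4.07), ("W", 7.49)]
        for idx in range(K):
            nearest = min(ref_items, key=lambda kv: abs(lam[idx] - kv[1]))[0]
            if nearest != labels[idx]:
                mismatch = True
        if mismatch:
            warnings.warn(
                "3-state labeling: rate ordering disagrees with nearest reference "
                "rates; ordering kept, flagged for manual review"
            )
    elif K == 2:
        labels[order[0]] = "sleep-like"
        labels[order[1]] = "wake-like"
        warnings.warn("2-state fit: generic sleep-like/wake-like labels assigned")
    else:
        for rank, idx in enumerate(order):
            labels[idx] = f"state{rank}"
        warnings.warn(f"{K}-state fit: generic rank labels assigned")
    return StateLabeling(tuple(labels), dict(REFERENCE_LAMBDAS), mismatch)


def occupancy(params: HMMParams, labeling: StateLabeling | None = None,
              states=None) -> pd.Series:
    """Long-run state probabilities from the dominant eigenvector of A."""
    if labeling is None:
        labeling = label_states(params)
    pi_inf = stationary_distribution(params.transmat, states=states)
    return pd.Series(pi_inf, index=list(labeling.labels), name="occupancy")


def _label_array(states: np.ndarray, labeling: StateLabeling) -> np.ndarray:
    return np.array([labeling[s] for s in states], dtype=object)


def state_proportions(seq, labeling: StateLabeling, period_labels) -> pd.DataFrame:
    """Fraction of bins per label within each period (columns sum to 1)."""
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    period_labels = np.asarray(period_labels, dtype=object)
    if states.size != period_labels.size:
        raise ValueError("state sequence and period labels differ in length")
    labs = _label_array(states, labeling)
    tab = pd.crosstab(pd.Series(labs, name="label"), pd.Series(period_labels, name="period"))
    tab = tab.reindex(index=list(labeling.label_set), fill_value=0)
    return tab / tab.sum(axis=0)


def state_minutes(seq, labeling: StateLabeling, period_labels) -> pd.DataFrame:
    """Total minutes per label per period."""
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    labs = _label_array(states, labeling)
    tab = pd.crosstab(pd.Series(labs, name="label"), pd.Series(np.asarray(period_labels, dtype=object), name="period"))
    return tab.reindex(index=list(labeling.label_set), fill_value=0)


def _runs(values: np.ndarray):
    """(start, length) of maximal runs of identical values."""
    n = values.size
    breaks = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], breaks))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths

def bout_durations(seq, labeling: StateLabeling, period_labels) -> pd.DataFrame:
    """Mean bout duration (minutes) per label per period.

    A bout is a maximal run of identical labels; runs spanning a day/night
    boundary are truncated there and each fragment counted in its own
    period, which keeps per-period totals conserved.  A label absent from a
    period yields NaN (missing), not zero.
    """
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    period_labels = np.asarray(period_labels, dtype=object)
    if states.size != period_labels.size:
        raise ValueError("state sequence and period labels differ in length")
    labs = _label_array(states, labeling)
    # combine label+period so runs break at either change
    combo = np.array([f"{l}\x00{p}" for l, p in zip(labs, period_labels)], dtype=object)
    starts, lengths = _runs(combo)
    frame = pd.DataFrame(
        {"label": labs[starts], "period": period_labels[starts], "length": lengths}
    )
    mean = frame.groupby(["label", "period"])["length"].mean().unstack("period")
    periods = [p for p in PERIODS if p in set(period_labels)]
    return mean.reindex(index=list(labeling.label_set), columns=periods)


def smoothed_state_probabilities(posteriors: np.ndarray, labeling: StateLabeling | None = None,
                                 window_min: int = 60) -> pd.DataFrame:
    """Centered moving average of the posterior time course.

    A "60 minute" window spans 61 bins (the bin itself plus 30 on each side);
    windows shrink at the edges.  Label columns sum to 1 at every time.
    """
    post = np.asarray(posteriors, dtype=float)
    window_bins = window_min + 1
    if window_bins > post.shape[0]:
        raise ValueError("smoothing window longer than the trace")
    cols = list(labeling.labels) if labeling is not None else list(range(post.shape[1]))
    df = pd.DataFrame(post, columns=cols)
    return df.rolling(window_bins, center=True, min_periods=1).mean()


def mean_state_probabilities(posteriors_list, labeling: StateLabeling,
                             window_min: int = 60) -> pd.DataFrame:
    """Cohort mean of per-fish smoothed posterior time courses."""
    smoothed = [smoothed_state_probabilities(p, labeling, window_min) for p in posteriors_list]
    lengths = {s.shape[0] for s in smoothed}
    if len(lengths) != 1:
        raise ValueError("all fish must share the same trace length")
    return sum(smoothed) / len(smoothed)


def compare_conventional_sleep(sequences, labelings, traces, period_labels_list,
                               sleep_label: str = "S2"):
    """Hours in S2 vs conventionally defined sleep hours, per fish per period.

    Returns (per-fish/period DataFrame, correlation stats).  The correlation
    (Pearson, against the line y = x) pools day and night points across
    fish; it is omitted (None) for fewer than 3 fish.
    """
    rows = []
    for seq, labeling, trace, periods in zip(sequences, labelings, traces, period_labels_list):
        states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
        labs = _label_array(states, labeling)
        flags, _ = conventional_sleep(trace)
        periods = np.asarray(periods, dtype=object)
        for period in (DAY, NIGHT):
            m = periods == period
            if not m.any():
                continue
            rows.append(
                {
                    "fish_id": trace.fish_id,
                    "period": period,
                    "s2_hours": float((labs[m] == sleep_label).sum()) / 60.0,
                    "conventional_hours": float(flags[m].sum()) / 60.0,
                }
            )
    df = pd.DataFrame(rows)
    stats = None
    if df["fish_id"].nunique() >= 3:
        stats = pearson_identity_fit(df["conventional_hours"].to_numpy(),
                                     df["s2_hours"].to_numpy())
    return df, stats


def assignment_by_activity(sequences, labelings, traces, period_labels_list) -> dict:
    """P(label | activity value), overall and split by day/night.

    Pools bins across fish; each table's rows (one per observed activity
    value) sum to 1 across labels.
    """
    frames = []
    for seq, labeling, trace, periods in zip(sequences, labelings, traces, period_labels_list):
        states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
        frames.append(
            pd.DataFrame(
                {
                    "activity": trace.values,
                    "label": _label_array(states, labeling),
                    "period": np.asarray(periods, dtype=object),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    out = {}
    for key, sub in (("overall", pooled), (DAY, pooled[pooled["period"] == DAY]),
                     (NIGHT, pooled[pooled["period"] == NIGHT])):
        if len(sub) == 0:
            continue
        tab = pd.crosstab(sub["activity"], sub["label"], normalize="index")
        out[key] = tab.reindex(columns=list(labelings[0].label_set), fill_value=0.0)
    return out


def average_parameters(fits, labelings):
    """Label-aligned cohort means of rates and transition probabilities.

    Returns (mean rate Series, mean transition DataFrame with rows
    re-normalised to sum to 1).
    """
    label_sets = {tuple(l.label_set) for l in labelings}
    if len(label_sets) != 1:
        raise ValueError("all fits must share the same label set")
    labels = list(label_sets.pop())
    lam_rows, A_rows = [], []
    for fit, labeling in zip(fits, labelings):
        params = fit.params if hasattr(fit, "params") else fit
        order = [labeling.index_of(l) for l in labels]
        lam_rows.append(params.lambdas[order])
        A_rows.append(params.transmat[np.ix_(order, order)])
    lam = pd.Series(np.mean(lam_rows, axis=0), index=labels, name="lambda")
    A = np.mean(A_rows, axis=0)
    A = A / A.sum(axis=1, keepdims=True)  # guard numeric drift
    return lam, pd.DataFrame(A, index=labels, columns=labels)


def architecture_table(sequences, labelings, fits, traces, period_labels_list) -> pd.DataFrame:
    """Per-fish per-label per-period report: proportion, minutes, mean bout,
    and long-run occupancy (CSV-ready)."""
    rows = []
    for seq, labeling, fit, trace, periods in zip(sequences, labelings, fits, traces,
                                                  period_labels_list):
        params = fit.params if hasattr(fit, "params") else fit
        states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
        props = state_proportions(seq, labeling, periods)
        mins = state_minutes(seq, labeling, periods)
        bouts = bout_durations(seq, labeling, periods)
        occ = occupancy(params, labeling, states=states)
        for label in labeling.label_set:
            for period in props.columns:
                bout = bouts.loc[label, period] if period in bouts.columns else np.nan
                rows.append(
                    {
                        "fish_id": trace.fish_id,
                        "label": label,
                        "period": period,
                        "proportion": float(props.loc[label, period]),
                        "minutes": int(mins.loc[label, period]),
                        "mean_bout_min": float(bout) if pd.notna(bout) else np.nan,
                        "occupancy": float(occ[label]),
                    }
                )
    return pd.DataFrame(rows)
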