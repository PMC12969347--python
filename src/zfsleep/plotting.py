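"""Small diagnostic plots: state rasters and smoothed probability courses."""

from __future__ import annotations

import numpy as np

STATE_COLORS = {"S2": "#1f3b73", "S1": "#5b8dd9", "W1": "#f2a541", "W2": "#d1462f"}


def plot_state_sequence(states_list, labeling, ax=None):
    """Raster of decoded states, one row per fish (dark = sleep states)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.25 * len(states_list) + 1))
    mat = np.vstack([np.asarray(s) for s in states_list])
    ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fish")
    ax.set_title(" / ".join(labeling.label_set))
    return ax


def plot_smoothed_probabilities(prob_df, ax=None):
    """Smoothed per-label posterior probabilities over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for col in prob_df.columns:
        ax.plot(prob_df.index, prob_df[col], label=str(col),
                color=STATE_COLORS.get(str(col)))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("state probability")
    ax.set_ylim(0, 1)
    ax.legend(ncol=len(prob_df.columns), fontsize=8)
    return ax


def plot_activity_histogram(cohort, ax=None, max_value: int = 60):
    """Pooled activity histogram (heavy-tailed with a mode at zero)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    pooled = np.concatenate([t.values for t in cohort.traces])
    ax.hist(pooled, bins=np.arange(max_value + 2) - 0.5, density=True,
            color="#444444")
    ax.set_xlabel("activity (s/min)")
    ax.set_ylabel("density")
    ax.set_yscale("log")
    return ax
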