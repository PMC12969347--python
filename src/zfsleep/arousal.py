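"""Stimulus-aligned arousability analysis.

During one night, a mechano-acoustic stimulus is delivered every five
minutes; a fish counts as having responded if it shows any supra-threshold
movement in the two seconds after the stimulus.  Because a single 10-h
night gives less reliable per-fish HMM fits, states are decoded from one
4-state model fitted to all fish's night data concatenated; fish whose
decoded path never visits one of the four states are excluded.  The state
of the one-minute bin ending at the stimulus is the fish's state at that
stimulus.  Raw response fractions per state are corrected by the
probability of spontaneous movement — the same two-second detector applied
at the start of the bin beginning two minutes before the stimulus,
conditioned on that baseline bin's own state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ActivityTrace, RawActivitySeries, bin_activity
from .hmm import PoissonHMMResults, StateSequence
from .selection import fit_multistart


@dataclass
class StimulusProtocol:
    """Stimulus times plus the detector and baseline window geometry."""

    stimulus_times: pd.DatetimeIndex  # strictly increasing, on bin boundaries
    response_window_s: int = 2
    baseline_offset_s: int = 120
    inter_stimulus_s: int = 300

    def __post_init__(self):
        self.stimulus_times = pd.DatetimeIndex(self.stimulus_times)
        if len(self.stimulus_times) == 0:
            raise ValueError("protocol needs at least one stimulus")
        deltas = np.diff(self.stimulus_times.view("int64"))
        if np.any(deltas <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if not self.response_window_s < self.inter_stimulus_s:
            raise ValueError("response window must be shorter than the stimulus interval")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_times)

    def to_csv(self, path, fish_id: str = "") -> None:
        pd.DataFrame({"fish_id": fish_id, "timestamp": self.stimulus_times.astype(str)}).to_csv(
            path, index=False
        )

    @classmethod
    def read_csv(cls, path) -> "StimulusProtocol":
        df = pd.read_csv(path)
        return cls(pd.to_datetime(df["timestamp"]))


@dataclass
class ArousalResult:
    """Per-state stimulus counts and raw / baseline / corrected fractions."""

    table: pd.DataFrame  # index label; columns n, raw, baseline_n, baseline, corrected
    excluded_fish: list = field(default_factory=list)
    dropped_stimuli: int = 0

    def corrected(self) -> pd.Series:
        return self.table["corrected"]


def concatenated_fit(traces, n_states: int = 4, n_restarts: int = 20,
                     seed: int = 0) -> PoissonHMMResults:
    """One multi-sequence fit pooled over all fish (no cross-fish transitions)."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    return fit_multistart(traces, n_states, n_restarts=n_restarts, seed=seed)


def exclude_incomplete_fish(sequences: dict, n_states: int):
    """Keep fish whose decoded path visits every state at least once.

    Returns (retained ids, counts dict).
    """
    retained, excluded = [], []
    for fish_id, seq in sequences.items():
        states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
        if np.unique(states).size == n_states:
            retained.append(fish_id)
        else:
            excluded.append(fish_id)
    counts = {"retained": len(retained), "excluded": len(excluded),
              "total": len(sequences)}
    return retained, excluded, counts


def prestimulus_states(seq, trace: ActivityTrace, protocol: StimulusProtocol) -> pd.Series:
    """State index of the bin ending at each stimulus time.

    Stimuli must coincide with bin boundaries; a stimulus before one full
    bin has elapsed is dropped with a warning (NaN in the output).
    """
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    out = {}
    n_dropped = 0
    for ts in protocol.stimulus_times:
        off = (ts - trace.start_clock).total_seconds()
        if off % 60 != 0:
            raise ValueError(
                f"stimulus at {ts} is not on a 1-min bin boundary; re-align the bins"
            )
        idx = int(off // 60) - 1
        if idx < 0 or idx >= states.size:
            n_dropped += 1
            out[ts] = np.nan
            continue
        out[ts] = states[idx]
    if n_dropped:
        warnings.warn(f"{n_dropped} stimulus(es) outside the recorded span dropped")
    return pd.Series(out, name="state")


def _detector(raw: RawActivitySeries, t0: pd.Timestamp, window_s: int,
              threshold: float) -> bool | None:
    """Any supra-threshold sample within window_s after t0; None if uncovered.

    Sample i covers the interval [i/sr, (i+1)/sr) after the recording start,
    so the window holds samples [t0, t0 + window_s) — the first sample
    starting at or after the stimulus onward.
    """
    sr = int(round(raw.sample_rate))
    i0 = int(round((t0 - raw.start_clock).total_seconds() * sr))
    i1 = i0 + window_s * sr
    if i0 < 0 or i1 > raw.values.size:
        return None
    return bool(np.any(raw.values[i0:i1] > threshold))


def response_fractions(raws: dict, states_per_stim: dict, protocol: StimulusProtocol,
                       labeling, traces: dict | None = None,
                       active_threshold: float = 0.0) -> ArousalResult:
    """Per-state raw, baseline and corrected response fractions.

    ``raws`` maps fish_id -> RawActivitySeries and ``states_per_stim`` maps
    fish_id -> per-stimulus state indices (from :func:`prestimulus_states`).
    The baseline detector runs over the first two seconds of the bin
    starting ``baseline_offset_s`` before each stimulus and is tallied under
    that baseline bin's own state.
    """
    labels = list(labeling.label_set)
    hits = {l: 0 for l in labels}
    n = {l: 0 for l in labels}
    base_hits = {l: 0 for l in labels}
    base_n = {l: 0 for l in labels}
    dropped = 0
    for fish_id, per_stim in states_per_stim.items():
        raw = raws[fish_id]
        for ts, state in per_stim.items():
            if pd.isna(state):
                dropped += 1
                continue
            resp = _detector(raw, ts, protocol.response_window_s, active_threshold)
            if resp is None:
                dropped += 1
                continue
            lab = labeling[int(state)]
            n[lab] += 1
            hits[lab] += int(resp)
            # baseline window: first 2 s of the bin starting offset earlier
            tb = ts - pd.Timedelta(seconds=protocol.baseline_offset_s)
            off = (tb - raw.start_clock).total_seconds()
            if off < 0 or off % 60 != 0:
                continue
            idx = int(off // 60)
            states_fish = per_stim.attrs.get("full_states") if hasattr(per_stim, "attrs") else None
            if states_fish is None or idx >= len(states_fish):
                continue
            base_lab = labeling[int(states_fish[idx])]
            base_resp = _detector(raw, tb, protocol.response_window_s, active_threshold)
            if base_resp is None:
                continue
            base_n[base_lab] += 1
            base_hits[base_lab] += int(base_resp)
    rows = []
    for l in labels:
        raw_frac = hits[l] / n[l] if n[l] else np.nan
        base_frac = base_hits[l] / base_n[l] if base_n[l] else np.nan
        rows.append(
            {"label": l, "n": n[l], "raw": raw_frac, "baseline_n": base_n[l],
             "baseline": base_frac,
             "corrected": raw_frac - base_frac if n[l] and base_n[l] else np.nan}
        )
    table = pd.DataFrame(rows).set_index("label")
    return ArousalResult(table, dropped_stimuli=dropped)


def matched_activity_comparison(trace: ActivityTrace, seq, per_stim: pd.Series,
                                raw: RawActivitySeries, protocol: StimulusProtocol,
                                labeling, activity_value: int,
                                active_threshold: float = 0.0) -> pd.DataFrame:
    """Response fractions restricted to stimuli whose pre-stimulus bin had a
    fixed activity value, split by decoded label.

    Distinguishes state effects from activity effects: at a matched activity
    level, a light-sleep bin should still respond less than a wake bin.
    Also reports the label split among the qualifying bins.
    """
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    counts, resp_counts = {}, {}
    for ts, state in per_stim.items():
        if pd.isna(state):
            continue
        idx = int((ts - trace.start_clock).total_seconds() // 60) - 1
        if trace.values[idx] != activity_value:
            continue
        lab = labeling[int(state)]
        r = _detector(raw, ts, protocol.response_window_s, active_threshold)
        if r is None:
            continue
        counts[lab] = counts.get(lab, 0) + 1
        resp_counts[lab] = resp_counts.get(lab, 0) + int(r)
    if not counts:
        return pd.DataFrame(columns=["n", "split", "response_fraction"])
    total = sum(counts.values())
    rows = []
    for lab in labeling.label_set:
        if lab not in counts:
            continue
        rows.append(
            {"label": lab, "n": counts[lab], "split": counts[lab] / total,
             "response_fraction": resp_counts[lab] / counts[lab]}
        )
    return pd.DataFrame(rows).set_index("label")


def run_arousal_analysis(raws: dict, protocol: StimulusProtocol, n_states: int = 4,
                         n_restarts: int = 20, seed: int = 0,
                         active_threshold: float = 0.0):
    """Full pipeline: bin, concatenated fit, decode, exclude, classify, correct.

    Returns (ArousalResult, per-fish StateSequence dict, fit results).
    """
    from .architecture import label_states  # deferred: avoid import cycle

    traces = {fid: bin_activity(raw, active_threshold) for fid, raw in raws.items()}
    fit = concatenated_fit(list(traces.values()), n_states, n_restarts, seed)
    labeling = label_states(fit.params)
    sequences = {}
    for fid, tr in traces.items():
        sequences[fid] = fit.decode(tr)
    retained, excluded, counts = exclude_incomplete_fish(sequences, n_states)
    per_stim = {}
    for fid in retained:
        s = prestimulus_states(sequences[fid], traces[fid], protocol)
        s.attrs["full_states"] = sequences[fid].states
        per_stim[fid] = s
    result = response_fractions(
        {fid: raws[fid] for fid in retained}, per_stim, protocol, labeling,
        active_threshold=active_threshold,
    )
    result.excluded_fish = excluded
    result.table.attrs["exclusion_counts"] = counts
    return result, sequences, fit, labeling
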