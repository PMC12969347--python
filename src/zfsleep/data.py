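"""Containers and I/O for larval zebrafish locomotor activity recordings.

Activity is recorded per fish as pixel changes between consecutive video
frames and summarised, for modelling, as whole seconds of locomotor activity
per one-minute bin (an integer in [0, 60]).  A light schedule (e.g. a 14:10
light:dark cycle with lights on 09:00-23:00) assigns each bin to day or
night.  The conventional behavioural definition of zebrafish sleep — any
one-minute bin with zero activity — is also provided here so that HMM-derived
sleep states can be compared against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_SECONDS = 60

DAY = "day"
NIGHT = "night"

#: schedule conditions and their day/night period mapping
CONDITIONS = ("light", "dark", "subjective_day", "subjective_night")
_TO_PERIOD = {
    "light": DAY,
    "subjective_day": DAY,
    "dark": NIGHT,
    "subjective_night": NIGHT,
}


@dataclass(frozen=True)
class RawActivitySeries:
    """High-rate activity magnitudes for one fish (e.g. 1 Hz or 30 Hz)."""

    fish_id: str
    start_clock: pd.Timestamp
    sample_rate: float  # samples per second, >= 1
    values: np.ndarray  # non-negative magnitudes

    def __post_init__(self):
        object.__setattr__(self, "start_clock", pd.Timestamp(self.start_clock))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("raw activity series must be a non-empty 1-d array")
        if np.any(values < 0):
            raise ValueError("raw activity magnitudes must be non-negative")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "values", values)

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate


@dataclass(frozen=True)
class ActivityTrace:
    """One fish's activity in integer seconds-active per one-minute bin."""

    fish_id: str
    start_clock: pd.Timestamp
    values: np.ndarray  # integers in [0, 60]
    bin_width: int = BIN_SECONDS

    def __post_init__(self):
        object.__setattr__(self, "start_clock", pd.Timestamp(self.start_clock))
        values = np.asarray(self.values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("activity trace must be a non-empty 1-d array")
        if not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(np.asarray(values, dtype=float))
            if not np.allclose(rounded, values, atol=1e-9):
                raise ValueError("activity values must be integers (seconds per minute)")
            values = rounded.astype(np.int64)
        else:
            values = values.astype(np.int64)
        if values.min() < 0 or values.max() > BIN_SECONDS:
            raise ValueError("activity values must lie in [0, 60] seconds per minute")
        if self.bin_width != BIN_SECONDS:
            raise ValueError("bin_width is fixed at 60 seconds")
        object.__setattr__(self, "values", values)

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_starts(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_clock, periods=self.n_bins, freq="60s")

    @property
    def end_clock(self) -> pd.Timestamp:
        return self.start_clock + pd.Timedelta(seconds=60 * self.n_bins)


@dataclass
class LightSchedule:
    """Ordered, contiguous labelled intervals defining the lighting protocol.

    Intervals are half-open ``[start, end)`` and a bin belongs to the interval
    containing its start time, so a bin starting exactly at lights-off is a
    night bin.
    """

    intervals: list  # of (start: Timestamp, end: Timestamp, condition: str)

    def __post_init__(self):
        cleaned = []
        for start, end, cond in self.intervals:
            start, end = pd.Timestamp(start), pd.Timestamp(end)
            if cond not in CONDITIONS:
                raise ValueError(f"unknown schedule condition {cond!r}")
            if not start < end:
                raise ValueError("schedule interval must have start < end")
            cleaned.append((start, end, cond))
        cleaned.sort(key=lambda iv: iv[0])
        for (s0, e0, _), (s1, _, _) in zip(cleaned, cleaned[1:]):
            if s1 != e0:
                raise ValueError(
                    f"schedule intervals must be contiguous; gap/overlap at {e0} vs {s1}"
                )
        self.intervals = cleaned

    @property
    def start(self) -> pd.Timestamp:
        return self.intervals[0][0]

    @property
    def end(self) -> pd.Timestamp:
        return self.intervals[-1][1]

    @classmethod
    def ld_cycle(
        cls,
        start,
        duration_h: float = 48.0,
        lights_on_hour: int = 9,
        lights_off_hour: int = 23,
        subjective: bool = False,
    ) -> "LightSchedule":
        """Standard light:dark cycle covering ``[start, start + duration_h)``.

        Defaults give the 14:10 LD protocol with white lights on 09:00-23:00.
        With ``subjective=True`` the same phases are labelled subjective day /
        subjective night (free-running constant dark after entrainment).
        """
        start = pd.Timestamp(start)
        end = start + pd.Timedelta(hours=duration_h)
        on_lab = "subjective_day" if subjective else "light"
        off_lab = "subjective_night" if subjective else "dark"
        # walk day by day from the midnight before `start`
        day0 = start.normalize() - pd.Timedelta(days=1)
        edges = []
        for d in range(int(duration_h / 24) + 3):
            day = day0 + pd.Timedelta(days=d)
            edges.append((day + pd.Timedelta(hours=lights_on_hour), on_lab))
            edges.append((day + pd.Timedelta(hours=lights_off_hour), off_lab))
        intervals = []
        for (t0, lab), (t1, _) in zip(edges, edges[1:]):
            if t1 <= start or t0 >= end:
                continue
            intervals.append((max(t0, start), min(t1, end), lab))
        return cls(intervals)

    def condition_at(self, ts) -> str:
        ts = pd.Timestamp(ts)
        for s, e, cond in self.intervals:
            if s <= ts < e:
                return cond
        raise ValueError(f"timestamp {ts} is not covered by the schedule")

    def period_labels(self, trace: ActivityTrace) -> np.ndarray:
        """Day/night label per bin (by bin start time)."""
        return label_bins(trace, self)


def bin_activity(raw: RawActivitySeries, active_threshold: float = 0.0) -> ActivityTrace:
    """Integrate a high-rate series into 1-min bins of seconds-active.

    A second counts as active when any sample within it exceeds
    ``active_threshold``; the bin value is the number of active seconds
    (0-60).  A trailing partial minute is discarded.
    """
    if active_threshold < 0:
        raise ValueError("active_threshold must be non-negative")
    sr = raw.sample_rate
    if abs(sr - round(sr)) > 1e-9 or sr < 1:
        raise ValueError("sample_rate must be a whole number of samples per second")
    sr = int(round(sr))
    n_min = raw.values.size // (60 * sr)
    if n_min < 1:
        raise ValueError("raw series shorter than one full minute")
    chunk = raw.values[: n_min * 60 * sr].reshape(n_min, 60, sr)
    active_sec = (chunk > active_threshold).any(axis=2)
    values = active_sec.sum(axis=1).astype(np.int64)
    return ActivityTrace(raw.fish_id, raw.start_clock, values)


def label_bins(trace: ActivityTrace, schedule: LightSchedule) -> np.ndarray:
    """Label each bin 'day' or 'night' by the interval containing its start."""
    starts = np.array([s for s, _, _ in schedule.intervals], dtype="datetime64[ns]")
    conds = [c for _, _, c in schedule.intervals]
    end = schedule.end
    bin_starts = trace.bin_starts.values
    idx = np.searchsorted(starts, bin_starts, side="right") - 1
    labels = np.empty(trace.n_bins, dtype=object)
    for i, (t, j) in enumerate(zip(bin_starts, idx)):
        if j < 0 or pd.Timestamp(t) >= end:
            raise ValueError(f"bin {i} (start {pd.Timestamp(t)}) is not covered by the schedule")
        labels[i] = _TO_PERIOD[conds[j]]
    return labels


def conventional_sleep(trace: ActivityTrace):
    """Conventional zebrafish sleep: a bin is asleep iff activity == 0.

    Returns (per-bin boolean flags, total sleep minutes).
    """
    flags = trace.values == 0
    return flags, int(flags.sum())


@dataclass
class Cohort:
    """A labelled group of fish (genotype or treatment) with their traces."""

    label: str
    traces: list  # of ActivityTrace
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.traces:
            raise ValueError("cohort must contain at least one trace")
        ids = [t.fish_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("fish_ids must be unique within a cohort")

    @property
    def fish_ids(self):
        return [t.fish_id for t in self.traces]

    def __len__(self):
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_traces(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (fish_id, timestamp, activity_sec), sorted."""
    frames = []
    for tr in sorted(cohort.traces, key=lambda t: t.fish_id):
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": tr.fish_id,
                    "timestamp": tr.bin_starts.strftime("%Y-%m-%dT%H:%M:%S"),
                    "activity_sec": tr.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path, label: str = "cohort") -> Cohort:
    """Read a trace CSV back into a :class:`Cohort`.

    Strict by contract: non-integer values are rounded with a warning, values
    outside [0, 60] or gaps in the 60 s bin grid raise with the offending row.
    """
    df = pd.read_csv(path)
    required = {"fish_id", "timestamp", "activity_sec"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    traces = []
    for fish_id, grp in df.groupby("fish_id", sort=True):
        grp = grp.reset_index()  # 'index' = original row position
        ts = pd.to_datetime(grp["timestamp"])
        vals = grp["activity_sec"].to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 60) | ~np.isfinite(vals)
        if bad.any():
            row = int(grp["index"][bad.argmax()]) + 2  # header + 1-based
            raise ValueError(f"activity value out of range [0, 60] at CSV row {row}")
        if not np.allclose(vals, np.rint(vals), atol=1e-9):
            warnings.warn("non-integer activity values rounded to nearest integer")
            vals = np.rint(vals)
        steps = ts.diff().dt.total_seconds().to_numpy()[1:]
        if np.any(steps != 60):
            k = int(np.argmax(steps != 60))
            row = int(grp["index"][k + 1]) + 2
            raise ValueError(
                f"fish {fish_id!r}: time gap of {steps[k]:.0f} s before CSV row {row} "
                "(bins must be contiguous 60 s)"
            )
        traces.append(ActivityTrace(str(fish_id), ts.iloc[0], vals.astype(np.int64)))
    return Cohort(label, traces)


def write_schedule(schedule: LightSchedule, path) -> None:
    pd.DataFrame(
        [(s.isoformat(), e.isoformat(), c) for s, e, c in schedule.intervals],
        columns=["start", "end", "condition"],
    ).to_csv(path, index=False)


def read_schedule(path) -> LightSchedule:
    df = pd.read_csv(path)
    return LightSchedule(
        [(pd.Timestamp(r.start), pd.Timestamp(r.end), r.condition) for r in df.itertuples()]
    )


def coerce_activity(values) -> np.ndarray:
    """Lenient coercion for external data: round to integer, clip to [0, 60]."""
    vals = np.asarray(values, dtype=float)
    rounded = np.rint(vals)
    if not np.array_equal(rounded, vals):
        warnings.warn("non-integer activity values rounded to nearest integer")
    clipped = np.clip(rounded, 0, 60)
    if not np.array_equal(clipped, rounded):
        warnings.warn("activity values outside [0, 60] clipped")
    return clipped.astype(np.int64)


def load_figshare_activity(path, label: str = "figshare") -> Cohort:
    """Optional loader for the study's deposited recordings (never required).

    Expects a long-format CSV with columns ``fish`` (id), ``time`` (ISO bin
    start) and ``activity`` (seconds active per minute, possibly fractional);
    values are coerced leniently via :func:`coerce_activity`.
    """
    df = pd.read_csv(path)
    colmap = {"fish": "fish_id", "time": "timestamp", "activity": "activity_sec"}
    missing = set(colmap) - set(df.columns)
    if missing:
        raise ValueError(f"deposit CSV missing columns {sorted(missing)}")
    traces = []
    for fish_id, grp in df.rename(columns=colmap).groupby("fish_id", sort=True):
        ts = pd.to_datetime(grp["timestamp"])
        vals = coerce_activity(grp["activity_sec"].to_numpy())
        traces.append(ActivityTrace(str(fish_id), ts.iloc[0], vals))
    return Cohort(label, traces)
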