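"""Synthetic cohort generator: circadian, time-inhomogeneous HMM fish.

Ground truth is a hidden Markov chain whose transition matrix switches
between a day matrix (wake-dominated) and a night matrix (sleep-dominated)
at light/dark boundaries, while the per-state emission rates stay constant
across the day — the circadian structure of the data comes entirely from
occupancy changes, not from rate changes.  Each simulated fish gets
log-normally jittered rates to mimic individual variability.  Protocol
variants reproduce the sleep-deprivation experiment (lights on for the
first 6 h of night 2, then a rebound window with boosted deep-sleep
persistence) and the night-time arousal assay (1 Hz raw traces with a
mechano-acoustic stimulus every 5 minutes and state-dependent response
probabilities).

Named presets perturb the wild-type matrices to emulate the direction of
the studied genetic and pharmacological manipulations (melatonin,
serotonin, noradrenaline) and the free-running constant-dark condition,
which collapses to a 3-state generator without the high-activity wake
state.  Preset matrices are package constants chosen for their qualitative
direction, not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import Cohort, LightSchedule, RawActivitySeries, label_bins, ActivityTrace
from .hmm import stationary_distribution
from .reference import LABELS3, LABELS4, REFERENCE_LAMBDAS

DEFAULT_START = "2024-01-01 09:00:00"

# wild-type matrices (rows/cols in label order S2, S1, W1, W2); designed so
# the night stationary distribution concentrates ~80% on S2+S1 and the day
# one ~75% on W1+W2, with strong self-persistence throughout
WT_DAY = np.array(
    [
        [0.860, 0.080, 0.040, 0.020],
        [0.040, 0.840, 0.090, 0.030],
        [0.010, 0.040, 0.900, 0.050],
        [0.005, 0.015, 0.080, 0.900],
    ]
)
WT_NIGHT = np.array(
    [
        [0.950, 0.030, 0.015, 0.005],
        [0.060, 0.880, 0.040, 0.020],
        [0.060, 0.060, 0.850, 0.030],
        [0.020, 0.040, 0.060, 0.880],
    ]
)

CD_DAY = np.array(  # constant dark, subjective day (labels S2, S1, W)
    [
        [0.900, 0.060, 0.040],
        [0.050, 0.880, 0.070],
        [0.030, 0.070, 0.900],
    ]
)
CD_NIGHT = np.array(
    [
        [0.950, 0.035, 0.015],
        [0.070, 0.880, 0.050],
        [0.050, 0.070, 0.880],
    ]
)

DEFAULT_RESPONSE_PROBS = {"S2": 0.1, "S1": 0.3, "W1": 0.6, "W2": 0.8}

PRESET_NAMES = (
    "wt",
    "constant_dark",
    "aanat2_like",
    "melatonin_treated",
    "tph2_like",
    "quipazine_like",
    "dbh_like",
    "prazosin_like",
)


@dataclass
class SyntheticSpec:
    """Ground-truth generative description of a simulated cohort."""

    labels: tuple = LABELS4
    lambdas: np.ndarray = None  # per-label rates, s/min
    day_transitions: np.ndarray = None
    night_transitions: np.ndarray = None
    jitter_sd: float = 0.1  # lognormal sd of per-fish rate jitter
    zip_weights: np.ndarray | None = None
    response_probs: dict | None = None  # label -> P(respond | stimulus)
    rebound_boost: float = 0.05  # post-deprivation S2 self-transition increment
    subjective: bool = False  # constant-dark (free-running) schedule labels
    lights_on_hour: int = 9
    lights_off_hour: int = 23

    def __post_init__(self):
        if self.lambdas is None:
            self.lambdas = np.array([REFERENCE_LAMBDAS[l] for l in self.labels])
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.day_transitions is None:
            self.day_transitions = WT_DAY.copy()
        if self.night_transitions is None:
            self.night_transitions = WT_NIGHT.copy()
        self.day_transitions = np.asarray(self.day_transitions, dtype=float)
        self.night_transitions = np.asarray(self.night_transitions, dtype=float)
        K = len(self.labels)
        for name, A in (("day", self.day_transitions), ("night", self.night_transitions)):
            if A.shape != (K, K) or np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1) > 1e-8):
                raise ValueError(f"{name} transition matrix must be {K}x{K} row-stochastic")
        if self.lambdas.shape != (K,) or np.any(self.lambdas <= 0):
            raise ValueError("one positive rate per label required")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.zip_weights is not None:
            self.zip_weights = np.asarray(self.zip_weights, dtype=float)
            if np.any(self.zip_weights < 0) or np.any(self.zip_weights >= 1):
                raise ValueError("zip weights must lie in [0, 1)")
        if self.response_probs is not None:
            bad = [l for l, p in self.response_probs.items() if not 0 <= p <= 1]
            if bad:
                raise ValueError(f"response probabilities outside [0, 1] for {bad}")

    def to_yaml(self, path=None) -> str:
        obj = {
            "labels": list(self.labels),
            "lambdas": self.lambdas.tolist(),
            "day_transitions": self.day_transitions.tolist(),
            "night_transitions": self.night_transitions.tolist(),
            "jitter_sd": self.jitter_sd,
            "zip_weights": None if self.zip_weights is None else self.zip_weights.tolist(),
            "response_probs": self.response_probs,
            "rebound_boost": self.rebound_boost,
            "subjective": self.subjective,
            "lights_on_hour": self.lights_on_hour,
            "lights_off_hour": self.lights_off_hour,
        }
        text = yaml.safe_dump(obj, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SyntheticSpec":
        if isinstance(source, str) and "\n" in source:
            obj = yaml.safe_load(source)
        else:
            with open(source) as fh:
                obj = yaml.safe_load(fh)
        obj["labels"] = tuple(obj["labels"])
        for key in ("lambdas", "day_transitions", "night_transitions", "zip_weights"):
            if obj.get(key) is not None:
                obj[key] = np.asarray(obj[key], dtype=float)
        return cls(**obj)


@dataclass
class GroundTruth:
    """Per-fish generating parameters and hidden paths for a simulated cohort."""

    spec: SyntheticSpec
    schedule: LightSchedule
    states: dict = field(default_factory=dict)  # fish_id -> hidden label-index path
    lambdas: dict = field(default_factory=dict)  # fish_id -> jittered rates
    n_clipped: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)  # protocol events (boost windows, stimuli)

    def label_path(self, fish_id) -> np.ndarray:
        return np.array([self.spec.labels[s] for s in self.states[fish_id]], dtype=object)


def _perturb(A, edits) -> np.ndarray:
    """Return a row-stochastic copy of A with whole rows replaced."""
    out = A.copy()
    for row, values in edits.items():
        out[row] = values
    if np.any(np.abs(out.sum(axis=1) - 1) > 1e-8):
        raise ValueError("perturbed rows must sum to 1")
    return out


def preset(name: str) -> SyntheticSpec:
    """Named generator presets emulating the studied manipulations.

    Directions (night, unless noted): aanat2_like / tph2_like shift deep
    sleep (S2) into light sleep (S1); quipazine_like does the opposite;
    melatonin_treated suppresses the day-time high-activity wake state W2;
    dbh_like / prazosin_like gain S2 at the expense of S1 and wake
    maintenance; constant_dark removes W2 entirely (3-state generator under
    a subjective-day/night schedule).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    if name == "wt":
        return SyntheticSpec(response_probs=dict(DEFAULT_RESPONSE_PROBS))
    if name == "constant_dark":
        return SyntheticSpec(
            labels=LABELS3,
            lambdas=np.array([0.02, 1.18, 4.07]),
            day_transitions=CD_DAY,
            night_transitions=CD_NIGHT,
            subjective=True,
        )
    wt = preset("wt")
    if name == "aanat2_like":  # less S2, more S1 at night; day unchanged
        night = _perturb(wt.night_transitions, {
            0: [0.880, 0.090, 0.020, 0.010],
            1: [0.030, 0.920, 0.030, 0.020],
        })
        return replace(wt, night_transitions=night,
                       lambdas=np.array([0.05, 1.45, 4.07, 7.49]))
    if name == "tph2_like":  # like aanat2 at night, plus S2 loss by day and higher rates
        night = _perturb(wt.night_transitions, {
            0: [0.890, 0.080, 0.020, 0.010],
            1: [0.030, 0.910, 0.040, 0.020],
        })
        day = _perturb(wt.day_transitions, {0: [0.800, 0.110, 0.060, 0.030]})
        return replace(wt, night_transitions=night, day_transitions=day,
                       lambdas=np.array([0.03, 1.45, 4.30, 8.30]))
    if name == "quipazine_like":  # more S2, less S1 at night; lower rates
        night = _perturb(wt.night_transitions, {
            0: [0.975, 0.012, 0.009, 0.004],
            1: [0.120, 0.820, 0.040, 0.020],
        })
        return replace(wt, night_transitions=night,
                       lambdas=np.array([0.015, 1.10, 3.50, 6.50]))
    if name == "melatonin_treated":  # day W2 suppressed; night S1 -> W1/W2
        day = _perturb(wt.day_transitions, {
            2: [0.010, 0.040, 0.940, 0.010],
            3: [0.020, 0.030, 0.150, 0.800],
        })
        night = _perturb(wt.night_transitions, {1: [0.060, 0.840, 0.070, 0.030]})
        return replace(wt, day_transitions=day, night_transitions=night,
                       lambdas=np.array([0.01, 1.18, 3.60, 7.49]))
    if name == "dbh_like":  # more S2 day and night; weaker wake maintenance
        night = _perturb(wt.night_transitions, {
            0: [0.970, 0.015, 0.010, 0.005],
            1: [0.100, 0.840, 0.040, 0.020],
            3: [0.060, 0.060, 0.060, 0.820],
        })
        day = _perturb(wt.day_transitions, {
            2: [0.030, 0.070, 0.850, 0.050],
            3: [0.030, 0.050, 0.080, 0.840],
        })
        return replace(wt, night_transitions=night, day_transitions=day,
                       lambdas=np.array([0.02, 1.18, 4.07, 8.40]))
    if name == "prazosin_like":  # phenocopies dbh_like with milder day effect
        night = _perturb(wt.night_transitions, {
            0: [0.965, 0.020, 0.010, 0.005],
            1: [0.100, 0.840, 0.040, 0.020],
            3: [0.050, 0.050, 0.070, 0.830],
        })
        day = _perturb(wt.day_transitions, {
            2: [0.025, 0.060, 0.865, 0.050],
            3: [0.025, 0.045, 0.080, 0.850],
        })
        return replace(wt, night_transitions=night, day_transitions=day,
                       lambdas=np.array([0.02, 1.18, 4.07, 8.20]))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# sampling machinery
# ---------------------------------------------------------------------------

def _sample_fish(spec: SyntheticSpec, matrices_per_bin: np.ndarray, rng):
    """Hidden path + binned observations for one fish.

    ``matrices_per_bin`` is a (T, K, K) stack; the transition into bin t+1
    uses the matrix of bin t+1 (the regime being entered governs the
    dynamics from the boundary onward).
    """
    K = len(spec.labels)
    T = matrices_per_bin.shape[0]
    lam = spec.lambdas * np.exp(rng.normal(0.0, spec.jitter_sd, K))
    states = np.empty(T, dtype=np.int64)
    pi0 = stationary_distribution(matrices_per_bin[0])
    states[0] = rng.choice(K, p=pi0)
    u = rng.random(T)
    for t in range(1, T):
        row = matrices_per_bin[t][states[t - 1]]
        states[t] = min(int(np.searchsorted(np.cumsum(row), u[t])), K - 1)
    obs = rng.poisson(lam[states])
    if spec.zip_weights is not None:
        zero = rng.random(T) < spec.zip_weights[states]
        obs[zero] = 0
    n_clipped = int((obs > 60).sum())
    return np.minimum(obs, 60).astype(np.int64), states, lam, n_clipped


def _matrix_stack(spec: SyntheticSpec, schedule: LightSchedule, trace_like) -> np.ndarray:
    labels = label_bins(trace_like, schedule)
    K = len(spec.labels)
    stack = np.empty((labels.size, K, K))
    day_mask = labels == "day"
    stack[day_mask] = spec.day_transitions
    stack[~day_mask] = spec.night_transitions
    return stack


def _placeholder_trace(start, n_bins) -> ActivityTrace:
    return ActivityTrace("_grid", start, np.zeros(n_bins, dtype=np.int64))


def generate_cohort(spec: SyntheticSpec, n_fish: int = 20, duration_h: float = 48.0,
                    seed: int = 0, start=DEFAULT_START, label: str = "synthetic"):
    """Simulate a cohort under the spec's light:dark protocol.

    Returns (Cohort, GroundTruth); fully reproducible from ``seed``.
    """
    n_bins = int(round(duration_h * 60))
    if abs(duration_h * 60 - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("duration must be a whole number of minutes")
    start = pd.Timestamp(start)
    schedule = LightSchedule.ld_cycle(
        start, duration_h, spec.lights_on_hour, spec.lights_off_hour, spec.subjective
    )
    stack = _matrix_stack(spec, schedule, _placeholder_trace(start, n_bins))
    truth = GroundTruth(spec, schedule)
    traces = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_fish)):
        rng = np.random.default_rng(child)
        obs, states, lam, n_clip = _sample_fish(spec, stack, rng)
        fish_id = f"fish{i:03d}"
        traces.append(ActivityTrace(fish_id, start, obs))
        truth.states[fish_id] = states
        truth.lambdas[fish_id] = lam
        truth.n_clipped[fish_id] = n_clip
    return Cohort(label, traces), truth


def generate_sleep_deprivation(spec: SyntheticSpec, n_fish: int = 20, seed: int = 0,
                               start=DEFAULT_START, deprivation_h: float = 6.0,
                               label: str = "sleep_deprivation"):
    """48-h protocol with light-forced waking early in night 2.

    Night 2's first ``deprivation_h`` hours stay lit (day matrix, labelled
    light in the schedule); the remaining rebound window uses the night
    matrix with the deep-sleep self-transition raised by
    ``spec.rebound_boost`` (row renormalised).
    """
    start = pd.Timestamp(start)
    n_bins = 48 * 60
    on, off = spec.lights_on_hour, spec.lights_off_hour
    day0 = start.normalize()
    h = pd.Timedelta(hours=1)
    dep_end = day0 + pd.Timedelta(days=1) + off * h + pd.Timedelta(hours=deprivation_h)
    schedule = LightSchedule([
        (day0 + on * h, day0 + off * h, "light"),
        (day0 + off * h, day0 + pd.Timedelta(days=1) + on * h, "dark"),
        (day0 + pd.Timedelta(days=1) + on * h, dep_end, "light"),  # day 2 + lit deprivation
        (dep_end, day0 + pd.Timedelta(days=2) + on * h, "dark"),  # rebound window
    ])
    stack = _matrix_stack(spec, schedule, _placeholder_trace(start, n_bins))
    # boost S2 self-transition inside the rebound window
    boosted = spec.night_transitions.copy()
    s2 = 0  # S2 is label index 0 by construction
    boosted[s2, s2] = min(boosted[s2, s2] + spec.rebound_boost, 1.0)
    boosted[s2] /= boosted[s2].sum()
    grid = _placeholder_trace(start, n_bins).bin_starts
    rebound_mask = (grid.values >= np.datetime64(dep_end)) & (
        grid.values < np.datetime64(day0 + pd.Timedelta(days=2) + on * h)
    )
    stack[rebound_mask] = boosted
    truth = GroundTruth(spec, schedule)
    truth.events["deprivation"] = {
        "lights_on_until": dep_end.isoformat(),
        "rebound_boost": spec.rebound_boost,
    }
    traces = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_fish)):
        rng = np.random.default_rng(child)
        obs, states, lam, n_clip = _sample_fish(spec, stack, rng)
        fish_id = f"fish{i:03d}"
        traces.append(ActivityTrace(fish_id, start, obs))
        truth.states[fish_id] = states
        truth.lambdas[fish_id] = lam
        truth.n_clipped[fish_id] = n_clip
    return Cohort(label, traces), truth


def generate_arousal_experiment(spec: SyntheticSpec, n_fish: int = 20,
                                n_stimuli: int = 99, seed: int = 0,
                                start=None, label: str = "arousal"):
    """One night of 1 Hz raw traces with periodic stimuli.

    Recording runs lights-off to lights-on (10 h at 1 Hz); stimuli fall on
    1-min bin boundaries every 5 min starting 90 min after lights-off.  A
    second of activity is injected right after a stimulus with the current
    hidden state's response probability; spontaneous per-second activity is
    Bernoulli(rate/60), independent of the stimuli.

    Returns ({fish_id: RawActivitySeries}, StimulusProtocol, GroundTruth).
    """
    from .arousal import StimulusProtocol  # deferred: avoid import cycle

    if spec.response_probs is None:
        raise ValueError("spec.response_probs must be set for the arousal protocol")
    missing = [l for l in spec.labels if l not in spec.response_probs]
    if missing:
        raise ValueError(f"response probability missing for labels {missing}")
    if start is None:
        start = pd.Timestamp(DEFAULT_START).normalize() + pd.Timedelta(
            hours=spec.lights_off_hour
        )
    start = pd.Timestamp(start)
    night_h = 24 - (spec.lights_off_hour - spec.lights_on_hour)
    n_bins = int(night_h * 60)
    stim_offsets_min = 90 + 5 * np.arange(n_stimuli)
    if stim_offsets_min[-1] >= n_bins:
        raise ValueError("stimulus train longer than the night recording")
    schedule = LightSchedule([(start, start + pd.Timedelta(hours=night_h), "dark")])
    stack = _matrix_stack(spec, schedule, _placeholder_trace(start, n_bins))
    resp = np.array([spec.response_probs[l] for l in spec.labels])
    stim_times = start + pd.to_timedelta(stim_offsets_min, unit="m")
    protocol = StimulusProtocol(stimulus_times=stim_times)
    truth = GroundTruth(spec, schedule)
    truth.events["stimulus_offsets_min"] = stim_offsets_min.tolist()
    raws = {}
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_fish)):
        rng = np.random.default_rng(child)
        K = len(spec.labels)
        lam = spec.lambdas * np.exp(rng.normal(0.0, spec.jitter_sd, K))
        states = np.empty(n_bins, dtype=np.int64)
        states[0] = rng.choice(K, p=stationary_distribution(stack[0]))
        u = rng.random(n_bins)
        for t in range(1, n_bins):
            row = stack[t][states[t - 1]]
            states[t] = min(int(np.searchsorted(np.cumsum(row), u[t])), K - 1)
        # per-second spontaneous activity consistent with the per-minute rates
        p_sec = np.minimum(lam[states] / 60.0, 1.0)
        raw = (rng.random((n_bins, 60)) < p_sec[:, None]).astype(float).ravel()
        responded = rng.random(n_stimuli) < resp[states[stim_offsets_min - 1]]
        for m, hit in zip(stim_offsets_min, responded):
            if hit:
                raw[m * 60] = 1.0  # first second after the stimulus
        fish_id = f"fish{i:03d}"
        raws[fish_id] = RawActivitySeries(fish_id, start, 1.0, raw)
        truth.states[fish_id] = states
        truth.lambdas[fish_id] = lam
        truth.events.setdefault("responses", {})[fish_id] = responded.tolist()
    return raws, protocol, truth
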