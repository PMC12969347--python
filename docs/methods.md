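# Methods

## Data model

Activity is stored as integer seconds-active per one-minute bin (0–60),
anchored to clock time. High-rate recordings (e.g. 1 Hz or 30 Hz pixel
change magnitudes) are binned by counting, per minute, the whole seconds
containing at least one supra-threshold sample; a trailing partial minute
is discarded. Light schedules are ordered, contiguous, half-open
`[start, end)` intervals labelled light/dark (or subjective day/night for
free-running recordings); a bin belongs to the interval containing its
start time, so a bin starting exactly at lights-off is a night bin. The
default protocol is 14 h light : 10 h dark with lights on 09:00–23:00 and
recording start 09:00. Conventional sleep is defined per bin as zero
activity. The strict CSV reader rejects out-of-range values and time gaps
with the offending row; only the (optional) external-deposit loader
coerces leniently (round to integer, clip to [0, 60], with warnings),
since real pixel-based activity may be fractional while the model treats
observations as counts.

## HMM machinery

Emissions are Poisson with per-state mean λ_k (s/min), optionally
zero-inflated: `P(x|k) = w_k·[x=0] + (1−w_k)·Pois(x; λ_k)`. Inference uses
the scaled (normalised-forward) recursions rather than log-space sums; the
emission likelihood matrix is row-max-normalised first so that the scaled
recursion stays finite even when every state finds an observation
unlikely. Forward/backward/Viterbi and the full Poisson EM loop are numba
kernels; the zero-inflated EM shares the same E-step structure in NumPy,
with the standard responsibility split at zero counts for the M-step.

Numerical choices:

- `tol = 1e-4` absolute log-likelihood gain, `max_iter = 500`.
- `λ_floor = 1e-3` s/min prevents degenerate zero-rate states; it sits far
  below the smallest rate of interest (≈ 0.02 s/min). States whose
  posterior mass collapses are floored and flagged on the results object.
- Initialisation (multi-restart): λ from the K inner quantiles of the
  pooled observations with multiplicative log-normal jitter (sd 0.5,
  floor 0.1 before jitter); transition rows near-diagonal (self 0.8, rest
  uniform) with Dirichlet jitter (concentration 50); π uniform. All
  jitter derives from the restart seed; restart seeds spawn
  deterministically from the base seed, so fits are bit-reproducible.
- Viterbi ties break toward the lower state index, making decoded paths
  deterministic.
- Sampling clips observations at 60 s/min (the physical bound); clip
  events are counted and returned.
- Multi-sequence fits pool sufficient statistics per sequence with no
  transitions across sequence boundaries; π is re-estimated as the mean
  first-bin posterior across sequences.
- The stationary distribution comes from the (unique) unit eigenvalue of
  Aᵀ; if the unit eigenvalue is not simple (reducible/periodic chains,
  which EM on real data does not produce but callers can construct), the
  code falls back to empirical decoded-path frequencies when a path is
  supplied and raises otherwise.

## Model selection

`BIC = p·ln(n) − 2·loglik` with `p = (K−1) + K(K−1) + K` for Poisson
(initial, transition, rate parameters) and `p + K` with zero-inflation
weights. K is selected over 2–6 by best-of-n-restarts likelihood per K;
BIC ties break toward the smaller K (parsimony). A fitted model whose
adjacent rates fall within 0.1 s/min is flagged with a state-similarity
warning — fits of over-specified K to simple data select the range
minimum, and this threshold only marks truly indistinguishable rates.
The default restart count is configurable; 1000 restarts reproduces the
original protocol, while the tests and experiments here use 10–20, which
is ample for the well-separated synthetic generators (the EM surface for
these data is benign; see the recovery experiment below).

Two surrogate experiments validate the protocol end to end:

- **State-number recovery** — sample sequences from a known 4-state model,
  re-run the full selection, report the fraction recovering K = 4 and the
  K* histogram.
- **Length sufficiency** — per recording length, refit the generating K
  and report mean absolute error of rank-aligned rates and transition
  entries; error shrinks with length and is small by 48 h (2880 bins).

The reference wild-type generator uses the reported emission means
(0.02 / 1.18 / 4.07 / 7.49 s/min) and the reported group-average
sleep↔wake transition probabilities; the within-sleep and within-wake
exchange probabilities are not reported and are set to a common small
value (0.05), with diagonals absorbing the remainder. This is an
approximation of a per-fish fitted matrix, chosen once; its stationary
distribution (≈ 0.33 / 0.23 / 0.17 / 0.28) keeps all four states well
visited in 2880-bin surrogates.

## Semantic labeling and architecture

States are labelled by ascending rate: (S2, S1, W1, W2) for K = 4 and
(S2, S1, W) for K = 3, the free-running case in which the high-activity
wake state disappears. For K = 3 the ordering is cross-checked against the
reference rates by nearest match; disagreement is recorded as a warning
rather than an error because the original assignment also used circadian
timing, which cannot be fully automated here. Rate ties within 1e-6 raise
and demand manual labels. Other K get generic labels with a warning.

Architecture summaries: day/night state proportions (normalised per
period); total minutes per label per period; bout statistics where a bout
is a maximal run of one label, truncated at day/night boundaries with each
fragment counted in its own period (this keeps per-period totals
conserved; assigning boundary-spanning bouts to their start period would
not). Absent labels give missing values, not zeros. Posterior time courses
are smoothed with a centred moving average spanning 61 bins (labelled
"60 minutes": the bin plus 30 on each side), shrinking at the edges, which
preserves the per-time unit sum. The conventional-sleep comparison reports
per fish and period the hours decoded as S2 against the hours of
zero-activity bins, with Pearson correlation against the line y = x pooled
over fish (omitted below 3 fish). Activity-conditioned assignment tables
give P(label | activity value) overall and split by period; rows sum to 1.
Cohort parameter averages align states by label and re-normalise averaged
transition rows (entrywise means of stochastic rows are already
stochastic; renormalisation only guards numeric drift).

## Arousal analysis

The assay delivers a stimulus every 5 min during one night; because one
10-h night fits less reliably per fish, states come from a single 4-state
model fitted to all fish concatenated. Fish whose decoded path misses any
state are excluded. Each stimulus falls on a bin boundary and takes the
state of the bin ending there; the response detector asks for any
supra-threshold sample within the 2 s after the stimulus (with 1 Hz
samples labelled by their left edge, the window holds the two samples
starting at the stimulus). Baseline correction applies the same detector
to the first 2 s of the bin starting 120 s before the stimulus,
conditioned on that baseline bin's own state — this estimates the
probability that a fish in a given state moves in an arbitrary 2-s window
without a stimulus — and subtracts it from the raw per-state fraction.
The matched-activity comparison restricts to stimuli whose pre-stimulus
bin has one fixed activity value and splits by label, separating state
effects from activity effects.

## Group statistics

Group differences in occupancies, rates and transition entries use a
two-sided permutation test on the absolute difference of group means:
exact enumeration when the number of group assignments is ≤ 20,000,
otherwise Monte-Carlo with +1 smoothing (so p > 0). The phrase "bootstrap
sampling and a permutation test" is interpreted as: permutation for the
p-value, bootstrap (2000 resamples) only for a percentile CI on the group
difference reported alongside. Bonferroni families scale with the label
set — factor 4 for occupancies/λs and 16 for transition entries of a
4-state model (K and K² in general). Day/night contrasts use the Wilcoxon
signed-rank test (zero differences dropped; exact null to 25 pairs);
between-group state amounts use Welch t-tests (the unequal-variance form,
since nothing guarantees equal group variances); both are
Benjamini–Hochberg corrected across states. Response fractions may be
arcsine-transformed (`asin √f`) before testing.

## Synthetic cohorts

The generator is a time-inhomogeneous hidden Markov chain: one transition
matrix during light bins, another during dark bins (the transition into a
bin uses that bin's matrix), with emission rates constant across the day —
circadian structure in the synthetic data comes entirely from occupancy
changes, matching the homogeneous-model premise that a single HMM captures
day and night. Defaults: reference rates; a day matrix whose stationary
law puts ≈ 72% on W1+W2 and a night matrix putting ≈ 75% on S2+S1, all
self-transitions ≥ 0.82 — package constants chosen for qualitative realism
(day-dominant wake, night-dominant sleep, heavy-tailed pooled activity
with a mode at zero), not fitted values. Per-fish individuality is
log-normal rate jitter (sd 0.1). Zero-inflation weights are optional.

Protocol variants: **sleep deprivation** keeps night 2 lit for its first
6 h (day matrix) and then raises the deep-sleep self-transition by a
phenomenological rebound boost (default 0.05, renormalised) for the final
4 h; **arousal** generates 1 Hz binary night traces whose per-second
activity is Bernoulli(λ/60) — so binned counts are Binomial(60, λ/60) ≈
Poisson(λ) — and injects one active second after each stimulus with a
per-label response probability (defaults 0.1 / 0.3 / 0.6 / 0.8 for
S2/S1/W1/W2). Presets perturb the wild-type matrices to emulate the
direction of each studied manipulation (melatonin loss or treatment,
serotonin loss or agonism, noradrenaline loss or blockade, constant dark);
they are directional emulations, not quantitative fits — no published
effect sizes exist to calibrate them beyond the rates and a few transition
probabilities.

What passing tests on these cohorts do and do not show: they verify the
pipeline's statistical machinery, identifiability at realistic sequence
lengths, and the direction of inferred group differences under known
ground truth. They cannot certify behaviour on real recordings, which have
batch effects, non-Markovian bout structure, fractional activity values
and longer-range homeostatic dynamics the generator deliberately omits.

## Problem sizes

Experiments are scaled for a single CPU: the state-number recovery check
uses 50 sequences × 20 restarts (the original protocol used 100 × 1000);
directional preset checks use 8–12 fish per cohort and 5–10 restarts;
calibration checks use 2000 null replicates. These sizes are stated here
as the package's own defaults for its validation suite.

## Known limitations

- The Markov and Poisson assumptions are modelling choices; real bout
  durations are not geometric and real counts are bounded at 60 (sampling
  clips, fitting ignores the bound, which is harmless at λ ≤ 10).
- 3-state labeling automates only the rate-based part of the original
  qualitative assignment.
- The rebound boost models deprivation phenomenologically; there is no
  latent sleep-pressure process.
- Preset effect sizes are directional constructs; significance thresholds
  reached on synthetic cohorts say nothing about power on real data.
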