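# zfsleep

Hidden-Markov segmentation of larval zebrafish locomotor activity into
sleep and wake sub-states, with the downstream sleep-architecture,
arousability and group-comparison analyses that build on it.

## The problem

Zebrafish sleep is conventionally defined behaviourally: any one-minute
bin with zero locomotor activity counts as sleep. That binary definition
hides structure. When multi-day activity recordings (integer seconds of
movement per minute, 0–60) are modelled with a Poisson hidden Markov model
(HMM), the Bayesian Information Criterion selects **four** hidden states:
two sleep-like states occupied mostly at night — a quiescent deep-sleep
state **S2** (emission mean λ ≈ 0 s/min) and a low-activity light-sleep
state **S1** (λ ≈ 1 s/min) — and two wake states **W1** (λ ≈ 4) and
**W2** (λ ≈ 8) occupied mostly by day. The sub-states behave like light
and deep NREM sleep: arousability orders S2 < S1 < W1, and rebound after
sleep deprivation is S2-dominated. This package implements that entire
analysis as a tested library plus CLI, exercised end-to-end on a synthetic
cohort generator with known ground truth.

## The model

Observations `x_t ∈ {0..60}` (seconds active in minute `t`) are emitted by
a K-state Markov chain with initial distribution π, row-stochastic
transition matrix A, and per-state Poisson means λ_k (optionally
zero-inflated with weight w_k):

    P(x | state k) = w_k·[x=0] + (1−w_k)·Poisson(x; λ_k)

Fitting is multi-restart Baum–Welch EM (scaled forward–backward, numba
kernels); the state count is chosen by minimising
`BIC = p·ln(n) − 2·loglik` with `p = (K−1) + K(K−1) + K` free parameters
(plus K for zero-inflated emissions) over K = 2…6. Decoded paths come from
Viterbi; long-run occupancies from the dominant eigenvector of A; group
contrasts from permutation tests with Bonferroni families (×4 for
occupancies and λs, ×16 for transition entries), Wilcoxon signed-rank and
Welch t-tests with Benjamini–Hochberg correction.

## Worked example

```python
from zfsleep import (generate_cohort, preset, select_states, label_states,
                     label_bins, state_proportions)

cohort, truth = generate_cohort(preset("wt"), n_fish=5, duration_h=48, seed=7)
trace = cohort.traces[0]

sel = select_states([trace], n_restarts=20, seed=1)   # K = 2..6, BIC
print(sel.summary())
res = sel.best
labeling = label_states(res.params)
props = state_proportions(res.decode(trace), labeling,
                          label_bins(trace, truth.schedule))
print(props.round(3))
```

Output (abridged):

```
 n_states       loglik          bic  selected
        2 -6183.248073 12406.323873     False
        3 -5323.564209 10734.749420     False
        4 -5164.719753 10480.784872      True
        5 -5159.579322 10550.159465     False
        6 -5155.488419 10637.564206     False

state   lambda (s/min)        period    day  night
    0          0.0137         S2      0.140  0.512
    1          1.3043         S1      0.108  0.243
    2          3.8392         W1      0.417  0.170
    3          9.5458         W2      0.335  0.075
```

BIC bottoms out at K = 4. The four fitted rates bracket the reference
values (0.02 / 1.18 / 4.07 / 7.49 s/min); labeling is by ascending rate.
The decoded fish spends 51% of the night in deep sleep S2 but only 14% of
the day, while the high-activity wake state W2 shows the opposite pattern
— the circadian sleep/wake architecture the model is built to expose.

The same pipeline is scriptable from the shell:

```bash
zfsleep simulate --preset wt --n-fish 5 --seed 7 --out run/sim
zfsleep fit      --traces run/sim/traces.csv --states 2-6 --out run/fit
zfsleep analyze  --traces run/sim/traces.csv --schedule run/sim/schedule.csv \
                 --fit-dir run/fit --out run/analysis
```

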