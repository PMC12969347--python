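"""Semantic labeling, occupancy, proportions, bouts, smoothing, comparisons."""

import numpy as np
import pandas as pd
import pytest

from zfsleep.architecture import (assignment_by_activity, average_parameters,
                                  bout_durations, compare_conventional_sleep,
                                  label_states, mean_state_probabilities,
                                  occupancy, smoothed_state_probabilities,
                                  state_minutes, state_proportions)
from zfsleep.data import ActivityTrace, label_bins
from zfsleep.hmm import HMMParams, StateSequence

START = pd.Timestamp("2024-01-01 09:00:00")


def _params4(lam, A=None):
    lam = np.asarray(lam, float)
    K = lam.size
    if A is None:
        A = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(A, 0.9)
    return HMMParams(np.full(K, 1 / K), A, lam)


class TestLabelStates:
    def test_reference_rates_any_order(self, rng):
        lam = np.array([0.02, 1.18, 4.07, 7.49])
        perm = rng.permutation(4)
        labeling = label_states(_params4(lam[perm]))
        for idx, rate in enumerate(lam[perm]):
            expected = {0.02: "S2", 1.18: "S1", 4.07: "W1", 7.49: "W2"}[rate]
            assert labeling[idx] == expected

    def test_three_state_labels(self):
        labeling = label_states(_params4([0.03, 1.2, 4.0]))
        assert labeling.label_set == ("S2", "S1", "W")
        assert not labeling.mismatch

    def test_two_state_fallback_warns(self):
        with pytest.warns(UserWarning, match="sleep-like"):
            labeling = label_states(_params4([0.5, 5.0]))
        assert labeling.label_set == ("sleep-like", "wake-like")

    def test_rate_tie_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            label_states(_params4([1.0, 1.0 + 1e-8, 4.0, 7.0]))


class TestOccupancy:
    def test_uniform_rows_give_equal_occupancy(self):
        A = np.full((4, 4), 0.25)
        occ = occupancy(_params4([0.02, 1.18, 4.07, 7.49], A))
        assert np.allclose(occ.to_numpy(), 0.25)

    def test_balance_equations_with_labels(self):
        A = np.array([[0.5, 0.5], [0.25, 0.75]])
        with pytest.warns(UserWarning):
            p = _params4([0.5, 5.0], A)
            occ = occupancy(p, label_states(p))
        assert occ["sleep-like"] == pytest.approx(1 / 3)
        assert occ["wake-like"] == pytest.approx(2 / 3)

    def test_matches_hidden_path_frequencies(self, wt_cohort):
        cohort, truth = wt_cohort
        spec = truth.spec
        from zfsleep.hmm import stationary_distribution

        night_occ = stationary_distribution(spec.night_transitions)
        sched = truth.schedule
        pooled = []
        for tr in cohort.traces:
            night = label_bins(tr, sched) == "night"
            pooled.append(truth.states[tr.fish_id][night])
        freq = np.bincount(np.concatenate(pooled), minlength=4) / sum(p.size for p in pooled)
        # long pooled sample: empirical frequencies near the stationary law
        assert np.allclose(freq, night_occ, atol=0.03)


class TestProportionsAndBouts:
    @pytest.fixture()
    def labeling(self):
        return label_states(_params4([0.02, 1.18, 4.07, 7.49]))

    def test_toy_night_proportions(self, labeling):
        states = np.array([0, 0, 0, 2, 2, 2])  # S2 at night, W1 by day
        periods = np.array(["night"] * 3 + ["day"] * 3, dtype=object)
        props = state_proportions(states, labeling, periods)
        assert props.loc["S2", "night"] == 1.0
        assert props.loc["W1", "day"] == 1.0
        assert np.allclose(props.sum(axis=0), 1.0)

    def test_minutes_conserve_period_length(self, labeling, rng):
        states = rng.integers(0, 4, 300)
        periods = np.array(["day"] * 120 + ["night"] * 180, dtype=object)
        mins = state_minutes(states, labeling, periods)
        assert mins["day"].sum() == 120 and mins["night"].sum() == 180

    def test_bout_means_single_period(self, labeling):
        states = np.array([0, 0, 1, 0])  # S2 bouts of 2 and 1, S1 bout of 1
        periods = np.array(["night"] * 4, dtype=object)
        bouts = bout_durations(states, labeling, periods)
        assert bouts.loc["S2", "night"] == pytest.approx(1.5)
        assert bouts.loc["S1", "night"] == pytest.approx(1.0)
        assert np.isnan(bouts.loc["W1", "night"])  # absent label -> missing

    def test_boundary_truncation(self, labeling):
        states = np.zeros(5, dtype=int)
        periods = np.array(["day"] * 3 + ["night"] * 2, dtype=object)
        bouts = bout_durations(states, labeling, periods)
        assert bouts.loc["S2", "day"] == 3.0
        assert bouts.loc["S2", "night"] == 2.0

    def test_night_sleep_dominates_on_synthetic_truth(self, wt_cohort, labeling):
        cohort, truth = wt_cohort
        night_s, day_s = [], []
        for tr in cohort.traces:
            periods = label_bins(tr, truth.schedule)
            props = state_proportions(truth.states[tr.fish_id], labeling, periods)
            night_s.append(props.loc[["S2", "S1"], "night"].sum())
            day_s.append(props.loc[["S2", "S1"], "day"].sum())
        assert np.mean(night_s) > np.mean(day_s)

    def test_night_bouts_longer_on_synthetic_truth(self, wt_cohort, labeling):
        cohort, truth = wt_cohort
        diffs = []
        for tr in cohort.traces:
            periods = label_bins(tr, truth.schedule)
            bouts = bout_durations(truth.states[tr.fish_id], labeling, periods)
            diffs.append(bouts.loc["S2", "night"] - bouts.loc["S2", "day"])
        assert np.nanmean(diffs) > 0  # stickier night sleep transitions


class TestSmoothing:
    def test_constant_posteriors_unchanged(self):
        post = np.tile([0.25, 0.25, 0.25, 0.25], (200, 1))
        sm = smoothed_state_probabilities(post, window_min=60)
        assert np.allclose(sm.to_numpy(), 0.25)

    def test_rows_sum_to_one(self, rng):
        post = rng.dirichlet(np.ones(4), size=300)
        sm = smoothed_state_probabilities(post, window_min=60)
        assert np.allclose(sm.sum(axis=1), 1.0, atol=1e-9)

    def test_impulse_mass_preserved(self):
        post = np.zeros((301, 2))
        post[:, 1] = 1.0
        post[150, 0], post[150, 1] = 1.0, 0.0
        sm = smoothed_state_probabilities(post, window_min=60)
        # away from edges a moving average redistributes but conserves mass
        assert sm[0].sum() == pytest.approx(1.0, abs=1e-9)
        assert sm[0].max() == pytest.approx(1 / 61, abs=1e-12)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smoothed_state_probabilities(np.ones((30, 2)) * 0.5, window_min=60)

    def test_cohort_mean(self, rng):
        posts = [rng.dirichlet(np.ones(4), size=200) for _ in range(3)]
        labeling = label_states(_params4([0.02, 1.18, 4.07, 7.49]))
        mean = mean_state_probabilities(posts, labeling)
        assert list(mean.columns) == ["S2", "S1", "W1", "W2"]
        assert np.allclose(mean.sum(axis=1), 1.0, atol=1e-9)


class TestConventionalComparison:
    def _seq(self, states, K=4):
        post = np.zeros((len(states), K))
        post[np.arange(len(states)), states] = 1.0
        return StateSequence(np.asarray(states), post)

    def test_perfect_match_lies_on_identity(self, rng):
        labeling = label_states(_params4([0.02, 1.18, 4.07, 7.49]))
        seqs, labels, traces, periods = [], [], [], []
        for i in range(4):
            values = rng.integers(0, 5, 240)
            states = np.where(values == 0, 0, 2)  # S2 exactly on zero bins
            traces.append(ActivityTrace(f"f{i}", START, values))
            seqs.append(self._seq(states))
            labels.append(labeling)
            periods.append(np.array(["day"] * 240, dtype=object))
        df, stats = compare_conventional_sleep(seqs, labels, traces, periods)
        assert np.allclose(df["s2_hours"], df["conventional_hours"])
        assert stats.r == pytest.approx(1.0)
        assert stats.mean_deviation == pytest.approx(0.0)

    def test_single_fish_omits_correlation(self):
        labeling = label_states(_params4([0.02, 1.18, 4.07, 7.49]))
        trace = ActivityTrace("f0", START, [0, 1, 0, 2])
        seq = self._seq([0, 1, 0, 2])
        df, stats = compare_conventional_sleep(
            [seq], [labeling], [trace], [np.array(["day"] * 4, dtype=object)])
        assert stats is None and len(df) == 1


class TestAssignment:
    def test_rows_sum_to_one(self, rng):
        labeling = label_states(_params4([0.02, 1.18, 4.07, 7.49]))
        values = rng.integers(0, 10, 500)
        states = rng.integers(0, 4, 500)
        seq = TestConventionalComparison()._seq(states)
        trace = ActivityTrace("f0", START, values)
        periods = np.array(["day"] * 250 + ["night"] * 250, dtype=object)
        tables = assignment_by_activity([seq], [labeling], [trace], [periods])
        for tab in tables.values():
            assert np.allclose(tab.sum(axis=1), 1.0)

    def test_deterministic_model_gives_unit_rows(self):
        labeling = label_states(_params4([0.02, 1.18, 4.07, 7.49]))
        values = np.array([0, 0, 5, 5, 9])
        states = np.array([0, 0, 1, 1, 3])
        seq = TestConventionalComparison()._seq(states)
        trace = ActivityTrace("f0", START, values)
        periods = np.array(["day"] * 5, dtype=object)
        tab = assignment_by_activity([seq], [labeling], [trace], [periods])["overall"]
        assert np.allclose(tab.max(axis=1), 1.0)


class TestAverageParameters:
    def test_identity_and_mean(self):
        p1 = _params4([0.02, 1.18, 4.07, 7.49])
        p2 = _params4([0.04, 1.30, 4.00, 7.00])
        l1 = label_states(p1)
        lam, A = average_parameters([p1, p1], [l1, l1])
        assert np.allclose(A.to_numpy(), p1.transmat)
        lam2, A2 = average_parameters([p1, p2], [l1, label_states(p2)])
        assert lam2["S2"] == pytest.approx(0.03)
        assert np.allclose(A2.sum(axis=1), 1.0)

    def test_mixed_label_sets_rejected(self):
        p4 = _params4([0.02, 1.18, 4.07, 7.49])
        p3 = _params4([0.02, 1.18, 4.07])
        with pytest.raises(ValueError, match="label set"):
            average_parameters([p4, p3], [label_states(p4), label_states(p3)])
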