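"""Trial extraction, familiarity metric, SVM decoding and burst replay."""

import numpy as np
import pytest

from meareplay import (
    BurstSet,
    SpikeData,
    TrialTensor,
    accuracy_timecourse,
    arm_replay_bias,
    classify_snb_bins,
    detect_snbs,
    extract_trials,
    familiarity_delta,
    make_default_network,
    make_pattern,
    make_test_schedule,
    pattern_response_summary,
    simulate_evoked,
    simulate_spontaneous,
    train_pattern_classifier,
)
from meareplay.stimuli import Frame, StimulusSchedule


def toy_session(n_trials=6, interval_ms=1000.0):
    labels = ["A", "B"] * (n_trials // 2)
    frames = [Frame(k * interval_ms, 100.0, (0,)) for k in range(n_trials)]
    sched = StimulusSchedule(frames, (16, 16), n_trials * interval_ms)
    # electrode 1 fires 2 spikes for A trials, electrode 2 fires 1 spike for B
    sp1, sp2 = [], []
    for k, lbl in enumerate(labels):
        if lbl == "A":
            sp1.extend([k * interval_ms + 30.0, k * interval_ms + 35.0])
        else:
            sp2.append(k * interval_ms + 30.0)
    data = SpikeData(
        {1: np.array(sp1), 2: np.array(sp2)}, n_trials * interval_ms
    )
    return data, sched, labels


class TestExtractTrials:
    def test_no_bursts_keeps_all(self):
        data, sched, labels = toy_session()
        t = extract_trials(data, sched, labels, 200.0, 10.0)
        assert t.n_trials == 6
        assert t.dropped_trials == []

    def test_pre_onset_burst_drops_trial(self):
        """A burst ending 0.5 s before an onset falls in the 1-s exclusion window."""
        data, sched, labels = toy_session()
        bursts = BurstSet(np.array([[300.0, 500.0]]), np.array([10]))  # ends 500 ms before t=1000
        t = extract_trials(data, sched, labels, 200.0, 10.0, bursts, 1.0)
        assert t.n_trials == 5
        assert t.dropped_trials[0]["trial"] == 1

    def test_counts_match_hand_binning(self):
        data, sched, labels = toy_session(2)
        t = extract_trials(data, sched, labels, 200.0, 10.0)
        e1 = list(t.electrode_ids).index(1)
        # A trial: electrode 1 spikes at +30 and +35 -> bin 3 holds both
        assert t.counts[0, e1, 3] == 2
        assert t.counts[0].sum() == 2
        assert t.counts[1].sum() == 1  # B trial, one spike on electrode 2

    def test_all_trials_of_pattern_dropped_errors(self):
        data, sched, labels = toy_session(2)
        bursts = BurstSet(np.array([[100.0, 400.0]]), np.array([5]))  # kills trial 1 (B)
        with pytest.raises(ValueError, match="dropped"):
            extract_trials(data, sched, labels, 200.0, 10.0, bursts, 1.0)


class TestPatternSummary:
    def test_identical_trials_zero_sem(self):
        data, sched, labels = toy_session()
        t = extract_trials(data, sched, labels, 200.0, 10.0)
        s = pattern_response_summary(t)
        assert s["A"]["sem_total"] == 0.0
        assert s["A"]["mean_total"] == pytest.approx(2.0)
        assert s["B"]["mean_total"] == pytest.approx(1.0)

    def test_single_trial_sem_flagged(self):
        counts = np.zeros((2, 3, 4), dtype=int)
        t = TrialTensor(counts, np.array(["A", "B"]), 10.0, 40.0, np.array([1, 2, 3]))
        s = pattern_response_summary(t)
        assert s["A"]["sem_total"] == 0.0
        assert not s["A"]["sem_defined"]

    def test_means_match_hand_computation(self):
        counts = np.zeros((2, 1, 2), dtype=int)
        counts[0] = [[1, 2]]
        counts[1] = [[3, 5]]
        t = TrialTensor(counts, np.array(["A", "A"]), 10.0, 20.0, np.array([1]))
        s = pattern_response_summary(t)
        assert s["A"]["mean_total"] == pytest.approx(5.5)
        np.testing.assert_allclose(s["A"]["psth"], [2.0, 3.5])


class TestFamiliarityDelta:
    def test_symmetry_zero(self):
        assert familiarity_delta(1.0, 1.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "xf,x1,x2,expected", [(2, 1, 1, 0.5), (4, 2, 0, 0.75), (1, 2, 2, -1.0)]
    )
    def test_formula(self, xf, x1, x2, expected):
        assert familiarity_delta(xf, x1, x2) == pytest.approx(expected)

    def test_nonpositive_familiar_errors(self):
        with pytest.raises(ValueError):
            familiarity_delta(0.0, 1.0, 1.0)


def separable_tensor(seed=0, n_trials_per=6, n_electrodes=12, n_bins=5):
    """Three linearly separable classes: each has its own hot electrode block."""
    rng = np.random.default_rng(seed)
    labels, blocks = [], {"A": 0, "B": 4, "C": 8}
    counts = []
    for lbl, start in blocks.items():
        for _ in range(n_trials_per):
            x = rng.poisson(0.2, size=(n_electrodes, n_bins))
            x[start : start + 4] += rng.poisson(6.0, size=(4, n_bins))
            counts.append(x)
            labels.append(lbl)
    return TrialTensor(
        np.array(counts), np.array(labels), 10.0, 50.0, np.arange(1, n_electrodes + 1)
    )


class TestClassifier:
    def test_separable_training_accuracy(self):
        t = separable_tensor()
        clf = train_pattern_classifier(t, mode="pool_all")
        X, y, _ = t.instances()
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_split_determinism(self):
        t = separable_tensor()
        _, h1 = train_pattern_classifier(t, mode="split", seed=3)
        _, h2 = train_pattern_classifier(t, mode="split", seed=3)
        np.testing.assert_array_equal(h1.labels, h2.labels)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_randomized_labels_at_chance(self):
        """Shuffled labels -> held-out accuracy within 3 SE of 1/3."""
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(6):
            t = separable_tensor(seed=rep, n_trials_per=8)
            shuffled = t.labels.copy()
            rng.shuffle(shuffled)
            t2 = TrialTensor(t.counts, shuffled, t.bin_ms, t.window_ms, t.electrode_ids)
            clf, held = train_pattern_classifier(t2, mode="split", seed=rep)
            X, y, _ = held.instances()
            accs.append(np.mean(clf.predict(X) == y))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 3) <= 3 * max(se, 0.03)

    def test_single_class_errors(self):
        t = separable_tensor()
        t_one = TrialTensor(
            t.counts, np.array(["A"] * t.n_trials), t.bin_ms, t.window_ms, t.electrode_ids
        )
        with pytest.raises(ValueError, match="two pattern classes"):
            train_pattern_classifier(t_one)

    def test_electrode_permutation_invariance(self):
        """Consistently permuting electrodes leaves predictions unchanged."""
        t = separable_tensor()
        clf = train_pattern_classifier(t, mode="pool_all")
        perm = np.random.default_rng(0).permutation(t.counts.shape[1])
        tp = TrialTensor(
            t.counts[:, perm, :], t.labels, t.bin_ms, t.window_ms, t.electrode_ids[perm]
        )
        clfp = train_pattern_classifier(tp, mode="pool_all")
        X, _, _ = t.instances()
        Xp, _, _ = tp.instances()
        np.testing.assert_array_equal(clf.predict(X), clfp.predict(Xp))


class TestReplayClassification:
    def setup_pipeline(self, seed, bias: bool):
        net = make_default_network(seed=seed)
        patterns = [make_pattern(n, (16, 16)) for n in ("car", "dog", "human")]
        sched, labels = make_test_schedule(patterns, 10, 2.0, 100.0, seed=seed)
        spk = simulate_evoked(net, sched, seed=seed, with_snbs=False)
        tensor = extract_trials(spk, sched, labels, 200.0, 10.0)
        clf = train_pattern_classifier(tensor, mode="pool_all")
        if bias:
            net = arm_replay_bias(net, patterns[2], strength=0.8)  # human
        rec = simulate_spontaneous(net, 120.0, seed=seed + 1)
        bursts = detect_snbs(rec)
        return classify_snb_bins(clf, rec, bursts, 10.0, trained_pattern="human")

    def test_biased_replay_favors_trained_pattern(self):
        out = self.setup_pipeline(seed=21, bias=True)
        assert out.ratios["human"] > out.ratios["car"]
        assert out.ratios["human"] > out.ratios["dog"]
        assert out.delta > 0

    def test_ratios_sum_to_one(self):
        out = self.setup_pipeline(seed=22, bias=False)
        assert sum(out.ratios.values()) == pytest.approx(1.0)
        assert out.n_snb_bins >= 1

    def test_no_bursts_errors(self):
        t = separable_tensor()
        clf = train_pattern_classifier(t, mode="pool_all")
        data = SpikeData({1: np.array([1.0])}, 1000.0)
        with pytest.raises(ValueError):
            classify_snb_bins(clf, data, BurstSet(np.empty((0, 2)), np.empty(0)), 10.0)


class TestAccuracyTimecourse:
    def test_informative_window_above_chance(self):
        """Evoked responses at ~30 ms: accuracy above chance there, bounded in [0,1]."""
        net = make_default_network(seed=31, n_connections=300,
                                   response_prob_range=(0.8, 0.95))
        patterns = [make_pattern(n, (16, 16)) for n in ("car", "dog", "human")]
        sched, labels = make_test_schedule(patterns, 10, 1.0, 100.0, seed=31)
        spk = simulate_evoked(net, sched, seed=31, with_snbs=False)
        tensor = extract_trials(spk, sched, labels, 200.0, 10.0)
        tc = accuracy_timecourse(tensor, n_replicas=4, seed=0)
        assert np.all((tc["accuracy_mean"] >= 0) & (tc["accuracy_mean"] <= 1))
        # bins covering 20-40 ms hold the ~30 +/- 1 ms evoked response
        informative = tc["accuracy_mean"][2:4].mean()
        late = tc["accuracy_mean"][15:].mean()
        assert informative > tc["chance"] + 0.15
        assert informative > late
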