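"""Confusion/accuracy/ROC layer: brute-force oracles and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractvalid import validation as va


def toy_truth():
    # AB present, AC absent, BC present
    states = np.array([[-1, 1, 0], [1, -1, 1], [0, 1, -1]])
    return va.TernaryTruth(states, ["A", "B", "C"])


def toy_sci():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 5.0
    m[0, 2] = m[2, 0] = 3.0
    m[1, 2] = m[2, 1] = 1.0
    return m


def brute_confusion(values, truth, threshold):
    """Independent oracle: enumerate unordered pairs explicitly."""
    tp = tn = fp = fn = 0
    n = len(truth.region_names)
    for i, j in itertools.combinations(range(n), 2):
        state = truth.states[i, j]
        if state == -1:
            continue
        predicted = values[i, j] > threshold
        if state == 1 and predicted:
            tp += 1
        elif state == 1:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def random_truth_and_matrix(rng, n=22):
    states = rng.choice([-1, 0, 1], size=(n, n))
    states = np.triu(states, 1)
    states = states + states.T
    np.fill_diagonal(states, -1)
    truth = va.TernaryTruth(states, [f"r{i}" for i in range(n)])
    m = rng.random((n, n)) * 100
    m = np.maximum(m, m.T)
    np.fill_diagonal(m, 0)
    return truth, m


class TestConfusion:
    def test_all_indeterminate_counts_nothing(self):
        states = -np.ones((3, 3), dtype=int)
        truth = va.TernaryTruth(states, list("ABC"))
        c = va.confusion(np.zeros((3, 3)), truth, 0.0)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 0)

    def test_threshold_100_has_no_false_positives(self):
        truth, m = random_truth_and_matrix(np.random.default_rng(0), n=8)
        assert va.confusion(m, truth, 100.0).fp == 0

    def test_toy_case_enumerated(self):
        c = va.confusion(toy_sci(), toy_truth(), 2.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 0)

    def test_region_name_mismatch_rejected(self):
        from tractvalid.connectome import SciMatrix
        sci = SciMatrix(toy_sci(), ["A", "B", "X"])
        with pytest.raises(ValueError, match="region names"):
            va.confusion(sci, toy_truth(), 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            truth, m = random_truth_and_matrix(rng)
            t = rng.random() * 100
            c = va.confusion(m, truth, t)
            assert (c.tp, c.tn, c.fp, c.fn) == brute_confusion(m, truth, t)


class TestAccuracyAndRates:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 1, 0, 0), 100.0),
        ((10, 20, 5, 5), 75.0),
        ((0, 0, 1, 1), 0.0),
    ])
    def test_accuracy_arithmetic(self, counts, expected):
        assert va.accuracy(va.ConfusionCounts(*counts)) == pytest.approx(expected)

    def test_accuracy_undefined_for_empty(self):
        with pytest.raises(ValueError, match="undefined"):
            va.accuracy(va.ConfusionCounts(0, 0, 0, 0))

    def test_rates_formulas(self):
        tp_rate, fp_rate, pct_tp, pct_tn = va.rates(va.ConfusionCounts(10, 20, 5, 5))
        assert tp_rate == pytest.approx(10 / 15)
        assert fp_rate == pytest.approx(5 / 25)
        assert pct_tp == pytest.approx(100 * 10 / 15)
        assert pct_tn == pytest.approx(100 * 20 / 25)

    def test_rates_degenerate_cases(self):
        tp_rate, _, pct_tp, _ = va.rates(va.ConfusionCounts(1, 0, 0, 0))
        assert tp_rate == 1.0 and pct_tp == 100.0
        tp_rate, fp_rate, _, _ = va.rates(va.ConfusionCounts(0, 1, 0, 0))
        assert fp_rate == 0.0 and np.isnan(tp_rate)

    @given(tp=st.integers(0, 200), tn=st.integers(0, 200),
           fp=st.integers(0, 200), fn=st.integers(0, 200))
    @settings(derandomize=True, max_examples=200)
    def test_accuracy_identity_with_rates(self, tp, tn, fp, fn):
        """accuracy == 100 * (tp_rate*P + (1-fp_rate)*N) / (P+N)."""
        c = va.ConfusionCounts(tp, tn, fp, fn)
        if c.total == 0:
            return
        tp_rate, fp_rate, _, _ = va.rates(c)
        P, N = tp + fn, fp + tn
        lhs = va.accuracy(c)
        rhs = 100 * ((0 if P == 0 else tp_rate * P)
                     + (0 if N == 0 else (1 - fp_rate) * N)) / (P + N)
        assert lhs == pytest.approx(rhs)


class TestThresholdScan:
    def test_101_rows(self):
        scan = va.threshold_scan(toy_sci(), toy_truth())
        assert len(scan.table) == 101
        assert scan.table["threshold"].tolist() == list(range(101))

    def test_perfectly_separable_reaches_100(self):
        states = np.array([[-1, 1, 0], [1, -1, 0], [0, 0, -1]])
        truth = va.TernaryTruth(states, list("ABC"))
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 50.0
        scan = va.threshold_scan(m, truth)
        assert scan.optimum_accuracy == 100.0

    def test_optimum_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            truth, m = random_truth_and_matrix(rng, n=10)
            scan = va.threshold_scan(m, truth)
            best_acc, best_t = -1.0, None
            for t in range(101):
                tp, tn, fp, fn = brute_confusion(m, truth, float(t))
                acc = 100 * (tp + tn) / (tp + tn + fp + fn)
                if acc > best_acc:
                    best_acc, best_t = acc, t
            assert scan.optimum_threshold == best_t
            assert scan.optimum_accuracy == pytest.approx(best_acc)

    def test_roc_traversal_monotone(self):
        rng = np.random.default_rng(3)
        truth, m = random_truth_and_matrix(rng)
        scan = va.threshold_scan(m, truth)
        tp_rates = scan.table["tp_rate"].to_numpy()
        fp_rates = scan.table["fp_rate"].to_numpy()
        assert np.all(np.diff(tp_rates) <= 1e-12)
        assert np.all(np.diff(fp_rates) <= 1e-12)

    def test_accuracy_invariant_under_permutation(self):
        rng = np.random.default_rng(4)
        truth, m = random_truth_and_matrix(rng, n=8)
        perm = rng.permutation(8)
        truth_p = va.TernaryTruth(truth.states[np.ix_(perm, perm)],
                                  [truth.region_names[i] for i in perm])
        for t in (0.0, 10.0, 50.0):
            a = va.accuracy(va.confusion(m, truth, t))
            b = va.accuracy(va.confusion(m[np.ix_(perm, perm)], truth_p, t))
            assert a == pytest.approx(b)


class TestLengthBinnedRates:
    def lengths_matrix(self, n, rng):
        m = rng.random((n, n)) * 40
        m = np.maximum(m, m.T)
        np.fill_diagonal(m, 0)
        return m

    def test_equal_bins_for_10_pairs(self):
        rng = np.random.default_rng(5)
        truth, m = random_truth_and_matrix(rng, n=5)
        # force all 10 pairs determinate
        states = np.where(truth.states == -1, 0, truth.states)
        np.fill_diagonal(states, -1)
        truth = va.TernaryTruth(states, truth.region_names)
        out = va.length_binned_rates(m, self.lengths_matrix(5, rng), truth, 10.0)
        assert out["n_pairs"].tolist() == [2, 2, 2, 2, 2]

    def test_remainder_rule_12_pairs(self):
        rng = np.random.default_rng(6)
        names = [f"r{i}" for i in range(6)]
        states = np.zeros((6, 6), dtype=int)
        np.fill_diagonal(states, -1)
        # 15 pairs; mark 3 indeterminate -> 12 determinate
        for i, j in ((0, 1), (2, 3), (4, 5)):
            states[i, j] = states[j, i] = -1
        truth = va.TernaryTruth(states, names)
        m = self.lengths_matrix(6, rng)
        out = va.length_binned_rates(m, m, truth, 10.0)
        assert out["n_pairs"].tolist() == [3, 3, 2, 2, 2]

    def test_bins_ordered_by_length(self):
        rng = np.random.default_rng(7)
        truth, m = random_truth_and_matrix(rng, n=7)
        lengths = self.lengths_matrix(7, rng)
        out = va.length_binned_rates(m, lengths, truth, 10.0)
        assert np.all(np.diff(out["length_min"]) >= 0)
        assert np.all(out["length_max"] >= out["length_min"])

    def test_too_few_pairs_rejected(self):
        states = -np.ones((3, 3), dtype=int)
        states[0, 1] = states[1, 0] = 1
        truth = va.TernaryTruth(states, list("ABC"))
        with pytest.raises(ValueError, match="fewer"):
            va.length_binned_rates(np.zeros((3, 3)), np.zeros((3, 3)), truth, 1.0)


class TestTernaryTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            va.TernaryTruth(np.array([[-1, 1], [0, -1]]), ["A", "B"])
        with pytest.raises(ValueError, match="diagonal"):
            va.TernaryTruth(np.zeros((2, 2), dtype=int), ["A", "B"])

    def test_csv_round_trip(self, tmp_path):
        truth = toy_truth()
        truth.to_csv(tmp_path / "t.csv")
        back = va.TernaryTruth.from_csv(tmp_path / "t.csv")
        assert np.array_equal(back.states, truth.states)
        assert back.region_names == truth.region_names
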