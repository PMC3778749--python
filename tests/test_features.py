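import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connectoscan as cs
from connectoscan.features import (
    aggregate_selection,
    devectorize,
    information_gain,
    select_features,
    vectorize,
)


# --- independent brute-force oracle -----------------------------------------
# Naive recursive implementation built on plain Python containers: at each
# node it enumerates every cut position between sorted samples, takes the
# entropy-minimising one (leftmost on ties), and recurses under the MDL rule.

def _H(ys):
    n = len(ys)
    return -sum(c / n * math.log2(c / n) for c in Counter(ys).values())


def _oracle_split(xs, ys, force):
    n = len(ys)
    best = None
    for i in range(1, n):
        if xs[i - 1] == xs[i]:
            continue
        h = (i * _H(ys[:i]) + (n - i) * _H(ys[i:])) / n
        if best is None or h < best[1]:
            best = (i, h)
    if best is None:
        return [ys]
    i, _ = best
    left, right = ys[:i], ys[i:]
    if not force:
        gain = _H(ys) - (len(left) * _H(left) + len(right) * _H(right)) / n
        k, k1, k2 = len(set(ys)), len(set(left)), len(set(right))
        delta = math.log2(3**k - 2) - (k * _H(ys) - k1 * _H(left) - k2 * _H(right))
        if gain <= (math.log2(n - 1) + delta) / n:
            return [ys]
    return _oracle_split(xs[:i], left, False) + _oracle_split(xs[i:], right, False)


def oracle_information_gain(x, y, force_top=True):
    order = sorted(range(len(x)), key=lambda i: x[i])
    xs = [x[i] for i in order]
    ys = [y[i] for i in order]
    bins = _oracle_split(xs, ys, force_top)
    if len(bins) == 1:
        return 0.0
    cond = sum(len(b) * _H(b) for b in bins) / len(ys)
    return max(0.0, _H(ys) - cond)


class TestInformationGain:
    def test_perfect_separation_equals_class_entropy(self):
        assert information_gain([0, 0, 1, 1], ["A", "A", "B", "B"]) == pytest.approx(1.0)

    def test_hand_computed_three_one_split(self):
        # H(class) = 0.8113, conditional = 0.5 -> IG = 0.3113 bits
        ig = information_gain([0, 0, 1, 1], ["A", "A", "A", "B"])
        assert ig == pytest.approx(0.3113, abs=5e-5)

    def test_constant_feature_scores_zero(self):
        assert information_gain([2, 2, 2, 2], ["A", "A", "B", "B"]) == 0.0

    def test_single_class_scores_zero(self):
        assert information_gain([1, 2, 3, 4], ["A", "A", "A", "A"]) == 0.0

    def test_bounded_by_class_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 12)
            x = rng.normal(size=n)
            y = rng.choice(["A", "B"], size=n)
            ig = information_gain(x, y)
            assert 0.0 <= ig <= _H(list(y)) + 1e-12

    @pytest.mark.parametrize("force_top", [True, False])
    def test_matches_brute_force_oracle_on_random_tables(self, force_top):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            # small value grids force plenty of ties
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.choice(["A", "B"], size=n)
            got = information_gain(x, y, force_top_cut=force_top)
            want = oracle_information_gain(list(x), list(y), force_top)
            assert got == pytest.approx(want, abs=1e-12)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_monotone_transform(self, xs, rnd):
        y = [rnd.choice("AB") for _ in xs]
        if len(set(y)) < 2:
            y[0] = "A"; y[-1] = "B"
        x = np.asarray(xs)
        # rank mapping: strictly monotone and exact in floating point
        ranks = np.searchsorted(np.unique(x), x).astype(float)
        a = information_gain(x, y)
        b = information_gain(ranks**3 + 5.0, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = rng.choice(["A", "B"], size=10)
        perm = rng.permutation(10)
        assert information_gain(x, y) == pytest.approx(
            information_gain(x[perm], y[perm]), abs=1e-12
        )


class TestVectorize:
    def test_feature_ordering_lexicographic(self, planted_cohort):
        fm = vectorize(planted_cohort, "fa")
        R = planted_cohort.n_regions
        assert fm.n_features == R * (R - 1) // 2
        assert fm.feature_index[0] == (0, 1)
        assert fm.feature_index[-1] == (R - 2, R - 1)

    def test_round_trip_devectorize(self, planted_cohort):
        fm = vectorize(planted_cohort, "md")
        mat = devectorize(fm.values[0], planted_cohort.n_regions)
        assert np.allclose(mat, planted_cohort.networks[0].md)

    def test_absent_edges_are_zero(self, planted_cohort):
        fm = vectorize(planted_cohort, "cd")
        net = planted_cohort.networks[0]
        iu = np.triu_indices(net.n_regions, k=1)
        absent = net.counts[iu] == 0
        assert np.all(fm.values[0][absent] == 0)


class TestSelection:
    def test_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        y = np.array(["A"] * 5 + ["B"] * 5)
        X[:, 3] = np.where(y == "A", 0.0, 1.0)  # perfectly separating
        fm = cs.FeatureMatrix(X, [(0, i + 1) for i in range(6)], y, "fa")
        sel, gains = select_features(fm)
        assert sel[0] == 3
        assert gains[3] == pytest.approx(1.0)

    def test_top_n_cardinality(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        fm = cs.FeatureMatrix(X, [(0, 1), (0, 2)], np.array([0, 0, 1, 1]), "cd")
        sel, _ = select_features(fm, top_n=1)
        assert len(sel) == 1

    def test_all_zero_gains_select_nothing(self):
        X = np.ones((6, 4))
        fm = cs.FeatureMatrix(X, [(0, 1), (0, 2), (0, 3), (1, 2)],
                              np.array([0, 0, 0, 1, 1, 1]), "cd")
        sel, gains = select_features(fm)
        assert len(sel) == 0
        assert np.all(gains == 0)


class TestAggregateSelection:
    def test_counts_and_strict_highlight_threshold(self):
        index = [(0, 1), (0, 2), (1, 2)]
        rounds = [np.array([0])] * 10 + [np.array([1])] * 0
        rounds = [np.array([0, 1]) if r < 5 else np.array([0]) for r in range(10)]
        rep = aggregate_selection(rounds, index, round_threshold=5)
        assert rep.counts[0] == 10
        assert rep.counts[1] == 5
        # selected in all 10 rounds -> highlighted; exactly 5 -> not (strict >)
        assert (0, 1) in rep.highlighted
        assert (0, 2) not in rep.highlighted

    def test_no_rounds_empty_report(self):
        rep = aggregate_selection([], [(0, 1)], round_threshold=5)
        assert rep.n_rounds == 0
        assert rep.highlighted == []
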