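import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cervimotion.metrics import (
    framewise_std,
    kendall_tau,
    ranking_from_scores,
    rbo,
    regression_metrics,
)


def two_pass_std(column):
    """Independent two-pass sample standard deviation."""
    n = len(column)
    mean = sum(column) / n
    return math.sqrt(sum((x - mean) ** 2 for x in column) / (n - 1))


def brute_force_tau(b, p):
    """All-pairs concordant/discordant count over the tau-a denominator."""
    n = len(b)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        # compare orderings directly (a product of differences can underflow)
        sb = int(b[i] > b[j]) - int(b[i] < b[j])
        sp = int(p[i] > p[j]) - int(p[i] < p[j])
        if sb * sp > 0:
            conc += 1
        elif sb * sp < 0:
            disc += 1
    return (conc - disc) / (n * (n - 1) / 2)


def rbo_oracle(a, b, p):
    """Depth-by-depth overlap summation using explicit set intersections."""
    n = len(a)
    total = 0.0
    for d in range(1, n + 1):
        x_d = len(set(a[:d]) & set(b[:d]))
        total += (x_d / d) * p**d
    x_n = len(set(a) & set(b))
    return (x_n / n) * p**n + (1 - p) / p * total


class TestFramewiseStd:
    def test_identical_runs_give_zero(self):
        m = np.tile(np.linspace(0, 5, 20), (4, 1))
        stds, mean = framewise_std(m)
        np.testing.assert_array_equal(stds, 0.0)
        assert mean == 0.0

    def test_textbook_sample_std(self):
        stds, mean = framewise_std(np.array([[1.0], [2.0], [3.0]]))
        assert stds[0] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(21)
        m = rng.normal(3, 2, (5, 20))
        stds, mean = framewise_std(m)
        oracle = [two_pass_std(m[:, j].tolist()) for j in range(20)]
        np.testing.assert_allclose(stds, oracle, atol=1e-12)
        assert mean == pytest.approx(np.mean(oracle), abs=1e-12)

    def test_translation_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 1, (6, 15))
        base, _ = framewise_std(m)
        shifted, _ = framewise_std(m + 100.0)
        scaled, _ = framewise_std(3.0 * m)
        np.testing.assert_allclose(shifted, base, atol=1e-10)
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-10)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            framewise_std(np.ones((1, 10)))


class TestRegressionMetrics:
    def test_perfect_agreement(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 1.0)

    def test_hand_evaluated_case(self):
        rmse, mae, r2 = regression_metrics([0.0, 2.0], [1.0, 1.0])
        assert (rmse, mae, r2) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(0.0))

    def test_mean_prediction_gives_zero_r2(self):
        b = np.array([10.0, 20.0, 30.0, 40.0])
        _, _, r2 = regression_metrics(b, np.full(4, b.mean()))
        assert r2 == pytest.approx(0.0)

    def test_adversarial_predictions_give_negative_r2(self):
        # b=(0,1,2), p=(2,1,0): SS_res=8, SS_tot=2 -> r2 = 1 - 4 = -3
        _, _, r2 = regression_metrics([0.0, 1.0, 2.0], [2.0, 1.0, 0.0])
        assert r2 == pytest.approx(-3.0)

    def test_constant_benchmark_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([5.0, 5.0], [1.0, 2.0])


class TestKendallTau:
    def test_identical_rankings(self):
        x = list(range(10))
        assert kendall_tau(x, x) == 1.0

    def test_reversed_rankings(self):
        x = list(range(10))
        assert kendall_tau(x, x[::-1]) == -1.0

    def test_two_discordant_pairs_at_n10(self):
        """One adjacent swap flips exactly 1 pair; two swaps -> 41/45."""
        b = list(range(10))
        p = [1, 0, 2, 3, 4, 5, 6, 8, 7, 9]
        assert kendall_tau(b, p) == pytest.approx(41 / 45)
        assert f"{kendall_tau(b, p):.4f}" == "0.9111"

    def test_matches_brute_force_on_random_permutations(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 11))
            b = rng.permutation(n).astype(float)
            p = rng.permutation(n).astype(float)
            assert kendall_tau(b, p) == pytest.approx(brute_force_tau(b, p), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10),
           st.lists(st.floats(-50, 50), min_size=2, max_size=10))
    def test_matches_brute_force_with_arbitrary_ties(self, b, p):
        n = min(len(b), len(p))
        b, p = b[:n], p[:n]
        assert kendall_tau(b, p) == pytest.approx(brute_force_tau(b, p), abs=1e-12)

    def test_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(2)
        b = rng.permutation(9).astype(float)
        p = rng.permutation(9).astype(float)
        assert kendall_tau(b, p) == pytest.approx(stats.kendalltau(b, p).statistic)

    def test_ties_count_as_neither(self):
        # pairs: (1,2) concordant via b and p; pairs involving the b-tie
        # contribute 0; denominator stays n(n-1)/2 = 3
        t = kendall_tau([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 / 3)


class TestRBO:
    def test_identical_rankings_give_one(self):
        r = list("abcdef")
        assert rbo(r, r, 0.9) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_rankings_give_zero(self):
        assert rbo([1, 2, 3], [4, 5, 6], 0.9) == 0.0

    @pytest.mark.parametrize("p", [0.5, 0.9, 0.98])
    def test_matches_depthwise_oracle(self, p):
        a = [0, 1, 2, 3, 4]
        b = [0, 2, 1, 3, 4]  # one adjacent swap
        assert rbo(a, b, p) == pytest.approx(rbo_oracle(a, b, p), abs=1e-12)

    def test_matches_oracle_on_random_rankings(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            a = rng.permutation(n).tolist()
            b = rng.permutation(n).tolist()
            assert rbo(a, b, 0.9) == pytest.approx(rbo_oracle(a, b, 0.9), abs=1e-12)

    def test_monotone_under_adjacent_swaps(self):
        """Each swap moving away from identity never increases RBO."""
        base = list(range(8))
        current = list(base)
        prev = rbo(base, current, 0.9)
        for i in range(7):
            current[i], current[i + 1] = current[i + 1], current[i]
            val = rbo(base, current, 0.9)
            assert val <= prev + 1e-12
            prev = val

    def test_persistence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rbo([1, 2], [1, 2], 1.0)


def test_ranking_from_scores_descending_with_deterministic_ties():
    assert ranking_from_scores([3.0, 9.0, 3.0, 7.0], ids=["a", "b", "c", "d"]) == [
        "b", "d", "a", "c"]
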