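"""Ordinal encoding and permutation entropy against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pevar.ordinal import (
    DimensionError,
    OrdinalDistribution,
    OrdinalPattern,
    SeriesTooShortError,
    _lambda0_from_probs,
    encode_window,
    lambda0,
    ordinal_distribution,
    permutation_entropy,
    permutation_entropy_series,
    sigma_harris,
    sigma_memoryless,
)


def rank_oracle(window):
    """Reference encoder: sort by (value, index), read off ranks."""
    order = sorted(range(len(window)), key=lambda i: (window[i], i))
    ranks = [0] * len(window)
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    return tuple(ranks)


class TestEncodeWindow:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ((1, 2, 3), (1, 2, 3)),
            ((4, 7, 2), (2, 3, 1)),
            ((5, 5, 3), (2, 3, 1)),  # tie: earlier 5 gets the smaller rank
        ],
    )
    def test_examples(self, window, expected):
        assert tuple(encode_window(window)) == expected

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_exhaustive_against_oracle(self, m):
        """Every ordering of m distinct values encodes as the oracle says."""
        for perm in itertools.permutations(range(m)):
            assert tuple(encode_window(perm)) == rank_oracle(perm)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_is_permutation(self, window):
        pattern = encode_window(window)
        assert tuple(pattern) == rank_oracle(window)
        assert sorted(pattern) == list(range(1, len(window) + 1))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            encode_window([1.0, float("nan"), 2.0])
        with pytest.raises(DimensionError):
            encode_window([1.0])


class TestOrdinalDistribution:
    def test_hand_enumerated_counts(self):
        d = ordinal_distribution([1, 3, 2, 4], m=2)
        assert d.window_count == 3
        assert d.counts == {OrdinalPattern((1, 2)): 2, OrdinalPattern((2, 1)): 1}
        assert abs(sum(d.frequencies.values()) - 1.0) < 1e-12

    def test_monotone_series_single_pattern(self):
        d = ordinal_distribution(np.arange(50.0), m=3)
        assert d.counts == {OrdinalPattern((1, 2, 3)): 48}

    def test_series_too_short(self):
        with pytest.raises(SeriesTooShortError):
            ordinal_distribution([1.0, 2.0], m=3)

    def test_overlap_constrains_successors(self, rng):
        """An ascending window (x1 < x2 < x3) constrains its successor
        (x2, x3, x4): since x2 < x3, the next rank vector must rank its
        first entry below its second, leaving only (1,2,3), (1,3,2) and
        (2,3,1).  (In the argsort/inverse labeling used by some packages
        the last of these is written (3,1,2).)"""
        x = rng.standard_normal(3000)
        patterns = [tuple(encode_window(x[i : i + 3])) for i in range(len(x) - 2)]
        allowed = {(1, 2, 3), (1, 3, 2), (2, 3, 1)}
        followers = {
            patterns[i + 1]
            for i in range(len(patterns) - 1)
            if patterns[i] == (1, 2, 3)
        }
        assert followers <= allowed


class TestPermutationEntropy:
    def test_monotone_is_exactly_zero(self):
        est = permutation_entropy_series(np.arange(100.0), m=4)
        assert est.h == 0.0
        assert est.plug_in == 0.0 and est.mm_correction == 0.0

    def test_hand_computed_value(self):
        est = permutation_entropy_series([1, 3, 2, 4], m=2)
        assert est.plug_in == pytest.approx(0.6365141682948128, abs=1e-12)
        assert est.mm_correction == pytest.approx(1.0 / 6.0, abs=1e-15)
        assert est.h == pytest.approx(0.8031808349614795, abs=1e-12)
        assert est.h == est.plug_in + est.mm_correction
        assert est.h_normalized == pytest.approx(est.h / math.log(2), abs=1e-12)

    def test_uniform_limit_normalized_to_one(self):
        counts = {
            OrdinalPattern(p): 10_000 for p in itertools.permutations((1, 2, 3))
        }
        d = OrdinalDistribution(m=3, window_count=60_000, counts=counts)
        est = permutation_entropy(d)
        assert est.h_normalized == pytest.approx(1.0, abs=1e-3)
        assert est.h_normalized >= 1.0  # correction pushes past the plug-in max

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_plug_in_bounded_by_log_visited(self, values):
        d = ordinal_distribution(values, m=3)
        est = permutation_entropy(d)
        assert est.plug_in <= math.log(d.n_visited) + 1e-10
        assert math.log(d.n_visited) <= math.log(math.factorial(3)) + 1e-15

    def test_iid_noise_normalized_near_one(self):
        x = np.random.default_rng(0).uniform(size=10006)
        est = permutation_entropy_series(x, m=4)
        tol = 3 * sigma_harris(4, 10006) / math.log(math.factorial(4))
        assert abs(est.h_normalized - 1.0) < tol


class TestVarianceMachinery:
    def test_lambda0_uniform_is_zero(self):
        d = ordinal_distribution(np.arange(30.0), m=2)  # single pattern, p = 1
        assert lambda0(d) == 0.0
        assert _lambda0_from_probs(np.full(6, 1 / 6)) == pytest.approx(0.0, abs=1e-15)

    def test_lambda0_hand_value(self):
        # oracle: 0.75 ln^2(0.75) + 0.25 ln^2(0.25) - H^2 with H = 0.562335...
        assert _lambda0_from_probs(np.array([0.75, 0.25])) == pytest.approx(
            0.22630293015235908, abs=1e-12
        )

    def test_sigma_memoryless_hand_value_and_scaling(self):
        counts = {OrdinalPattern((1, 2)): 75, OrdinalPattern((2, 1)): 25}
        d100 = OrdinalDistribution(m=2, window_count=100, counts=counts)
        assert sigma_memoryless(d100) == pytest.approx(0.047571, abs=1e-5)
        counts4 = {s: 4 * c for s, c in counts.items()}
        d400 = OrdinalDistribution(m=2, window_count=400, counts=counts4)
        assert sigma_memoryless(d400) == pytest.approx(
            sigma_memoryless(d100) / 2, rel=1e-12
        )

    def test_sigma_memoryless_matches_monte_carlo(self, rng):
        """Leading-order formula vs 500 multinomial draws, skewed probs."""
        p = np.array([0.5, 0.3, 0.15, 0.05])
        n = 10_000
        draws = rng.multinomial(n, p, size=500)
        q = draws / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log(q), 0.0)
        empirical = np.std(-terms.sum(axis=1), ddof=1)
        predicted = math.sqrt(_lambda0_from_probs(p) / n)
        assert empirical == pytest.approx(predicted, rel=0.10)

    def test_sigma_harris_value_and_scaling(self):
        assert sigma_harris(4, 10006) == pytest.approx(3.389e-4, rel=1e-3)
        assert sigma_harris(4, 20012) == pytest.approx(
            sigma_harris(4, 10006) / 2, rel=1e-12
        )


def test_ordinal_pattern_validation():
    with pytest.raises(ValueError):
        OrdinalPattern((1, 3))  # not a permutation of 1..2
    p = OrdinalPattern((2, 1, 3))
    assert p.m == 3
    assert {p: "ok"}[OrdinalPattern((2, 1, 3))] == "ok"  # usable as a key
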