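"""Truncated-wave criterion: worked examples, oracle equivalence, bounds."""

import math

import numpy as np
import pytest

from epgkit import (
    GeneratorProfile,
    apply_truncation_criterion,
    generate_recording,
    generate_truncation_suite,
    mean_with_truncation,
    true_median_estimate,
)
from epgkit.synthetic import brute_force_median_range


class TestTrueMedianEstimate:
    def test_truncated_longest_gives_exact_median(self):
        est = true_median_estimate([2, 4], 9)
        assert est.exact and est.method == "include-exact"
        assert est.estimate == 4

    def test_midpoint_of_possible_range(self):
        est = true_median_estimate([2, 10], 5)
        assert (est.median_low, est.median_high) == (5, 10)
        assert est.estimate == 7.5 and est.method == "midpoint"

    def test_no_untruncated_periods_is_lower_bound(self):
        est = true_median_estimate([], 30)
        assert est.estimate == 30 and est.method == "lower-bound"
        assert math.isinf(est.median_high) and not est.exact

    def test_single_untruncated_period_fallback(self):
        est = true_median_estimate([7], 3)
        assert est.estimate == 7 and est.method == "fallback"
        assert math.isinf(est.median_high)

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            true_median_estimate([2, -1], 5)
        with pytest.raises(ValueError):
            true_median_estimate([2, 3], 0)

    def test_exactness_invariant_to_unknown_true_duration(self):
        # whenever >= 3 periods exist and the truncated one is the longest,
        # the median is invariant to the unknown true duration
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(2, 9))
            un = list(rng.uniform(0.5, 60, size=k))
            t_obs = max(un) * float(rng.uniform(1.0, 3.0))
            est = true_median_estimate(un, t_obs)
            assert est.exact and est.method == "include-exact"
            from epgkit.truncation import _median

            for true_dur in rng.uniform(t_obs, 1e6, size=20):
                assert _median(un + [float(true_dur)]) == pytest.approx(est.estimate, abs=1e-12)

    def test_midpoint_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(0, 7))
            un = list(rng.uniform(0.5, 50, size=k))
            t_obs = float(rng.uniform(0.5, 60))
            est = true_median_estimate(un, t_obs)
            lo, hi = brute_force_median_range(un, t_obs, grid_n=2001)
            assert est.median_low == pytest.approx(lo, abs=1e-9)
            if math.isfinite(hi):
                assert est.median_high == pytest.approx(hi, abs=1e-9)
                if est.method == "midpoint":
                    assert est.estimate == pytest.approx((lo + hi) / 2, abs=1e-9)

    def test_estimate_monotone_in_observed_truncation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            un = list(rng.uniform(0.5, 30, size=int(rng.integers(2, 6))))
            grid = np.sort(rng.uniform(0.5, 60, size=12))
            estimates = [true_median_estimate(un, float(t)).estimate for t in grid]
            assert all(b >= a - 1e-12 for a, b in zip(estimates, estimates[1:]))


class TestMeanPolicies:
    def test_include_is_plain_mean(self):
        value, flag = mean_with_truncation([2, 4], 9, "include")
        assert value == 5.0 and flag == "underestimate"

    def test_longest_include_excludes_middling_truncation(self):
        value, flag = mean_with_truncation([2, 10], 5, "longest-include")
        assert value == 6.0 and flag.startswith("excluded")

    def test_longest_include_keeps_dominant_truncation(self):
        value, flag = mean_with_truncation([2, 10], 50, "longest-include")
        assert value == pytest.approx(62 / 3)
        assert flag.startswith("included")

    def test_exclude_with_no_other_periods_is_missing(self):
        value, flag = mean_with_truncation([], 30, "exclude")
        assert value is None and "missing" in flag

    def test_include_mean_bounds_every_possible_true_mean(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            un = list(rng.uniform(0.5, 40, size=int(rng.integers(1, 6))))
            t_obs = float(rng.uniform(0.5, 50))
            inc, _ = mean_with_truncation(un, t_obs, "include")
            for true_dur in rng.uniform(t_obs, 1e5, size=10):
                true_mean = (sum(un) + float(true_dur)) / (len(un) + 1)
                assert inc <= true_mean + 1e-9


class TestCriterionApplication:
    def test_disabled_returns_none(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 20)])
        assert apply_truncation_criterion(rec, enabled=False) is None

    def test_only_final_waveform_adjusted(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 2), ("E1", 1),
                     ("E2", 10), ("E1", 1), ("E2", 5)])
        adj = apply_truncation_criterion(rec, enabled=True)
        assert adj.label == "E2"
        # prior E2 durations [2, 10], truncated 5 -> midpoint estimate 7.5
        assert adj.median == pytest.approx(7.5)
        assert adj.median_method == "midpoint"
        assert adj.mean == pytest.approx(6.0)  # longest-include excludes 5

    def test_recording_ending_in_np_touches_only_np(self, build):
        seq = [("Np", 5), ("C", 5), ("E1", 1), ("E2", 20), ("Np", 30)]
        adj = apply_truncation_criterion(build(seq), enabled=True)
        assert adj.label == "Np"


class TestTruncationSuite:
    def test_case_methods_match_oracle_ranges(self):
        for case in generate_truncation_suite(seed=5):
            est = true_median_estimate(list(case.untruncated), case.truncated_obs)
            assert est.median_low == pytest.approx(case.oracle_low, abs=1e-9)
            if math.isfinite(case.oracle_high):
                assert est.median_high == pytest.approx(case.oracle_high, abs=1e-9)
                if case.oracle_low == pytest.approx(case.oracle_high, abs=1e-12):
                    assert est.method == "include-exact"
                else:
                    assert est.method == "midpoint"
                    assert est.estimate == pytest.approx(
                        (case.oracle_low + case.oracle_high) / 2, abs=1e-9)
            else:
                assert est.method in ("fallback", "lower-bound")

    def test_suite_deterministic_under_seed(self):
        assert generate_truncation_suite(9) == generate_truncation_suite(9)
        assert generate_truncation_suite(9) != generate_truncation_suite(10)
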