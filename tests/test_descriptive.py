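"""CLSI nonparametric percentiles, reference intervals, bootstrap median
CIs, and the Mann-Whitney U-test, checked against independent brute-force
oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nflref.cohort import Cohort
from nflref.descriptive import (
    DEFAULT_STRATA,
    StratumDefinition,
    bootstrap_median_ci,
    mann_whitney_u,
    nonparametric_percentile,
    reference_interval,
    stratified_reference_intervals,
)
from nflref.simulate import SimulationConfig, generate_cohort


def oracle_percentile(values, p):
    """Independent sort-and-interpolate oracle for the r = p(n+1) rule."""
    xs = sorted(values)
    n = len(xs)
    r = p * (n + 1)
    if r <= 1:
        return xs[0]
    if r >= n:
        return xs[-1]
    k = int(np.floor(r))
    frac = r - k
    return xs[k - 1] + frac * (xs[k] - xs[k - 1])


def oracle_mannwhitney(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    null_us = []
    for idx in combinations(range(nx + ny), nx):
        rx = ranks[list(idx)]
        null_us.append(rx.sum() - nx * (nx + 1) / 2)
    null_us = np.array(null_us)
    mean_u = nx * ny / 2
    p = np.mean(np.abs(null_us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)
    return u_obs, min(1.0, p)


class TestNonparametricPercentile:
    def test_middle_order_statistic(self):
        assert nonparametric_percentile([1, 2, 3, 4, 5], 0.5) == 3

    def test_rank_interpolation_low_tail(self):
        # n=40, p=0.025: rank 1.025, interpolate between x(1) and x(2)
        assert nonparametric_percentile(range(1, 41), 0.025) == pytest.approx(1.025)

    def test_rank_interpolation_high_tail_symmetric(self):
        assert nonparametric_percentile(range(1, 41), 0.975) == pytest.approx(39.975)

    def test_clamps_to_extremes_for_small_n(self):
        assert nonparametric_percentile([3, 7, 9], 0.01) == 3
        assert nonparametric_percentile([3, 7, 9], 0.99) == 9

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 60)
            values = rng.normal(size=n) * 10
            p = rng.uniform(0.01, 0.99)
            assert nonparametric_percentile(values, p) == pytest.approx(
                oracle_percentile(values, p), rel=1e-12, abs=1e-12
            )

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50),
        st.floats(0.01, 0.99),
    )
    def test_oracle_property(self, values, p):
        assert nonparametric_percentile(values, p) == pytest.approx(
            oracle_percentile(values, p), rel=1e-9, abs=1e-9
        )

    def test_monotone_in_p(self, rng):
        values = rng.exponential(5, size=37)
        ps = np.linspace(0.01, 0.99, 25)
        qs = [nonparametric_percentile(values, p) for p in ps]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_rejects_empty_and_bad_p(self):
        with pytest.raises(ValueError):
            nonparametric_percentile([], 0.5)
        with pytest.raises(ValueError):
            nonparametric_percentile([1.0], 1.0)


class TestReferenceInterval:
    def test_degenerate_constant_sample(self):
        ri = reference_interval([5.0] * 200, "const")
        assert ri.lower == ri.upper == 5.0
        assert ri.meets_clsi_min_n

    def test_small_stratum_flagged_not_refused(self, rng):
        ri = reference_interval(rng.exponential(5, 57), "20-29")
        assert ri.n == 57 and not ri.meets_clsi_min_n

    def test_permutation_invariant(self, rng):
        values = rng.exponential(5, 101)
        a = reference_interval(values, "x")
        b = reference_interval(rng.permutation(values), "x")
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_coverage_on_large_sample(self):
        # interval from 10k pooled draws should contain ~95% of fresh draws
        cfg = SimulationConfig(
            decade_counts={k: v * 45 for k, v in {20: 57, 30: 58, 40: 59, 50: 37, 60: 12}.items()},
            seed=8,
        )
        coh = generate_cohort(cfg)
        ri = reference_interval(coh.data["snfl_pg_ml"], "all")
        fresh = generate_cohort(cfg.model_copy(update={"seed": 9}))
        y = fresh.data["snfl_pg_ml"]
        frac = ((y >= ri.lower) & (y <= ri.upper)).mean()
        assert frac == pytest.approx(0.95, abs=0.01)


class TestStratified:
    def test_merged_clsi_strata_counts(self):
        cfg = SimulationConfig(seed=4)
        coh = generate_cohort(cfg)
        merged = [
            StratumDefinition("20-39", 20, 40),
            StratumDefinition("40-69", 40, 70),
        ]
        intervals, medians = stratified_reference_intervals(coh, merged)
        assert [ri.n for ri in intervals] == [115, 108]
        assert intervals[0].meets_clsi_min_n is False  # 115 < 120
        assert [m.n for m in medians] == [115, 108]

    def test_medians_nondecreasing_when_mu_rises(self, large_cohort):
        _, coh = large_cohort
        _, medians = stratified_reference_intervals(coh, DEFAULT_STRATA)
        meds = [m.median for m in medians]
        assert all(a <= b for a, b in zip(meds, meds[1:]))

    def test_overlapping_strata_rejected(self, cohort223):
        with pytest.raises(ValueError, match="overlap"):
            stratified_reference_intervals(
                cohort223,
                [StratumDefinition("a", 20, 45), StratumDefinition("b", 40, 70)],
            )

    def test_empty_stratum_omitted_with_warning(self, cohort223, caplog):
        strata = list(DEFAULT_STRATA) + [StratumDefinition("90-99", 90, 100)]
        with caplog.at_level("WARNING"):
            intervals, _ = stratified_reference_intervals(cohort223, strata)
        assert len(intervals) == 5
        assert any("empty" in r.message for r in caplog.records)

    def test_subjects_outside_strata_logged(self, caplog):
        cfg = SimulationConfig(seed=4)
        coh = generate_cohort(cfg)
        with caplog.at_level("WARNING"):
            stratified_reference_intervals(coh, [StratumDefinition("20-29", 20, 30)])
        assert any("outside all strata" in r.message for r in caplog.records)


class TestBootstrapMedian:
    def test_constant_data_degenerate_ci(self):
        s = bootstrap_median_ci([4.2] * 50, seed=1)
        assert s.ci_low == s.median == s.ci_high == 4.2

    def test_seeded_determinism(self, rng):
        values = rng.exponential(5, 80)
        a = bootstrap_median_ci(values, seed=7)
        b = bootstrap_median_ci(values, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_median(self, rng):
        values = rng.exponential(5, 80)
        s = bootstrap_median_ci(values, seed=7)
        assert s.ci_low <= s.median <= s.ci_high

    def test_coverage_of_true_median(self, rng):
        # ~95% of replicated CIs should contain the true median of a known
        # distribution (Exp(1): median ln 2); 300 replicates keeps the check
        # fast while the binomial SE (~1.3%) stays inside the tolerance
        true_med = np.log(2)
        hits = 0
        reps = 300
        for i in range(reps):
            s = bootstrap_median_ci(rng.exponential(1, 150), reps=500, seed=i)
            hits += s.ci_low <= true_med <= s.ci_high
        assert hits / reps == pytest.approx(0.95, abs=0.04)


class TestMannWhitney:
    def test_tiny_exact_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res["U"] == 0
        assert res["method"] == "exact"
        assert res["p_two_sided"] == pytest.approx(2 / 6, rel=1e-9)

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.5, 3.1, 7.0] * 5, [1.0, 2.5, 3.1, 7.0] * 5)
        assert res["p_two_sided"] == pytest.approx(1.0, abs=0.05)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(1.0, size=5)
            res = mann_whitney_u(x, y)
            u_oracle, p_oracle = oracle_mannwhitney(x, y)
            assert res["method"] == "exact"
            assert res["U"] == pytest.approx(u_oracle)
            assert res["p_two_sided"] == pytest.approx(p_oracle, abs=1e-9)

    def test_normal_approx_close_to_exact_at_small_n(self, rng):
        # the asymptotic path (forced by a tie) stays within 0.05 of the
        # exact enumeration for n=5 per group
        for _ in range(10):
            x = rng.normal(size=5).round(1)
            y = rng.normal(0.5, size=5).round(1)
            _, p_exact = oracle_mannwhitney(x, y)
            res = mann_whitney_u(x, y)
            assert abs(res["p_two_sided"] - p_exact) < 0.05

    def test_u_complement_identity(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=9)
        u_x = mann_whitney_u(x, y)["U"]
        u_y = mann_whitney_u(y, x)["U"]
        assert u_x + u_y == pytest.approx(12 * 9)

    def test_large_samples_use_normal_approx(self, rng):
        res = mann_whitney_u(rng.normal(size=50), rng.normal(size=60))
        assert res["method"] == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def test_cohort_sex_difference_detected(large_cohort):
    # generator males are ~1 pg/ml above females: U-test should see it at n=4000
    _, coh = large_cohort
    males = coh.data.loc[coh.data["sex"] == "M", "snfl_pg_ml"]
    females = coh.data.loc[coh.data["sex"] == "F", "snfl_pg_ml"]
    res = mann_whitney_u(males, females)
    assert res["p_two_sided"] < 0.01
    assert males.median() > females.median()
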