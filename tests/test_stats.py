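"""Trial statistics against independent brute-force and simulation oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from telecost.stats import (
    PowerSpec,
    fisher_exact,
    fisher_exact_2xk,
    format_p,
    mann_whitney,
    sample_size_two_sample_t,
    two_sample_t_power,
)


# ---------------------------------------------------------------- oracles
def exact_mw_p(x, y):
    """Two-sided Mann-Whitney p by enumerating every group assignment of the
    pooled (tie-free) values: p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        group = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for a in group for b in rest if a > b))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def exact_fisher_p(table):
    """Two-sided Fisher p by hypergeometric enumeration (point-probability rule)."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    dist = sps.hypergeom(total, row1, col1)
    p_obs = dist.pmf(a)
    support = range(max(0, row1 + col1 - total), min(row1, col1) + 1)
    return min(1.0, sum(dist.pmf(k) for k in support if dist.pmf(k) <= p_obs * (1 + 1e-7)))


# ----------------------------------------------------------- Mann-Whitney
class TestMannWhitney:
    def test_tiny_sample_against_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)
        assert res.p_value == pytest.approx(exact_mw_p(x, y))

    def test_identical_samples_no_separation(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        res = mann_whitney(x, list(x))
        assert res.p_value >= 0.99

    def test_u_statistic_within_range(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=11)
        res = mann_whitney(x, y)
        assert 0 <= res.statistic <= 8 * 11

    def test_large_shifted_samples_use_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, size=200)
        y = rng.normal(10.0, 1.0, size=200)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        assert res.p_value < 0.001

    def test_ties_fall_back_to_corrected_approximation(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.5, 1.0, size=7)
        p_raw = mann_whitney(x, y).p_value
        p_exp = mann_whitney(np.exp(x), np.exp(y)).p_value
        assert p_raw == pytest.approx(p_exp)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_exact_and_asymptotic_agree_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 16, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(0.3, 1.0, size=n2)
        exact = mann_whitney(x, y)
        assert exact.method == "exact"
        approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(exact.p_value - approx.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ----------------------------------------------------------- Fisher exact
class TestFisherExact:
    def test_absence_table(self):
        """1/20 absent (telemedicine) vs 3/19 (control) is far from significant."""
        res = fisher_exact([[1, 19], [3, 16]])
        assert round(res.p_value, 2) == 0.34
        assert format_p(res.p_value) == ".34"

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_enumeration(self):
        # margins 3/3/3/3: only extreme tables have pmf <= pmf(3) = 1/20 each
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(0.10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact(table).p_value == pytest.approx(
            exact_fisher_p(table), rel=1e-6
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 10), b=st.integers(1, 10),
        c=st.integers(1, 10), d=st.integers(0, 10),
    )
    def test_invariant_to_transpose_and_row_swap(self, a, b, c, d):
        p = fisher_exact([[a, b], [c, d]]).p_value
        assert fisher_exact([[c, d], [a, b]]).p_value == pytest.approx(p)
        assert fisher_exact([[a, c], [b, d]]).p_value == pytest.approx(p)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])

    def test_2xk_reduces_to_2x2(self):
        table = [[1, 19], [3, 16]]
        assert fisher_exact_2xk(table).p_value == pytest.approx(
            fisher_exact(table).p_value, rel=1e-9
        )

    def test_2x3_demographic_table(self):
        # age-band counts of the motivating trial; clearly non-significant
        res = fisher_exact_2xk([[7, 17, 2], [5, 15, 6]])
        assert 0.2 < res.p_value < 0.6


# ------------------------------------------------------------ sample size
class TestSampleSize:
    def test_design_effect_size_gives_nineteen_per_arm(self):
        assert sample_size_two_sample_t(PowerSpec(effect_size=1.095)) == 19

    def test_agrees_with_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower

        n_float = TTestIndPower().solve_power(
            effect_size=1.095, power=0.90, alpha=0.05, alternative="two-sided"
        )
        assert sample_size_two_sample_t(PowerSpec(effect_size=1.095)) == math.ceil(n_float)

    def test_monte_carlo_power_brackets_the_answer(self):
        """Simulated power of the two-sample t test crosses 90% between
        n=18 and n=19 at d=1.095 (100k replicates, fixed seed)."""
        rng = np.random.default_rng(42)
        reps = 100_000

        def simulated_power(n):
            x = rng.standard_normal((reps, n)) + 1.095
            y = rng.standard_normal((reps, n))
            t = sps.ttest_ind(x, y, axis=1)
            return np.mean(t.pvalue <= 0.05)

        assert simulated_power(19) >= 0.90
        assert simulated_power(18) < 0.90

    @pytest.mark.parametrize("d_small, d_large", [(1.095, 2.19), (0.5, 0.8)])
    def test_non_increasing_in_effect_size(self, d_small, d_large):
        n_small = sample_size_two_sample_t(PowerSpec(effect_size=d_large))
        n_large = sample_size_two_sample_t(PowerSpec(effect_size=d_small))
        assert n_small <= n_large

    def test_monotone_in_alpha_and_power(self):
        base = PowerSpec(effect_size=0.8)
        assert sample_size_two_sample_t(
            PowerSpec(effect_size=0.8, alpha=0.01)
        ) >= sample_size_two_sample_t(base)
        assert sample_size_two_sample_t(
            PowerSpec(effect_size=0.8, power=0.95)
        ) >= sample_size_two_sample_t(base)

    def test_power_at_returned_n_meets_target(self):
        spec = PowerSpec(effect_size=1.095)
        n = sample_size_two_sample_t(spec)
        assert two_sample_t_power(n, spec) >= 0.90
        assert two_sample_t_power(n - 1, spec) < 0.90

    def test_invalid_effect_size_rejected(self):
        with pytest.raises(Exception):
            PowerSpec(effect_size=0.0)


@pytest.mark.parametrize(
    "p, text", [(0.34, ".34"), (0.0005, "<.001"), (0.999, ".99"), (0.02, ".02")]
)
def test_p_value_formatting(p, text):
    assert format_p(p) == text
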