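"""Nonparametric statistics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirpair.errors import StatisticsError, ValidationError
from mirpair.stats import (
    bh_adjust,
    chi_square,
    format_p,
    mann_whitney,
    shapiro_gate,
    spearman_with_ci,
    summarize,
)


def exact_mw_p_bruteforce(x, y):
    """Two-sided Mann-Whitney p by full enumeration of all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(first, second):
        return sum((a > b) + 0.5 * (a == b) for a in first for b in second)

    u_obs = u_stat(x, y)
    m = min(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        chosen = set(idx)
        first = [pooled[i] for i in idx]
        second = [pooled[i] for i in range(n1 + n2) if i not in chosen]
        u = u_stat(first, second)
        # as or more extreme in either direction
        if min(u, n1 * n2 - u) <= m + 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.p == pytest.approx(exact_mw_p_bruteforce(x, y), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0] * 3
        res = mann_whitney(x, x)
        assert res.p > 0.95  # ties force the approximation; p ~ 1

    def test_symmetry_and_u_complement(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=9)
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.u + b.u == pytest.approx(len(x) * len(y))

    def test_ties_switch_to_approximation(self):
        res = mann_whitney([1, 1, 2], [2, 3, 3])
        assert res.method == "normal-approximation"

    def test_tiny_sample_rejected(self):
        with pytest.raises(StatisticsError):
            mann_whitney([1.0], [2.0, 3.0])


class TestSummarize:
    def test_five_point_example(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.formatted == "3.00 (2.00; 4.00)"

    def test_single_value(self):
        assert summarize([7]).formatted == "7.00 (7.00; 7.00)"

    def test_matches_sorted_interpolation_oracle(self, rng):
        """Linear-interpolation quantiles against a direct implementation."""
        for _ in range(20):
            v = np.sort(rng.normal(size=rng.integers(2, 30)))

            def q(p):
                h = (len(v) - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, len(v) - 1)
                return v[lo] + (h - lo) * (v[hi] - v[lo])

            s = summarize(v)
            assert s.q1 == pytest.approx(q(0.25), abs=1e-9)
            assert s.median == pytest.approx(q(0.5), abs=1e-9)
            assert s.q3 == pytest.approx(q(0.75), abs=1e-9)


class TestSpearman:
    def test_n_below_four_rejected(self):
        with pytest.raises(StatisticsError):
            spearman_with_ci([1, 2, 3], [1, 2, 3])

    def test_perfect_monotone_is_degenerate(self):
        r = spearman_with_ci([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == 1.0
        assert r.degenerate
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_constant_input_flagged(self):
        with pytest.raises(StatisticsError):
            spearman_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_rho_matches_rank_formula(self):
        x, y = [1, 2, 3, 4], [3, 1, 2, 4]
        r = spearman_with_ci(x, y)
        d = np.array(x) - np.array(y)  # both already ranks
        n = 4
        assert r.rho == pytest.approx(1 - 6 * (d**2).sum() / (n * (n**2 - 1)), abs=1e-9)

    def test_fisher_z_interval_formula(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        r = spearman_with_ci(x, y)
        half = sps.norm.ppf(0.975) / np.sqrt(25 - 3)
        assert r.ci_low == pytest.approx(np.tanh(np.arctanh(r.rho) - half), abs=1e-12)
        assert r.ci_high == pytest.approx(np.tanh(np.arctanh(r.rho) + half), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        a = spearman_with_ci(x, y)
        b = spearman_with_ci(np.exp(x), y**3)  # strictly monotone maps
        assert a.rho == pytest.approx(b.rho, abs=1e-12)


class TestChiSquare:
    def test_perfect_association(self):
        stat, p, dof = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_identical_rows_independent(self):
        stat, p, _ = chi_square([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_matches_textbook_formula(self, rng):
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, 2)).astype(float)
            stat, _, _ = chi_square(table)
            total = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / total
            oracle = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(oracle, abs=1e-9)

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 30, size=(3, 3)).astype(float)
        s1, _, _ = chi_square(t)
        s2, _, _ = chi_square(t[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [1, 2]])


def bh_bruteforce(p):
    """Step-up BH by its definition: sort, scale by m/rank, cummin from top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_definition_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_output_dominates_input_and_capped(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])


class TestShapiroGate:
    def test_skewed_data_flagged_non_normal(self, rng):
        hits = sum(
            not shapiro_gate(np.exp(rng.normal(size=200))).normal for _ in range(50)
        )
        assert hits >= 48  # lognormal at n=200: essentially always detected

    def test_gaussian_rejection_near_alpha(self, rng):
        rejections = sum(
            not shapiro_gate(rng.normal(size=20)).normal for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.09

    def test_constant_vector_degenerate_not_crash(self):
        v = shapiro_gate([3.0, 3.0, 3.0, 3.0])
        assert v.degenerate and not v.normal

    def test_too_small_sample_rejected(self):
        with pytest.raises(StatisticsError):
            shapiro_gate([1.0, 2.0])


class TestFormatP:
    @pytest.mark.parametrize(
        "p,expected", [(0.0004, "<0.001"), (0.001, "0.001"), (0.0374, "0.0374")]
    )
    def test_display_convention(self, p, expected):
        assert format_p(p) == expected
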