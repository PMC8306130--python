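"""Unit and property tests for the statistical core.

Brute-force enumeration oracles (exact label permutations for Mann–Whitney,
exact-fraction hypergeometric sums for Fisher) are defined here and kept
independent of the implementation under test.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnas_imprint import (
    dagostino_pearson,
    derive_normal_range,
    fisher_exact,
    mann_whitney,
)

# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def mw_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings.

    Counts the fraction of equally likely group labelings whose
    min(U, n1*n2 - U) is at most the observed one. Assumes tie-free data.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(frozenset(range(n1)))
    m_obs = min(u_obs, n1 * (len(pooled) - n1) - u_obs)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_of(frozenset(idx))
        if min(u, n1 * (len(pooled) - n1) - u) <= m_obs:
            hits += 1
        total += 1
    return Fraction(hits, total)


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return Fraction(
            math.comb(row1, k) * math.comb(n - row1, col1 - k),
            math.comb(n, col1),
        )

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs)


# ---------------------------------------------------------------------------
# D'Agostino-Pearson
# ---------------------------------------------------------------------------

class TestDagostinoPearson:
    def test_matches_independent_oracle_on_fixed_vector(self):
        """K2 and p agree to 1e-6 with an independently coded implementation
        of the same transformed-moment formulas (scipy.stats.normaltest)."""
        from scipy.stats import normaltest

        vec = np.array([
            42.1, 39.8, 44.3, 40.2, 37.5, 43.9, 41.0, 38.7, 45.2, 40.8,
            39.1, 42.7, 41.5, 36.9, 44.8, 40.0, 38.2, 43.1, 41.9, 39.5,
        ])
        ours = dagostino_pearson(vec)
        ref = normaltest(vec)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-6)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_samples(self, seed):
        from scipy.stats import normaltest

        rng = np.random.default_rng(seed)
        for n in (8, 19, 63, 200):
            x = rng.lognormal(size=n)
            ours = dagostino_pearson(x)
            ref = normaltest(x)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            dagostino_pearson(np.arange(7))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson(np.full(20, 3.0))

    def test_type_i_error_near_alpha(self, rng):
        """Null rejection rate at alpha=0.05 is close to nominal (quick
        check at n=19; the full 10,000-replicate calibration runs in the
        acceptance suite)."""
        from gnas_imprint.stats import _null_rejection_rate

        rate = _null_rejection_rate(n=19, alpha=0.05, n_reps=2000, rng=rng)
        assert 0.02 <= rate <= 0.08


# ---------------------------------------------------------------------------
# reference ranges
# ---------------------------------------------------------------------------

class TestDeriveNormalRange:
    def test_gaussian_reference_gives_mean_pm_ksd(self, rng):
        x = rng.normal(42.4, 5.7, size=500)
        r = derive_normal_range(x, k_sd=2.0, unit="percent")
        assert not r.fallback
        assert r.lower == pytest.approx(x.mean() - 2 * x.std(ddof=1))
        assert r.upper == pytest.approx(x.mean() + 2 * x.std(ddof=1))
        # recovery of the generating bounds 31.0 / 53.8 within sampling error
        assert r.lower == pytest.approx(31.0, abs=1.5)
        assert r.upper == pytest.approx(53.8, abs=1.5)

    def test_k_sd_one_is_upper_mean_plus_sd(self, rng):
        x = rng.normal(293.0, 224.0, size=300)
        r = derive_normal_range(x, k_sd=1.0)
        assert r.upper == pytest.approx(x.mean() + x.std(ddof=1))

    def test_skewed_reference_falls_back_to_percentiles(self, rng):
        x = rng.lognormal(mean=0.0, sigma=1.0, size=500)
        r = derive_normal_range(x, k_sd=2.0)
        assert r.fallback
        assert r.lower == pytest.approx(np.percentile(x, 2.5))
        assert r.upper == pytest.approx(np.percentile(x, 97.5))

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            derive_normal_range([1.0, 2.0, 3.0], k_sd=2.0)

    def test_two_sd_coverage_quick(self, rng):
        """mean ± 2SD covers about 95.45% of a large Gaussian reference."""
        x = rng.normal(size=20_000)
        r = derive_normal_range(x, k_sd=2.0)
        coverage = np.mean((x >= r.lower) & (x <= r.upper))
        assert coverage == pytest.approx(0.9545, abs=0.01)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings

    def test_identical_groups_p_one(self):
        res = mann_whitney([1.0, 2.5, 7.0], [7.0, 1.0, 2.5])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 4), (2, 6)])
    def test_exact_p_equals_enumeration(self, n1, n2, rng):
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
            x, y = pooled[:n1], pooled[n1:]
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                float(mw_enumeration_p(x, y)), abs=1e-12
            )

    def test_label_swap_symmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=14)
        assert mann_whitney(x, y).p_value == pytest.approx(
            mann_whitney(y, x).p_value
        )

    def test_large_sample_matches_tie_corrected_normal_approximation(self, rng):
        from scipy.stats import mannwhitneyu

        x = np.round(rng.normal(size=30), 1)  # induce ties
        y = np.round(rng.normal(0.5, 1.0, size=25), 1)
        res = mann_whitney(x, y)
        assert res.method == "approximate"
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_worked_example(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_extreme_table(self):
        res = fisher_exact([[0, 4], [4, 0]])
        assert res.p_value == pytest.approx(2 / 70, abs=1e-12)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]]).p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fisher_exact([[-1, 2], [3, 4]])

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12),
            st.integers(0, 12), st.integers(0, 12),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_exact_fraction_enumeration(self, counts):
        a, b, c, d = counts
        ours = fisher_exact([[a, b], [c, d]]).p_value
        oracle = float(fisher_enumeration_p(a, b, c, d))
        assert ours == pytest.approx(oracle, abs=1e-9)

    @given(
        st.tuples(
            st.integers(0, 10), st.integers(0, 10),
            st.integers(0, 10), st.integers(0, 10),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_transpose_invariance(self, counts):
        a, b, c, d = counts
        p1 = fisher_exact([[a, b], [c, d]]).p_value
        p2 = fisher_exact([[a, c], [b, d]]).p_value
        assert p1 == pytest.approx(p2, abs=1e-9)
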