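"""Nonparametric statistics: exact-test oracles, effect sizes, power."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from mdephys import stats as st
from mdephys.errors import DomainError


def enumerate_mw_p(x, y):
    """Independent oracle: two-sided Mann-Whitney p by brute-force
    enumeration of all rank assignments (tie-free samples only)."""
    z = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(z)) + 1
    n1 = len(x)
    u_obs_1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u_obs_1, n1 * len(y) - u_obs_1)
    us = []
    for idx in combinations(range(len(z)), n1):
        r = sum(sorted(range(1, len(z) + 1))[i] for i in idx)
        u1 = r - n1 * (n1 + 1) / 2
        us.append(min(u1, n1 * len(y) - u1))
    us = np.array(us)
    return float(np.mean(us <= u_obs + 1e-9))


class TestMannWhitney:
    def test_tiny_separated_sample(self):
        u, p = st.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_are_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = st.mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_large_sample_normal_approximation(self):
        # U=281 with n=(32,34) corresponds to p about 6e-4
        z = st.mann_whitney_z(281, 32, 34)
        p = 2 * sps.norm.sf(abs(z))
        assert abs(p - 0.0006) < 2e-4

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u, p = st.mann_whitney_u(x, y)
            assert p == pytest.approx(enumerate_mw_p(x, y), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        # agreement between the exact and approximate branches on the
        # boundary of the exact regime
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            _, p_exact = st.mann_whitney_u(x, y)
            u, _ = st.mann_whitney_u(x, y)
            mu = 49 / 2
            var = 7 * 7 * 15 / 12
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            p_approx = 2 * sps.norm.sf(z)
            worst = max(worst, abs(p_exact - min(1.0, p_approx)))
        assert worst < 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            st.mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_negative_differences(self):
        # ten uniformly negative changes: W = -(1+...+10) = -55, p ~ 0.002
        pre = np.arange(1.0, 11.0)
        w, p = st.wilcoxon_signed_rank(pre, pre - 1.0)
        assert w == -55.0
        assert p == pytest.approx(2 / 1024)

    def test_seventeen_negative_one_small_positive(self):
        # 18 pairs with one smallest-rank reversal: W = -171 + 2 = -169
        pre = np.arange(1.0, 19.0)
        post = pre - 1.0
        post[0] = pre[0] + 0.05
        w, p = st.wilcoxon_signed_rank(pre, post)
        assert w == -169.0
        assert p < 0.001

    def test_antisymmetric_differences_cancel(self):
        pre = np.zeros(6)
        post = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w, p = st.wilcoxon_signed_rank(pre, post)
        assert w == 0.0
        assert p > 0.9

    def test_all_zero_differences_degenerate(self):
        w, p = st.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert (w, p) == (0.0, 1.0)

    @pytest.mark.parametrize("n", [5, 9, 12])
    def test_extreme_case_magnitude(self, n):
        pre = np.arange(1.0, n + 1)
        w, _ = st.wilcoxon_signed_rank(pre, pre + 1.0)
        assert w == n * (n + 1) / 2

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.normal(size=int(rng.integers(5, 14)))
            _, p = st.wilcoxon_signed_rank(np.zeros_like(d), d)
            ref = sps.wilcoxon(d, mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)


class TestMedianCI:
    def test_order_statistic_bounds(self):
        m = st.median_with_ci(np.arange(1.0, 101.0))
        assert m.median == 50.5
        # smallest symmetric order-statistic pair with >= 95% coverage
        assert (m.lo, m.hi) == (40.0, 61.0)
        assert not m.undercovered

    def test_constant_sample_collapses(self):
        m = st.median_with_ci([5.0] * 20)
        assert (m.median, m.lo, m.hi) == (5.0, 5.0, 5.0)

    def test_small_sample_undercovered(self):
        m = st.median_with_ci([1.0, 2.0, 3.0, 4.0, 5.0])
        assert m.undercovered
        assert (m.lo, m.hi) == (1.0, 5.0)

    def test_coverage_simulation(self):
        # binomial order-statistic CI covers the true median about 95%
        rng = np.random.default_rng(0)
        hits = 0
        trials = 400
        for _ in range(trials):
            x = rng.standard_cauchy(25)  # heavy tails on purpose
            m = st.median_with_ci(x)
            hits += m.lo <= 0.0 <= m.hi
        assert 0.93 <= hits / trials <= 0.995


class TestBootstrap:
    def test_pure_shift_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        b = st.bootstrap_median_difference(x, x + 3.0, seed=5)
        assert b.diff == pytest.approx(3.0)
        assert b.lo < 3.0 < b.hi

    def test_seeded_determinism(self):
        x = np.arange(20.0)
        y = x + 1.5
        b1 = st.bootstrap_median_difference(x, y, seed=9)
        b2 = st.bootstrap_median_difference(x, y, seed=9)
        assert (b1.lo, b1.hi) == (b2.lo, b2.hi)
        assert np.array_equal(b1.distribution, b2.distribution)

    def test_coverage_on_heavy_tails(self):
        rng = np.random.default_rng(2)
        hits = 0
        trials = 200
        for _ in range(trials):
            x = rng.standard_t(df=2, size=25)
            y = rng.standard_t(df=2, size=25) + 1.0
            b = st.bootstrap_median_difference(x, y, n_boot=600,
                                               seed=int(rng.integers(2**31)))
            hits += b.lo <= 1.0 <= b.hi
        assert 0.90 <= hits / trials <= 0.99

    def test_tiny_sample_flagged(self):
        b = st.bootstrap_median_difference([1, 2, 3.0], [2, 3, 4.0], seed=0)
        assert b.undercovered


class TestEffectSize:
    def test_formula(self):
        eta, cat = st.eta_squared_from_z(2.0, 41)
        assert eta == pytest.approx(0.1)
        assert cat == "medium"

    def test_null(self):
        assert st.eta_squared_from_z(0.0, 10)[0] == 0.0

    @pytest.mark.parametrize(
        "u,n1,n2,printed",
        [
            (281, 32, 34, 0.17),   # time-constant contrast
            (296, 30, 33, 0.12),   # input-resistance contrast
            (380, 33, 35, 0.09),   # sag contrast
            (87, 18, 18, 0.16),    # tonic-rheobase contrast
            (287, 31, 32, 0.13),   # burst-rheobase contrast
            (397, 34, 35, 0.08),   # rebound-rheobase contrast
            (393, 33, 34, 0.07),   # afterhyperpolarization contrast
        ],
    )
    def test_consistency_with_reported_values(self, u, n1, n2, printed):
        """eta^2 = z^2/(N-1) reproduces the published effect sizes."""
        eta, _ = st.eta_squared_from_u(u, n1, n2)
        assert abs(eta - printed) < 0.015


class TestSpearman:
    def test_perfect_monotone(self):
        rs, p = st.spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rs == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # only the two perfect orderings

    def test_antitone(self):
        rs, _ = st.spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert rs == pytest.approx(-1.0)

    def test_exact_enumeration_probability(self):
        # frozen from brute-force enumeration of all 5! rank permutations
        rs, p = st.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rs == pytest.approx(0.8)
        assert p == pytest.approx(16 / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            st.spearman_rho([1.0] * 5, [1, 2, 3, 4, 5])

    def test_large_n_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rs, p = st.spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSampleSize:
    def test_reported_power_analysis(self):
        # 25% difference in a ~80 ms time constant with SD 20 ms
        n = st.sample_size_two_sample_t(st.PowerSpec(delta=20.0, sd=20.0))
        assert n == 16

    def test_two_sd_effect(self):
        assert st.sample_size_two_sample_t(st.PowerSpec(delta=2.0, sd=1.0)) == 4

    def test_huge_effect_limit(self):
        assert st.sample_size_two_sample_t(st.PowerSpec(delta=1e6, sd=1.0)) == 1

    def test_exact_t_variant_is_slightly_larger(self):
        approx = st.sample_size_two_sample_t(st.PowerSpec(20.0, 20.0))
        exact = st.sample_size_two_sample_t(st.PowerSpec(20.0, 20.0), exact_t=True)
        assert exact >= approx

    def test_zero_delta_rejected(self):
        with pytest.raises(DomainError):
            st.sample_size_two_sample_t(st.PowerSpec(delta=0.0, sd=1.0))


class TestComparisonBundle:
    def test_eta_only_when_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=20)
        res = st.compare_two_groups(a, a + 5.0, feature="shifted", seed=1)
        assert res.p < 0.05 and res.eta_sq is not None
        res0 = st.compare_two_groups(a, a, feature="null", seed=1)
        assert res0.p > 0.05 and res0.eta_sq is None

    def test_paired_mode_uses_wilcoxon(self):
        pre = np.arange(1.0, 13.0)
        res = st.compare_two_groups(pre, pre - 2.0, paired=True, seed=0)
        assert res.method == "wilcoxon"
        assert res.statistic == -78.0  # 12 all-negative signed ranks
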