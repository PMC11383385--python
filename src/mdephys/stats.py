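"""Nonparametric estimation statistics for two-group and paired comparisons.

Conventions: U is reported as min(U_x, U_y); W is the sum of signed ranks
(so n all-negative differences give W = -n(n+1)/2); p-values are two-sided;
exact null distributions are used for small tie-free samples and normal
approximations with tie and continuity corrections otherwise; medians carry
order-statistic (binomial) confidence intervals; median differences carry
seeded percentile-bootstrap intervals; the rank-test effect size is
eta^2 = z^2 / (N - 1), categorised as small (0.01), medium (0.06) or
large (0.14).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "ComparisonResult",
    "PowerSpec",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "median_with_ci",
    "bootstrap_median_difference",
    "eta_squared_from_z",
    "eta_squared_from_u",
    "spearman_rho",
    "sample_size_two_sample_t",
    "compare_two_groups",
]

#: largest combined sample for which the Mann-Whitney p is enumerated exactly
EXACT_MW_LIMIT = 16
#: largest n for which the signed-rank p is enumerated exactly
EXACT_WILCOXON_LIMIT = 15
#: largest n for which the Spearman p is enumerated exactly
EXACT_SPEARMAN_LIMIT = 9

ETA_SQ_CUTOFFS = (("large", 0.14), ("medium", 0.06), ("small", 0.01))


def _eta_category(eta_sq: float) -> str:
    for name, cut in ETA_SQ_CUTOFFS:
        if eta_sq >= cut:
            return name
    return "negligible"


# ---------------------------------------------------------------------------
# Mann-Whitney


def _rank_with_ties(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks and the tie-group sizes."""
    ranks = sps.rankdata(z, method="average")
    _, counts = np.unique(z, return_counts=True)
    return ranks, counts


def _mw_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U_x over all C(n1+n2, n1) arrangements (no ties).

    counts[u] = number of rank assignments giving U = u, from the subset-sum
    DP over which of the ranks 1..n belong to sample x.
    """
    n = n1 + n2
    max_s = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_s + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    rank_sum_counts = dp[n1]
    offset = n1 * (n1 + 1) // 2
    return rank_sum_counts[offset: offset + n1 * n2 + 1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney test.

    Returns (U, p) with U = min(U_x, U_y), midranks for ties.  The p-value is
    exact (full enumeration) for tie-free samples with n_x + n_y <= 16 and a
    tie- and continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise DomainError("both samples must be non-empty")
    z = np.concatenate([x, y])
    ranks, tie_counts = _rank_with_ties(z)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    has_ties = bool(np.any(tie_counts > 1))
    if not has_ties and n1 + n2 <= EXACT_MW_LIMIT:
        counts = _mw_exact_counts(n1, n2)
        total = counts.sum()
        # two-sided: P(U_min <= u) == P(U1 <= u) + P(U1 >= n1 n2 - u)
        k = int(round(u))
        p = (counts[:k + 1].sum() + counts[n1 * n2 - k:].sum()) / total
        return float(u), float(min(1.0, p))

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    zstat = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(max(zstat, 0.0))
    return float(u), float(min(1.0, p))


def mann_whitney_z(u: float, n1: int, n2: int) -> float:
    """Normal deviate corresponding to a U statistic (no tie correction)."""
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (u - mu) / sd


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _wilcoxon_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank sum by subset enumeration (DP)."""
    # distribution of W+ over all 2^n sign assignments
    scale = 2  # ranks may be half-integral with ties; work in doubled units
    r2 = np.round(ranks * scale).astype(int)
    tot = int(r2.sum())
    f = np.zeros(tot + 1)
    f[0] = 1.0
    for r in r2:
        g = f.copy()
        g[r:] += f[: tot + 1 - r]
        f = g
    f /= f.sum()
    wp = int(round(w_plus * scale))
    # the null distribution of W+ is symmetric about tot/2 (in doubled units)
    lo = min(wp, tot - wp)
    hi = max(wp, tot - wp)
    p = f[: lo + 1].sum() + f[hi:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Paired signed-rank test with the signed-sum convention.

    W = sum of signed ranks of |post - pre| (negative when post < pre
    dominates).  Zero differences are dropped before ranking.  Exact p for
    n <= 15, normal approximation with tie and continuity corrections
    otherwise.  All differences zero is degenerate: returns (0, 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise DomainError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d), method="average")
    w = float(np.sum(np.sign(d) * ranks))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_LIMIT:
        p = _wilcoxon_exact_p(w_plus, ranks)
        return w, p

    # normal approximation on W (mean 0), tie-corrected variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 6.0
    var -= float(np.sum(counts**3 - counts)) / 12.0
    zstat = (abs(w) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(max(zstat, 0.0))
    return w, float(min(1.0, p))


# ---------------------------------------------------------------------------
# medians and bootstrap


@dataclass
class MedianCI:
    median: float
    lo: float
    hi: float
    level: float
    undercovered: bool = False


def median_with_ci(x: Sequence[float], level: float = 0.95) -> MedianCI:
    """Sample median with a distribution-free order-statistic CI.

    Uses the smallest symmetric order-statistic pair whose binomial coverage
    reaches the requested level; for n < 6 no such pair exists and the sample
    range is returned with the under-coverage flag set.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise DomainError("empty sample")
    med = float(np.median(x))
    if n == 1:
        return MedianCI(med, med, med, level, undercovered=True)
    best = None
    for k in range(1, n // 2 + 1):
        cover = sps.binom.cdf(n - k, n, 0.5) - sps.binom.cdf(k - 1, n, 0.5)
        if cover >= level:
            best = k
    if best is None:
        return MedianCI(med, float(x[0]), float(x[-1]), level, undercovered=True)
    return MedianCI(med, float(x[best - 1]), float(x[n - best]), level)


@dataclass
class BootstrapDiff:
    diff: float          # median(y) - median(x); x is the reference group
    lo: float
    hi: float
    distribution: np.ndarray
    undercovered: bool = False


def bootstrap_median_difference(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapDiff:
    """Seeded percentile bootstrap of the difference in medians (y minus x,
    group x as reference).  The full bootstrap distribution is retained so
    estimation plots can show it."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    under = x.size < 5 or y.size < 5
    rng = np.random.default_rng(seed)
    bx = rng.integers(0, x.size, size=(n_boot, x.size))
    by = rng.integers(0, y.size, size=(n_boot, y.size))
    dist = np.median(y[by], axis=1) - np.median(x[bx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(dist, [alpha, 1.0 - alpha])
    return BootstrapDiff(
        diff=float(np.median(y) - np.median(x)),
        lo=float(lo), hi=float(hi), distribution=dist, undercovered=under,
    )


# ---------------------------------------------------------------------------
# effect size, correlation, power


def eta_squared_from_z(z: float, n_total: int) -> tuple[float, str]:
    """Rank-test effect size eta^2 = z^2/(N-1) with its size category."""
    if n_total < 2:
        raise DomainError("n_total must be >= 2")
    eta = z * z / (n_total - 1)
    return float(eta), _eta_category(eta)


def eta_squared_from_u(u: float, n1: int, n2: int) -> tuple[float, str]:
    """eta^2 computed from a Mann-Whitney U via its normal deviate."""
    return eta_squared_from_z(mann_whitney_z(u, n1, n2), n1 + n2)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with two-sided p.

    p by exact enumeration over permutations for n <= 9, otherwise by the
    t approximation.  Constant input has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise DomainError("need n >= 4 for a Spearman correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])

    ties = np.any(np.unique(x, return_counts=True)[1] > 1) or np.any(
        np.unique(y, return_counts=True)[1] > 1)
    if n <= EXACT_SPEARMAN_LIMIT and not ties:
        from itertools import permutations

        perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
        rx0 = np.arange(1, n + 1, dtype=float)
        num = perms @ rx0 - n * ((n + 1) / 2.0) ** 2
        den = (np.sum(rx0**2) - n * ((n + 1) / 2.0) ** 2)
        all_rs = num / den
        p = float(np.mean(np.abs(all_rs) >= abs(rs) - 1e-12))
        return rs, p

    if abs(rs) >= 1.0:
        return rs, 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rs, float(min(1.0, p))


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-sample sample-size calculation."""

    delta: float          # difference in means to detect
    sd: float             # common standard deviation
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DomainError("sd must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise DomainError("alpha and power must be in (0, 1)")


def sample_size_two_sample_t(spec: PowerSpec, exact_t: bool = False) -> int:
    """Cells per group to detect ``delta`` at the given alpha and power.

    Default: the two-sided normal-approximation formula
    n = ceil(2 sd^2 (z_{1-alpha/2} + z_{power})^2 / delta^2).  With
    ``exact_t`` the noncentral-t requirement is iterated instead (one to two
    cells larger).
    """
    if spec.delta == 0:
        raise DomainError("delta must be nonzero")
    za = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = sps.norm.ppf(spec.power)
    n = 2.0 * (spec.sd / spec.delta) ** 2 * (za + zb) ** 2
    n_norm = max(1, math.ceil(n - 1e-12))
    if not exact_t:
        return n_norm
    n_it = max(2, n_norm)
    while True:
        df = 2 * (n_it - 1)
        tc = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        ncp = abs(spec.delta) / (spec.sd * math.sqrt(2.0 / n_it))
        achieved = sps.nct.sf(tc, df, ncp)
        if achieved >= spec.power:
            return n_it
        n_it += 1


# ---------------------------------------------------------------------------
# bundled two-group comparison


@dataclass
class ComparisonResult:
    """Everything the reporting layer needs for one feature contrast."""

    feature: str
    n_a: int
    n_b: int
    statistic: float               # U (unpaired) or W (paired)
    p: float
    median_a: MedianCI
    median_b: MedianCI
    diff: BootstrapDiff            # b minus a, group a as reference
    eta_sq: Optional[float] = None   # present only when p < 0.05
    eta_category: Optional[str] = None
    method: str = "mann-whitney"
    exact: bool = False


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    feature: str = "",
    n_boot: int = 5000,
    seed: int = 0,
    paired: bool = False,
) -> ComparisonResult:
    """Full two-group bundle: rank test, median CIs, bootstrap median
    difference, and eta^2 (reported only when p < 0.05)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        stat, p = wilcoxon_signed_rank(a, b)
        method = "wilcoxon"
        n_for_eta = a.size
        d = b - a
        nz = d[d != 0]
        var = nz.size * (nz.size + 1) * (2 * nz.size + 1) / 6.0
        zstat = stat / math.sqrt(var) if var > 0 else 0.0
    else:
        stat, p = mann_whitney_u(a, b)
        method = "mann-whitney"
        n_for_eta = a.size + b.size
        zstat = mann_whitney_z(stat, a.size, b.size)
    exact = (
        (not paired and a.size + b.size <= EXACT_MW_LIMIT)
        or (paired and a.size <= EXACT_WILCOXON_LIMIT)
    )
    res = ComparisonResult(
        feature=feature,
        n_a=int(a.size), n_b=int(b.size),
        statistic=float(stat), p=float(p),
        median_a=median_with_ci(a),
        median_b=median_with_ci(b),
        diff=bootstrap_median_difference(a, b, n_boot=n_boot, seed=seed),
        method=method, exact=exact,
    )
    if p < 0.05:
        eta, cat = eta_squared_from_z(zstat, n_for_eta)
        res.eta_sq = eta
        res.eta_category = cat
    return res
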