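"""Rank tests, ANOVA with post hocs, 2x2 categorical tests, BH FDR, Spearman.

These are the generic inferential procedures the analysis pipeline leans on.
They are written from first principles on top of ``scipy.special`` CDFs so
every convention (mid-rank ties, tie-corrected variances, no continuity
correction in the rank-test normal approximation, step-up FDR) is explicit
and testable against independent references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import integrate, special

__all__ = [
    "TestResult",
    "PosthocTable",
    "FdrResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "anova_oneway",
    "tukey_hsd",
    "welch_t",
    "chi2_2x2",
    "fisher_exact_2x2",
    "bh_fdr",
    "spearman",
    "studentized_range_cdf",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is U, H, F, t, chi-square, z or rho depending on ``method``;
    ``df`` is a float or pair of floats where the reference distribution has
    degrees of freedom; ``n`` records the per-group sample sizes.
    """

    statistic: float
    p_value: float
    method: str
    df: float | tuple[float, float] | None = None
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class PosthocTable:
    """All pairwise comparisons following an omnibus test."""

    pairs: tuple[tuple[int, int], ...]
    statistics: tuple[float, ...]
    p_raw: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    adjustment: str

    def as_dict(self) -> dict[tuple[int, int], float]:
        return dict(zip(self.pairs, self.p_adjusted))


@dataclass(frozen=True)
class FdrResult:
    p_values: tuple[float, ...]
    q_values: tuple[float, ...]
    m: int


# ---------------------------------------------------------------------------
# rank utilities
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average rank within tied blocks), 1-based."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """sum over tied blocks of (t^3 - t)."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_counts(nx: int, ny: int) -> np.ndarray:
    """Null distribution of U as counts over 0..nx*ny.

    Standard recurrence c(a, b, u) = c(a-1, b, u-b) + c(a, b-1, u): the largest
    pooled observation is either an x (beating all b y's) or a y. Identical to
    enumerating every assignment of ranks to the two groups.
    """
    m = nx * ny
    c = np.zeros((nx + 1, ny + 1, m + 1))
    c[:, 0, 0] = 1.0
    c[0, :, 0] = 1.0
    for a in range(1, nx + 1):
        for b in range(1, ny + 1):
            c[a, b, b:] += c[a - 1, b, : m + 1 - b]
            c[a, b, :] += c[a, b - 1, :]
    return c[nx, ny]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test; U counts y-over-x wins, ties as 1/2.

    ``mode='auto'`` uses the exact null distribution when nx*ny <= 400 and
    there are no ties, otherwise the normal approximation with tie-corrected
    variance (no continuity correction, so that the two-group Kruskal-Wallis
    identity H = z^2 holds exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode: {mode!r}")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r_y = float(ranks[nx:].sum())
    u = r_y - ny * (ny + 1) / 2.0  # y-over-x wins with ties as 1/2
    m = nx * ny
    has_ties = len(np.unique(pooled)) < len(pooled)

    use_exact = mode == "exact" or (mode == "auto" and m <= 400 and not has_ties)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        counts = _exact_u_counts(nx, ny)
        total = math.comb(nx + ny, nx)
        u_int = int(round(u))
        hi = max(u_int, m - u_int)
        # symmetric null: two-sided p doubles the upper tail
        tail = int(sum(counts[hi:]))
        p = min(1.0, 2.0 * tail / total)
        return TestResult(u, p, "mann_whitney_exact", n=(nx, ny))

    big_n = nx + ny
    tie = _tie_term(pooled)
    var = m / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "mann_whitney_normal", n=(nx, ny))
    z = (u - m / 2.0) / math.sqrt(var)
    p = min(1.0, 2.0 * special.ndtr(-abs(z)))
    return TestResult(u, p, "mann_whitney_normal", n=(nx, ny))


def _mann_whitney_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation z (shared with the H == z^2 check)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[nx:].sum()) - ny * (ny + 1) / 2.0
    big_n = nx + ny
    var = nx * ny / 12.0 * ((big_n + 1) - _tie_term(pooled) / (big_n * (big_n - 1)))
    if var <= 0:
        return 0.0
    return (u - nx * ny / 2.0) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    big_n = int(pooled.size)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for n_i in sizes:
        r_bar = ranks[start : start + n_i].mean()
        h += n_i * r_bar**2
        start += n_i
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(pooled) / (big_n**3 - big_n)
    if correction <= 0:  # every pooled value identical
        return TestResult(0.0, 1.0, "kruskal_wallis", df=len(groups) - 1,
                          n=tuple(int(s) for s in sizes))
    h /= correction
    h = max(h, 0.0)
    p = float(special.chdtrc(len(groups) - 1, h))
    return TestResult(h, p, "kruskal_wallis", df=len(groups) - 1,
                      n=tuple(int(s) for s in sizes))


def dunn_posthoc(
    groups: Sequence[Sequence[float]], adjustment: str = "bh"
) -> PosthocTable:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z for pair (i, j) is the difference of pooled-rank means over the
    tie-corrected standard error; two-sided normal p-values are adjusted with
    the chosen method (``bh`` default, ``bonferroni`` or ``none``).
    """
    if len(groups) < 3:
        raise ValueError("Dunn post hoc needs at least 3 groups")
    if adjustment not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment: {adjustment!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    big_n = int(pooled.size)
    ranks = _midranks(pooled)
    rank_means, start = [], 0
    for a in arrays:
        rank_means.append(ranks[start : start + a.size].mean())
        start += a.size
    base_var = big_n * (big_n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (big_n - 1))

    pairs, zs, p_raw = [], [], []
    for i, j in combinations(range(len(groups)), 2):
        se2 = base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if se2 <= 0:
            z = 0.0
        else:
            z = (rank_means[i] - rank_means[j]) / math.sqrt(se2)
        pairs.append((i, j))
        zs.append(z)
        p_raw.append(min(1.0, 2.0 * float(special.ndtr(-abs(z)))))

    if adjustment == "bh":
        p_adj = list(bh_fdr(p_raw).q_values)
    elif adjustment == "bonferroni":
        p_adj = [min(1.0, p * len(p_raw)) for p in p_raw]
    else:
        p_adj = list(p_raw)
    return PosthocTable(tuple(pairs), tuple(zs), tuple(p_raw), tuple(p_adj),
                        adjustment)


# ---------------------------------------------------------------------------
# one-way ANOVA and Tukey(-Kramer) HSD
# ---------------------------------------------------------------------------

def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA, F on (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    big_n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df = (k - 1, big_n - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(0.0, 1.0, "anova_oneway", df=df,
                              n=tuple(a.size for a in arrays))
        return TestResult(float("inf"), 0.0, "anova_oneway", df=df,
                          n=tuple(a.size for a in arrays))
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(special.fdtrc(df[0], df[1], f))
    return TestResult(f, p, "anova_oneway", df=df,
                      n=tuple(a.size for a in arrays))


def studentized_range_cdf(q: float, k: int, df: float, epsabs: float = 1e-8) -> float:
    """P(Q <= q) for the studentized range of k groups with df error df.

    Double numerical integration of the classical representation: the outer
    integral over the scale s = chi/sqrt(df), the inner over the location of
    the smallest of the k standard-normal means.
    """
    if q <= 0:
        return 0.0
    k = int(k)
    nu = float(df)

    def inner(s: float) -> float:
        def integrand(z: float) -> float:
            return k * _phi(z) * (special.ndtr(z) - special.ndtr(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(integrand, -np.inf, np.inf,
                                epsabs=epsabs, limit=200)
        return val

    log_c = (nu / 2.0) * math.log(nu) - (nu / 2.0 - 1.0) * math.log(2.0) \
        - special.gammaln(nu / 2.0)

    def outer(s: float) -> float:
        log_dens = log_c + (nu - 1.0) * math.log(s) - nu * s * s / 2.0
        return math.exp(log_dens) * inner(s)

    val, _ = integrate.quad(outer, 0.0, np.inf, epsabs=epsabs, limit=200)
    return min(1.0, max(0.0, val))


def _phi(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> PosthocTable:
    """Tukey(-Kramer) honestly-significant-difference pairwise comparisons.

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)); p-values from
    the studentized-range distribution with (k, N-k) parameters.
    """
    if len(groups) < 3:
        raise ValueError("Tukey HSD needs at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    big_n = sum(a.size for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df = big_n - k
    mse = ssw / df
    pairs, qs, ps = [], [], []
    for i, j in combinations(range(k), 2):
        diff = abs(arrays[i].mean() - arrays[j].mean())
        if mse == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = math.sqrt(mse / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            q = diff / se
            p = 1.0 - studentized_range_cdf(q, k, df)
            p = min(1.0, max(0.0, p))
        pairs.append((i, j))
        qs.append(q)
        ps.append(p)
    # Tukey p-values are already familywise; no further adjustment applied
    return PosthocTable(tuple(pairs), tuple(qs), tuple(ps), tuple(ps), "tukey")


# ---------------------------------------------------------------------------
# Welch t (per-protein differential testing)
# ---------------------------------------------------------------------------

def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch t needs at least 2 observations per group")
    vx = x.var(ddof=1) / x.size
    vy = y.var(ddof=1) / y.size
    diff = y.mean() - x.mean()
    if vx + vy == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, "welch_t", df=float(x.size + y.size - 2),
                              n=(x.size, y.size))
        return TestResult(float("inf") if diff > 0 else float("-inf"), 0.0,
                          "welch_t", df=float(x.size + y.size - 2),
                          n=(x.size, y.size))
    t = diff / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return TestResult(t, min(1.0, p), "welch_t", df=df, n=(x.size, y.size))


# ---------------------------------------------------------------------------
# 2x2 categorical tests
# ---------------------------------------------------------------------------

def chi2_2x2(table: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1.

    Default is WITHOUT the Yates continuity correction; pass ``yates=True``
    for the corrected statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2.0)
    chi2 = n * num**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(special.chdtrc(1, chi2))
    return TestResult(float(chi2), p, "chi2_yates" if yates else "chi2_pearson",
                      df=1.0, n=(int(rows[0]), int(rows[1])))


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Fisher's exact test, two-sided by summing tables as or less probable."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k: int) -> float:
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p_obs = pmf(a)
    p = sum(pk for k in range(lo, hi + 1)
            if (pk := pmf(k)) <= p_obs * (1 + 1e-10))
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult(odds, min(1.0, p), "fisher_exact", n=(r1, c + d))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> FdrResult:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult((), (), 0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return FdrResult(tuple(p.tolist()), tuple(q.tolist()), int(m))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation; two-sided p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    rx = _midranks(x)
    ry = _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return TestResult(rho, 0.0, "spearman", df=float(n - 2), n=(n,))
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return TestResult(rho, min(1.0, p), "spearman", df=float(n - 2), n=(n,))
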