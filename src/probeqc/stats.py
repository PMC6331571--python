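"""Statistical comparisons used across the pipeline.

Thin, contract-tested wrappers around scipy for the standard tests
(Kruskal-Wallis, Mann-Whitney U, chi-squared, Pearson r, t-test/ANOVA),
plus two hand-written procedures that no installed library provides:
Dunn's post-hoc rank test with Bonferroni correction, and Hartigan's dip
statistic of unimodality with a Monte-Carlo uniform-null p-value.

Conventions: alpha = 0.05 throughout; post-hoc tests run only when the
omnibus test is significant; adjusted p-values are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "kruskal_dunn",
    "mann_whitney",
    "chi_squared_2xk",
    "dip_statistic",
    "dip_test",
    "pearson_r",
    "t_test",
    "anova",
    "KruskalDunnResult",
]

ALPHA = 0.05


# --------------------------------------------------------------------------
# Hartigan's dip statistic
# --------------------------------------------------------------------------

def _side_costs(x: np.ndarray, y_hull: np.ndarray, y_dev: np.ndarray) -> np.ndarray:
    """Prefix deviation costs for the convex side of a unimodal-cdf fit.

    Processing points left to right, maintains the lower convex hull of
    (x, y_hull) and, after inserting point k, the maximum of
    y_dev[j] - hull(x_j) over j < k.  Inserting a point can only lower
    the hull, so deviations only grow and a running maximum over the
    re-hulled spans is exact.

    Returns M with M[k] = max_{j < k} (y_dev[j] - hull_k(x_j)), M[0] = 0.
    """
    n = len(x)
    M = np.zeros(n)
    dev = np.full(n, -np.inf)
    hull: list[int] = []  # indices of hull vertices
    running = 0.0
    for k in range(n):
        # y_hull is strictly increasing, so at tied x the hull keeps the
        # earlier (lower) point and this one just sits above it
        if hull and x[hull[-1]] == x[k]:
            M[k] = running
            dev[k] = y_dev[k] - y_hull[hull[-1]]
            running = max(running, dev[k])
            continue
        while len(hull) >= 2:
            j, m = hull[-2], hull[-1]
            # pop m if chord j -> k passes on or below it
            if (y_hull[m] - y_hull[j]) * (x[k] - x[j]) >= (
                y_hull[k] - y_hull[j]
            ) * (x[m] - x[j]):
                hull.pop()
            else:
                break
        if hull:
            v = hull[-1]
            span = np.arange(v, k)
            h = y_hull[v] + (y_hull[k] - y_hull[v]) * (
                (x[span] - x[v]) / (x[k] - x[v])
            )
            dev[span] = np.maximum(dev[span], y_dev[span] - h)
            running = max(running, float(dev[span].max()))
        M[k] = running
        dev[k] = y_dev[k] - y_hull[k]
        running = max(running, dev[k])
        hull.append(k)
    return M


def _join_envelopes(x: np.ndarray, D: float):
    """Extremal junction values of the two half-fits at each mode point.

    For the band of half-width D (count units), returns (A, B) where
    A[k] is the lowest value a convex in-band function over x_0..x_k-1
    can take when extended linearly to x_k, and B[k] the highest value a
    concave in-band function over x_k+1..x_n-1 can start from at x_k.
    Both are envelopes of extrapolation lines through one lower- and one
    upper-band point; a unimodal fit with its mode (and possibly an
    atom) at x_k exists iff additionally A[k] <= B[k].
    """
    n = len(x)
    L = np.arange(1, n + 1, dtype=float) - D   # count lower bands
    U = np.arange(n, dtype=float) + D          # count upper bands (left limits)

    dx = x[None, :] - x[:, None]               # dx[i, j] = x_j - x_i
    with np.errstate(divide="ignore", invalid="ignore"):
        # steepest forced slope into each j from some earlier i
        num = L[None, :] - U[:, None]          # L_j - U_i
        s = np.where(dx > 0, num / dx, np.where(num > 0, np.inf, -np.inf))
        s = np.where(np.tri(n, k=-1).T.astype(bool), s, -np.inf)  # i < j only
        sigma = np.maximum(s.max(axis=0), 0.0)                    # per j
        # steepest forced slope out of each j toward some later i
        num2 = L[:, None] - U[None, :]         # L_i - U_j  (i > j)
        s2 = np.where(dx.T > 0, num2 / dx.T, np.where(num2 > 0, np.inf, -np.inf))
        s2 = np.where(np.tri(n, k=-1).astype(bool), s2, -np.inf)
        sigma_t = np.maximum(s2.max(axis=0), 0.0)

        lines_a = L[:, None] + sigma[:, None] * dx      # line from j at x_k
        lines_a = np.where(np.tri(n, k=-1).T.astype(bool), lines_a, -np.inf)
        A = np.maximum(lines_a.max(axis=0), 0.0)
        lines_b = U[:, None] - sigma_t[:, None] * (-dx)  # from j>k back to x_k
        lines_b = np.where(np.tri(n, k=-1).astype(bool), lines_b, np.inf)
        B = np.minimum(lines_b.min(axis=0), np.arange(1, n + 1, dtype=float) + D)
        B = np.minimum(B, float(n))
    return A, B


def dip_statistic(values) -> float:
    """Hartigan's dip: min over unimodal cdfs G of sup |F_n - G|.

    Computed by decomposing over the position of the mode among the
    order statistics (an atom is allowed at the mode; any unimodal fit
    with an interior mode converts to one of this form).  With the mode
    at x_k, a band of half-width d admits a fit iff (i) the empirical
    cdf rises no more than 2d above the greatest convex minorant of its
    left limits over x_1..x_k, (ii) falls no more than 2d below the
    least concave majorant of its values over x_k..x_n, and (iii) the
    lowest convex endpoint does not exceed the highest concave start
    (the junction condition).  (i)/(ii) give closed-form per-mode
    thresholds from incremental hulls; (iii) is monotone in d and is
    resolved by bisection over line-extrapolation envelopes.

    Cross-validated against a linear-programming oracle of the defining
    minimax problem.  The result is at least 1/(2n) for non-degenerate
    samples and at most 0.25 (approached by two well-separated point
    masses).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0
    t = _mode_thresholds(x)
    lo = float(t.min())
    hi = max(0.25 * n, lo)
    if _band_feasible(x, t, lo):
        return lo / n
    while not _band_feasible(x, t, hi):  # numeric safety; dip <= 1/4 in theory
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _band_feasible(x, t, mid):
            hi = mid
        else:
            lo = mid
    return hi / n


def _mode_thresholds(x: np.ndarray) -> np.ndarray:
    """Per-mode hull thresholds in count units (independent of the band)."""
    n = len(x)
    f_lo = np.arange(n, dtype=float)
    f_hi = np.arange(1, n + 1, dtype=float)
    V = _side_costs(x, f_lo, f_hi)
    W = _side_costs(-x[::-1], -f_hi[::-1], -f_lo[::-1])[::-1]
    return np.maximum(V, W) / 2.0


def _band_feasible(x: np.ndarray, t: np.ndarray, D: float) -> bool:
    A, B = _join_envelopes(x, D)
    return bool(np.any((t <= D + 1e-12) & (A <= B + 1e-9)))


def _dip_at_least(values, d: float) -> bool:
    """Whether dip(values) >= d, via one feasibility query (no bisection)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 1 or x[0] == x[-1]:
        return 0.0 >= d
    D = d * n * (1.0 - 1e-12) - 1e-12
    t = _mode_thresholds(x)
    if t.min() >= D:
        return True
    return not _band_feasible(x, t, D)


_NULL_CACHE: dict = {}


def dip_null_distribution(n: int, reps: int = 2000, seed=0) -> np.ndarray:
    """Monte-Carlo null dips for samples of size n from the uniform.

    Cached on (n, reps, seed); useful when many samples of the same size
    are tested against the same null.
    """
    key = (int(n), int(reps), int(seed))
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.random(n)) for _ in range(reps)]
        )
    return _NULL_CACHE[key]


def dip_test(values, reps: int = 2000, seed=0, null_dips=None) -> tuple[float, float]:
    """Hartigan's dip test of unimodality.

    Returns (dip, p); p is Monte-Carlo calibrated against samples of the
    same size from the uniform distribution (the classical null).  A
    precomputed ``null_dips`` array for this sample size may be supplied
    to amortize the calibration; otherwise each null draw is only tested
    for exceeding the observed dip, which needs no bisection.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError("dip test requires at least 8 values")
    d = dip_statistic(values)
    if null_dips is not None:
        exceed = int(np.count_nonzero(np.asarray(null_dips) >= d))
        reps = len(null_dips)
    else:
        rng = np.random.default_rng(seed)
        exceed = sum(_dip_at_least(rng.random(n), d) for _ in range(reps))
    p = (1.0 + exceed) / (reps + 1.0)
    return d, float(p)


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _check_groups(groups, min_size=2, min_groups=2):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for g in groups:
        if len(g) < min_size:
            raise ValueError(f"every group needs at least {min_size} samples")
        if not np.all(np.isfinite(g)):
            raise ValueError("samples must be finite")
    return groups


@dataclass
class KruskalDunnResult:
    statistic: float
    p: float
    posthoc: pd.DataFrame | None  # pairwise table, None unless omnibus p < alpha


def _dunn_posthoc(groups) -> pd.DataFrame:
    """Dunn's z-test on mean ranks with tie correction, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    n_tot = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    k_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sstats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": i,
                "group_b": j,
                "z": z,
                "p_raw": p_raw,
                "p_adj": min(1.0, k_pairs * p_raw),
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(groups) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus + Dunn/Bonferroni pairwise post-hoc.

    The post-hoc table is computed only when the omnibus test rejects at
    alpha = 0.05 and at least 3 groups are present.
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalDunnResult(0.0, 1.0, None)
    stat, p = sstats.kruskal(*groups)
    posthoc = None
    if p < ALPHA and len(groups) >= 3:
        posthoc = _dunn_posthoc(groups)
    return KruskalDunnResult(float(stat), float(p), posthoc)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples."""
    a, b = _check_groups([group_a, group_b], min_size=1)
    pooled = np.concatenate([a, b])
    method = (
        "exact"
        if len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
        else "asymptotic"
    )
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_squared_2xk(table) -> tuple[float, float, int]:
    """Pearson chi-squared on a 2 x k count table; df = k - 1."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("need a 2 x k table with k >= 2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = sstats.chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation; undefined for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def t_test(group_a, group_b) -> tuple[float, float]:
    """Two-tailed independent-samples Student's t-test."""
    a, b = _check_groups([group_a, group_b])
    if np.all(np.concatenate([a, b]) == a[0]):
        return 0.0, 1.0
    res = sstats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def anova(groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA: returns (F, (df_between, df_within), p)."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    k, n = len(groups), len(pooled)
    if np.all(pooled == pooled[0]):
        return 0.0, (k - 1, n - k), 1.0
    f, p = sstats.f_oneway(*groups)
    return float(f), (k - 1, n - k), float(p)
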