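"""Two-group hypothesis tests for small culture-replicate designs.

Group sizes here are tiny (3 control vs 4-6 supplemented replicates), so
the Mann-Whitney U test uses the exact null distribution of U (full
enumeration over rank assignments) whenever the combined sample is small
and tie-free, falling back to the tie-corrected normal approximation with
continuity correction otherwise. Welch's t-test and the 2x2 Pearson
chi-squared (presence/absence frequencies) delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "t_test",
    "presence_chi2",
    "benjamini_hochberg",
    "compare_groups",
]


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_x: int
    n_y: int
    degenerate: bool = False


@lru_cache(maxsize=None)
def _exact_u_pmf(nx: int, ny: int) -> tuple[float, ...]:
    """P(U = u) for u = 0..nx*ny under the exact Mann-Whitney null.

    Counts subsets of size nx of the ranks {1..nx+ny} by rank sum with a
    plain subset-sum dynamic program (every rank assignment to the first
    group equally likely under the null), then shifts the rank sum to U.
    """
    n = nx + ny
    max_s = sum(range(n - nx + 1, n + 1))
    f = np.zeros((nx + 1, max_s + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, n + 1):
        for i in range(min(nx, r), 0, -1):
            f[i, r:] += f[i - 1, : max_s + 1 - r]
    min_s = nx * (nx + 1) // 2
    counts = f[nx, min_s : min_s + nx * ny + 1]
    return tuple(counts / comb(n, nx))


def _exact_two_sided_p(u: float, nx: int, ny: int) -> float:
    """Two-sided p: total probability of outcomes at least as far from
    the null mean nx*ny/2 as the observed U (symmetric-null convention)."""
    pmf = np.array(_exact_u_pmf(nx, ny))
    mu = nx * ny / 2.0
    dev = abs(u - mu)
    us = np.arange(len(pmf))
    return float(pmf[np.abs(us - mu) >= dev - 1e-12].sum())


def mann_whitney(x, y, exact_cap: int = 12) -> TestResult:
    """Double-tailed Mann-Whitney U test.

    Exact enumeration when n_x + n_y <= ``exact_cap`` and the pooled data
    are tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction. The U statistic reported is the
    U of the first sample (number of (x, y) pairs with x > y, counting
    ties as 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0
    has_ties = len(np.unique(pooled)) < nx + ny
    if not has_ties and nx + ny <= exact_cap:
        p = _exact_two_sided_p(u, nx, ny)
        return TestResult(u, min(p, 1.0), "mann_whitney_exact", nx, ny)
    # tie-corrected normal approximation with continuity correction
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values identical
        return TestResult(u, 1.0, "mann_whitney_normal", nx, ny, degenerate=True)
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(u, min(p, 1.0), "mann_whitney_normal", nx, ny)


def t_test(x, y) -> TestResult:
    """Welch's two-sided t-test with degenerate-variance handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "t_welch", nx, ny)
        return TestResult(np.inf, 0.0, "t_welch", nx, ny, degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "t_welch", nx, ny)


def presence_chi2(presence_a, presence_b, correction: bool = False) -> TestResult:
    """2x2 Pearson chi-squared on (present, absent) counts per group.

    Yates continuity correction is off by default. A zero row or column
    marginal makes the statistic undefined; the result is then flagged
    degenerate with NaN statistic and p = 1.
    """
    table = np.array([list(presence_a), list(presence_b)], dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected two (present, absent) count pairs")
    n = int(table.sum())
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return TestResult(np.nan, 1.0, "chi2", int(table[0].sum()),
                          int(table[1].sum()), degenerate=True)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return TestResult(float(chi2), float(p), "chi2",
                      int(table[0].sum()), int(table[1].sum()))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (optional post-processor; raw p-values
    are reported by default throughout)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def compare_groups(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    condition: str,
    control: str = "control",
    method: str = "mann_whitney",
) -> pd.DataFrame:
    """Run one test per metric column comparing two conditions.

    ``values`` is samples x metrics (e.g. Shannon, or the wide CPI
    matrix); ``method`` must be given explicitly ("mann_whitney" or
    "t_test"). Returns a long-format frame: metric, statistic, pvalue,
    method, n_x, n_y, degenerate.
    """
    tests = {"mann_whitney": mann_whitney, "t_test": t_test}
    if method not in tests:
        raise ValueError(f"unknown method {method!r}")
    cond_s = [s for s in values.index if metadata.loc[s, "condition"] == condition]
    ctrl_s = [s for s in values.index if metadata.loc[s, "condition"] == control]
    rows = []
    for metric in values.columns:
        xv = values.loc[cond_s, metric].dropna()
        yv = values.loc[ctrl_s, metric].dropna()
        res = tests[method](xv, yv)
        rows.append(
            {
                "metric": metric,
                "comparison": f"{condition}_vs_{control}",
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
                "n_x": res.n_x,
                "n_y": res.n_y,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
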