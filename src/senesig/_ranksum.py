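"""Wilcoxon rank-sum machinery shared by cluster scoring and marker detection.

Two routes: a tie-corrected normal approximation (vectorized over genes,
no continuity correction, matching the convention of the common single-cell
toolkits) and exact enumeration of the permutation null over group
assignments for small groups, which is valid in the presence of ties.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

EXACT_MAX = 10  # exact enumeration when both sides have <= this many observations


def _tie_term(pooled: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tie groups, per column, without a Python loop.

    Uses the identity sum over a run of length c of 3r(r+1) (r the 0-based
    within-run index) = c^3 - c, on column-sorted values.
    """
    s = np.sort(pooled, axis=0)
    n = s.shape[0]
    rows = np.arange(n)[:, None]
    new_run = np.vstack([np.ones((1, s.shape[1]), dtype=bool), s[1:] != s[:-1]])
    start = np.where(new_run, rows, 0)
    start = np.maximum.accumulate(start, axis=0)
    r = rows - start
    return (3.0 * r * (r + 1)).sum(axis=0)


def ranksum_normal(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p for each column.

    ``x`` (n1 x G) is the focal group, ``y`` (n2 x G) the complement. When a
    column is entirely tied the statistic carries no information and p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[0], y.shape[0]
    pooled = np.vstack([x, y])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = _tie_term(pooled)
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (w - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.minimum(p, 1.0)
    p[sd == 0] = 1.0
    return p


def ranksum_exact(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumerating all group assignments (tie-safe).

    Two-sided p is P(|W - E[W]| >= |w_obs - E[W]|) under the uniform
    assignment null.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    total = 0
    hits = 0
    for combo in combinations(range(pooled.size), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if alternative == "two-sided":
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                hits += 1
        elif alternative == "greater":
            if w >= w_obs - 1e-12:
                hits += 1
        elif alternative == "less":
            if w <= w_obs + 1e-12:
                hits += 1
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return hits / total
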