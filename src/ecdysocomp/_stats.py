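"""Rank-sum machinery shared by the family-enrichment and fold-change tests.

Ties are handled with midranks throughout. For small samples
(total n <= EXACT_LIMIT) the two-sided p-value is computed by exhaustive
enumeration of group assignments, which remains correct in the presence
of ties; larger samples use the tie-corrected normal approximation with
continuity correction (the behaviour of R's ``wilcox.test``).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

EXACT_LIMIT = 12


def mann_whitney_u(x, y) -> float:
    """U statistic for sample ``x`` against ``y`` using midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact p by enumerating all C(n, n_x) group assignments.

    Defined as P(|U - n_x n_y / 2| >= |u_obs - n_x n_y / 2|) under the
    permutation null; the U distribution is symmetric about n_x n_y / 2
    even under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n_x * n_y / 2.0
    offset = n_x * (n_x + 1) / 2.0
    u_obs = ranks[:n_x].sum() - offset
    dev_obs = abs(u_obs - mu)
    n_total = 0
    n_extreme = 0
    for idx in combinations(range(len(pooled)), n_x):
        u = ranks[list(idx)].sum() - offset
        n_total += 1
        # tolerance guards float midrank sums
        if abs(u - mu) >= dev_obs - 1e-9:
            n_extreme += 1
    return n_extreme / n_total


def rank_sum_test(x, y, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """(U, two-sided p); exact enumeration for small n, normal approx otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    u = mann_whitney_u(x, y)
    if len(x) + len(y) <= exact_limit:
        return u, exact_rank_sum_p(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u, 1.0  # all values tied: no evidence either way
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)
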