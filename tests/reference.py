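"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity, not speed, and deliberately shares
no code with the package: exhaustive enumeration for the rank-sum null,
direct mass-function summation for the hypergeometric tail, the textbook
step-up formula for Benjamini-Hochberg, and a literal O(n^2) DBSCAN.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def ranksum_exact_bruteforce(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every rank split."""
    x = list(x)
    y = list(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = rankdata(pooled)
    n1, N = len(x), len(pooled)
    mu = n1 * (N + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    extreme = 0
    for subset in combinations(range(N), n1):
        if abs(ranks[list(subset)].sum() - mu) >= observed - 1e-9:
            extreme += 1
    return extreme / comb(N, n1)


def hypergeom_tail_bruteforce(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by direct summation of C(K,i) C(N-K,n-i) / C(N,n)."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += comb(K, i) * comb(N - K, n - i)
    return acc / total


def bh_stepup_closed_form(p_values) -> np.ndarray:
    """min_{j >= i} p_(j) * m / j, mapped back to input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adjusted_sorted = np.minimum.accumulate(
        (sorted_p * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted_sorted, 1.0)
    return out


def dbscan_bruteforce(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Literal DBSCAN: O(n^2) distances, seeds visited in index order.

    Border points are claimed by the first cluster whose expansion reaches
    them, matching the standard sequential algorithm.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    is_core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    cluster = -1
    for i in range(n):
        if visited[i] or not is_core[i]:
            continue
        cluster += 1
        queue = [i]
        visited[i] = True
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            if not is_core[j]:
                continue
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cluster
                if not visited[q]:
                    visited[q] = True
                    queue.append(q)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition and the same noise
    set (noise = -1 compares by identity, not as a cluster)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    keep = a != -1
    a, b = a[keep], b[keep]
    map_ab: dict[int, int] = {}
    map_ba: dict[int, int] = {}
    for la, lb in zip(a, b):
        if map_ab.setdefault(la, lb) != lb:
            return False
        if map_ba.setdefault(lb, la) != la:
            return False
    return True
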