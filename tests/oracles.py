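"""Independent brute-force reference implementations.

These deliberately use different algorithms and code paths from the package
(full pairwise distance matrices, naive substring scans, exhaustive
permutation enumeration, textbook formulas) so that agreement is evidence of
correctness, not shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """O(N^2) sample entropy via full Chebyshev distance matrices."""
    x = np.asarray(x, dtype=np.float64)
    nt = x.size - m
    tm = np.stack([x[i : i + m] for i in range(nt)])
    tm1 = np.stack([x[i : i + m + 1] for i in range(nt)])
    dm = cdist(tm, tm, "chebyshev")
    dm1 = cdist(tm1, tm1, "chebyshev")
    iu = np.triu_indices(nt, k=1)
    b = int(np.sum(dm[iu] <= r))
    a = int(np.sum(dm1[iu] <= r))
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


def fuzen_bruteforce(x: np.ndarray, m: int, r: float, p: float) -> float:
    """Fuzzy entropy via full distance matrices on mean-centred templates."""
    x = np.asarray(x, dtype=np.float64)
    nt = x.size - m

    def phi(length: int) -> float:
        t = np.stack([x[i : i + length] for i in range(nt)])
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, "chebyshev")
        iu = np.triu_indices(nt, k=1)
        return float(np.sum(np.exp(-(d[iu] ** p) / r)))

    return -math.log(phi(m + 1) / phi(m))


def lz76_bruteforce(symbols) -> int:
    """LZ76 exhaustive parse by naive substring reproducibility checks."""
    s = "".join(str(int(v)) if not isinstance(v, str) else v for v in symbols)
    n = len(s)
    c = 0
    l = 0
    while l < n:
        k = 1
        while l + k <= n and s[l : l + k] in s[: l + k - 1]:
            k += 1
        c += 1
        l += k
    return c


def ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by full enumeration of group
    assignments (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us, dtype=float)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def friedman_bruteforce(data: np.ndarray) -> float:
    """Textbook Friedman chi-square on an (n blocks x k treatments) table
    without ties: 12n/(k(k+1)) * sum R_bar_j^2 - 3n(k+1)."""
    n, k = data.shape
    ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1
    rbar = ranks.mean(axis=0)
    return float(12.0 * n / (k * (k + 1)) * np.sum(rbar**2) - 3.0 * n * (k + 1))
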