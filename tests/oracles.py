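"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the rank-sum oracle
enumerates every assignment of pooled ranks, the corruption oracle simulates
per-read Bernoulli base errors directly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def exact_u_distribution(m: int, n: int) -> dict[float, int]:
    """Null distribution of the Mann-Whitney U statistic by enumerating all
    C(m+n, m) assignments of pooled ranks to the first group."""
    all_ranks = np.arange(1, m + n + 1)
    dist: dict[float, int] = {}
    for subset in combinations(all_ranks, m):
        u = sum(subset) - m * (m + 1) / 2
        dist[u] = dist.get(u, 0) + 1
    return dist


def exact_p_two_sided(dist: dict[float, int], u_obs: float, m: int, n: int) -> float:
    """p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) under the
    enumeration null."""
    total = comb(m + n, m)
    count_le = sum(c for u, c in dist.items() if u <= u_obs)
    count_ge = sum(c for u, c in dist.items() if u >= u_obs)
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of rank assignments
    (tie-free samples only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    m, n = x.size, y.size
    ranks = rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    return exact_p_two_sided(exact_u_distribution(m, n), u_obs, m, n)


def top_k_signed_mean(values, k: int = 3) -> float:
    """Reference top-k-by-|value| collapse: brute force over all k-subsets."""
    vals = sorted(values, key=abs, reverse=True)
    chosen = vals[:k] if len(vals) >= k else vals
    return float(np.mean(chosen))


def corrupt_reads(seq: str, n_reads: int, error_rate: float, seed: int) -> list[str]:
    """Per-read, per-base Bernoulli substitution simulation."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reads):
        read = list(seq)
        for i, base in enumerate(read):
            if rng.random() < error_rate:
                read[i] = rng.choice([b for b in "ACGT" if b != base])
        out.append("".join(read))
    return out
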