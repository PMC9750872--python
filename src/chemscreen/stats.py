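"""Shared rank statistics.

Both the gene-scoring stage (sgRNAs of a gene vs non-targeting controls) and
the mutation-association stage (IC50s of mutant vs wild-type cell lines) use
the two-sided Mann-Whitney U / Wilcoxon rank-sum test. Small tie-free
problems are solved exactly by enumeration of the U distribution; everything
else uses the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest group size (both groups) for which the exact null distribution is used.
EXACT_MAX = 8


def rank_sum_p(x, y, exact_max: int = EXACT_MAX) -> float:
    """Two-sided Mann-Whitney U p-value of ``x`` vs ``y``.

    Exact when both groups have at most ``exact_max`` observations and the
    pooled sample is tie-free; otherwise normal approximation with tie and
    continuity corrections. The result is clamped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_p requires two non-empty groups")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size <= exact_max and y.size <= exact_max:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(res.pvalue)
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
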