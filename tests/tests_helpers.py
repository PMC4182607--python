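"""Shared brute-force oracles for the statistics tests."""

import itertools

import numpy as np
from scipy.stats import rankdata


def brute_wilcoxon(diffs):
    """Two-sided exact p by literal enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.asarray(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    lower = (ws <= w_obs + 1e-9).mean()
    upper = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


def brute_bh(p, m):
    """Step-up BH straight from its definition, O(n²)."""
    p = np.asarray(p, float)
    ranks = rankdata(p, method="ordinal")
    return np.array(
        [
            min(min(1.0, p[j] * m / ranks[j]) for j in range(p.size) if ranks[j] >= ranks[i])
            for i in range(p.size)
        ]
    )
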