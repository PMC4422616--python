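"""Independent brute-force oracles used only by the test suite."""

import itertools

import numpy as np
from scipy import stats


def ranksum_p_by_enumeration(x, y):
    """Two-sided Mann-Whitney p by complete enumeration of rank splits.

    Assumes no ties.  Enumerates every C(n1+n2, n1) assignment of pooled
    ranks to the first sample and counts arrangements at least as extreme
    in either tail: p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n1 + n2, "oracle requires untied data"
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            sum(comb) - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(1, n1 + n2 + 1), n1)
        ]
    )
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def flat_metric_mean(case, metric_ids, weights=None):
    """Weighted mean of a case's non-missing levels, recomputed from scratch."""
    smap = {s.metric_id: s for s in case.scores}
    num = den = 0.0
    for mid in metric_ids:
        s = smap.get(mid)
        if s is None or s.level is None:
            continue
        w = 1.0 if weights is None or s.quality is None else weights[s.quality]
        num += w * s.level
        den += w
    return None if den == 0 else num / den


def discretized_spearman_oracle(rho, cutpoints, n=10**6, seed=999):
    """Large-sample Spearman rho of a discretized bivariate normal."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    cp = np.asarray(cutpoints)
    l1 = np.searchsorted(cp, z1) + 1
    l2 = np.searchsorted(cp, z2) + 1
    return float(stats.spearmanr(l1, l2).statistic)
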