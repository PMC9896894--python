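"""Independent oracles shared by unit and acceptance tests.

These deliberately avoid the library's own code paths: the slope oracle is
a brute-force refining grid search over the slope with a profiled
intercept, and the rank-sum oracle enumerates every split of the pooled
sample.
"""

import itertools

import numpy as np
from scipy import stats as ss


def grid_search_slope(x, y, lo=-5.0, hi=5.0, rounds=8, npts=401):
    """Minimize sum((y - (c + s*x))**2) over s by refining grid search;
    the intercept c is profiled out at its conditional optimum."""
    best = None
    for _ in range(rounds):
        grid = np.linspace(lo, hi, npts)
        sse = np.array([np.sum((y - ((y - s * x).mean() + s * x)) ** 2)
                        for s in grid])
        i = int(np.argmin(sse))
        best = grid[i]
        step = grid[1] - grid[0]
        lo, hi = best - 2 * step, best + 2 * step
    return best


def rank_sum_enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration over all splits."""
    pooled = np.concatenate([x, y])
    ranks = ss.rankdata(pooled)
    n, nx = pooled.size, len(x)
    w_obs = ranks[:nx].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(n), nx)]
    lo = sum(1 for s in sums if s <= w_obs + 1e-9)
    hi = sum(1 for s in sums if s >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / len(sums))
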