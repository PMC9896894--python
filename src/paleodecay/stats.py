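"""Rank-based group contrasts and correlations for decay constants.

Group sizes in this setting are tiny (3 stations per lake, 5 lakes), so
the Wilcoxon rank-sum test is computed exactly by full enumeration of rank
assignments whenever n_x + n_y <= 12 and the pooled sample has no ties.
With ties, mid-ranks are used and the p-value comes from a seeded
label-permutation null (10,000 draws).  For larger samples a normal
approximation with tie correction and continuity correction is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12
PERMUTATION_DRAWS = 10_000


@dataclass
class PairwiseTestResult:
    """Two-sided Wilcoxon rank-sum contrast between two groups.

    ``statistic`` is the rank sum of group a in the pooled mid-ranked
    sample; the result is symmetric in (a, b) up to reflection of the
    statistic about its null mean.
    """

    label_a: str
    label_b: str
    statistic: float
    p_value: float
    significant: bool = False
    adjustment: str = "none"
    method: str = "exact"
    p_adjusted: float | None = None


def _rank_sum_exact_p(w: float, n_x: int, n_y: int) -> float:
    """Exact two-sided p for rank sum w of the first sample, no ties:
    enumerate all C(n_x+n_y, n_x) assignments of ranks to the first sample."""
    n = n_x + n_y
    sums = [sum(c) for c in combinations(range(1, n + 1), n_x)]
    total = len(sums)
    lo = sum(1 for s in sums if s <= w + 1e-9)
    hi = sum(1 for s in sums if s >= w - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(x, y, seed: int | None = None,
                      alpha: float = 0.05) -> PairwiseTestResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact enumeration for n_x + n_y <= 12 without ties; seeded permutation
    null (10,000 draws) with mid-ranks when ties are present; otherwise
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n_x, n_y, n = x.size, y.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_x].sum())
    mean_w = n_x * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_MAX_N and not has_ties:
        p = _rank_sum_exact_p(w, n_x, n_y)
        method = "exact"
    elif n <= EXACT_MAX_N:
        rng = np.random.default_rng(seed)
        obs = abs(w - mean_w)
        count = 0
        for _ in range(PERMUTATION_DRAWS):
            perm = rng.permutation(ranks)
            if abs(perm[:n_x].sum() - mean_w) >= obs - 1e-9:
                count += 1
        p = (1 + count) / (PERMUTATION_DRAWS + 1)
        method = "permutation"
    else:
        # tie-corrected variance; continuity correction of 0.5
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts))
        var_w = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_w <= 0:
            p = 1.0
        else:
            z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        method = "normal"

    return PairwiseTestResult(
        label_a="x", label_b="y", statistic=w, p_value=p,
        significant=bool(p < alpha), method=method,
    )


def pairwise_contrasts(groups: dict[str, list[float]], adjustment: str = "none",
                       seed: int | None = None,
                       alpha: float = 0.05) -> list[PairwiseTestResult]:
    """All unordered pairwise Wilcoxon contrasts between labelled groups.

    ``adjustment`` is ``"none"`` (raw p-values, the conventional
    presentation for these small panels) or ``"holm"``.  Significance is
    assessed at ``alpha`` on the adjusted p when adjustment is enabled.
    Groups with < 2 members are skipped with a warning.
    """
    if adjustment not in ("none", "holm"):
        raise ValueError("adjustment must be 'none' or 'holm'")
    usable = {}
    for label, values in groups.items():
        if len(values) < 2:
            warnings.warn(f"group {label!r} has < 2 members; skipped")
        else:
            usable[label] = values
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    results = []
    for (la, va), (lb, vb) in combinations(usable.items(), 2):
        r = wilcoxon_rank_sum(va, vb, seed=seed, alpha=alpha)
        r.label_a, r.label_b = la, lb
        r.adjustment = adjustment
        results.append(r)
    if adjustment == "holm" and results:
        reject, p_adj, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="holm")
        for r, pa, rej in zip(results, p_adj, reject):
            r.p_adjusted = float(pa)
            r.significant = bool(rej)
    return results


def pearson_correlation(x, y, log_transform: bool = True) -> tuple[float, float]:
    """Pearson correlation with two-sided t-distribution p-value.

    ``log_transform`` (default on) applies log10 to both variables first —
    appropriate when correlating gene copy numbers and biomarker contents
    that span orders of magnitude; positive values required in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired observations, n >= 3")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log transform requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
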