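"""Amplicon community-table operations.

Covers the sequence-based side of the pipeline: relative abundances of
taxa or organism groups per sample, partitioning of total gene copy
numbers (qPCR) by group-specific amplicon fractions into absolute
per-group copy estimates, Bray-Curtis dissimilarities, a permutation
ANOSIM against a sample grouping such as trophic state at deposition, and
simple taxon-fraction-versus-age regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

TROPHIC_STATES = ("oligotrophic", "mesotrophic", "eutrophic")


@dataclass
class CommunityTable:
    """Sample x taxon counts with a taxon→group map and optional totals.

    ``counts``: DataFrame indexed by sample id, columns taxon ids,
    nonnegative integers.  ``taxon_groups``: Series mapping every taxon to
    exactly one organism group.  ``sample_metadata``: DataFrame indexed by
    sample id (lake, station, depth_cm, age_y, trophic_state).
    ``total_copies``: per-sample total gene copies per g dry sediment.
    """

    counts: pd.DataFrame
    taxon_groups: pd.Series
    sample_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    total_copies: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.taxon_groups.index)
        if missing:
            raise ValueError(f"taxa without group assignment: {sorted(missing)}")

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)


def relative_abundances(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample taxon fractions; each retained row sums to 1.

    Samples with zero total counts cannot be normalized and are excluded
    with a warning.
    """
    counts = table.counts if isinstance(table, CommunityTable) else table
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} sample(s) with zero counts: "
                      f"{list(counts.index[empty])}")
        counts, totals = counts.loc[~empty], totals[~empty]
    return counts.div(totals, axis=0)


def group_fractions(table: CommunityTable) -> pd.DataFrame:
    """Relative abundances after collapsing taxa to organism groups."""
    grouped = table.counts.T.groupby(table.taxon_groups).sum().T
    return relative_abundances(grouped)


def partition_total_abundance(fractions: pd.DataFrame,
                              totals: pd.Series) -> pd.DataFrame:
    """Absolute per-group copy estimates: fraction x total gene copies.

    This is the amplicon/qPCR cross-check: multiplying group-specific
    relative abundances by the total gene copy number of each sample
    yields group copy estimates whose sum recovers the total exactly
    (fractions sum to 1 per sample).  Samples without a total are skipped
    with a warning.
    """
    if ((fractions.values < -1e-12) | (fractions.values > 1 + 1e-12)).any():
        raise ValueError("fractions must lie in [0, 1]")
    missing = fractions.index.difference(totals.index)
    if len(missing):
        warnings.warn(f"no total copies for sample(s) {list(missing)}; skipped")
    keep = fractions.index.intersection(totals.index)
    t = totals.loc[keep]
    if (t < 0).any():
        raise ValueError("total copies must be >= 0")
    return fractions.loc[keep].mul(t, axis=0)


def bray_curtis(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples, on relative abundances.

    Operating on fractions makes the matrix invariant to per-sample
    sequencing depth.  Returns a symmetric DataFrame with zero diagonal
    and values in [0, 1].
    """
    fracs = relative_abundances(table)
    if fracs.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dm = squareform(pdist(fracs.values, metric="braycurtis"))
    return pd.DataFrame(dm, index=fracs.index, columns=fracs.index)


def jaccard(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Presence/absence Jaccard dissimilarity (alternative metric)."""
    counts = table.counts if isinstance(table, CommunityTable) else table
    pa = (counts.values > 0)
    dm = squareform(pdist(pa, metric="jaccard"))
    return pd.DataFrame(dm, index=counts.index, columns=counts.index)


@dataclass
class AnosimResult:
    """ANOSIM test outcome.

    R in [-1, 1]: ~0 when within- and between-group dissimilarities are
    interchangeable, 1 when all between-group dissimilarities exceed all
    within-group ones.  p is the permutation p-value with the +1
    correction, so its resolution is 1/(n_permutations + 1) and p > 0.
    """

    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def _anosim_r(dm: np.ndarray, labels: np.ndarray) -> float:
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    d = dm[iu]
    within = labels[iu[0]] == labels[iu[1]]
    ranks = stats.rankdata(d)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def anosim(dissimilarity: pd.DataFrame | np.ndarray, grouping,
           n_permutations: int = 999, seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on a precomputed dissimilarity matrix.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (N(N-1)/4), ranks taken over the
    N(N-1)/2 sample pairs.  The p-value counts label permutations whose R
    is at least the observed: p = (1 + #{R* >= R}) / (n_permutations + 1).
    Every group must contain at least 2 samples.
    """
    dm = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(grouping)
    if dm.shape[0] != dm.shape[1] or dm.shape[0] != labels.size:
        raise ValueError("dissimilarity matrix and grouping sizes disagree")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    for g, c in zip(uniq, counts):
        if c < 2:
            raise ValueError(f"group {g!r} has only {c} sample(s); need >= 2")
    r_obs = _anosim_r(dm, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _anosim_r(dm, rng.permutation(labels)) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return AnosimResult(r_statistic=r_obs, p_value=p,
                        n_permutations=n_permutations, seed=seed)


def fraction_vs_age_regression(fractions, ages) -> tuple[float, float, float]:
    """OLS of a taxon's per-sample fraction on sediment age.

    Returns (slope, r_squared, p) with a two-sided slope t-test.  A
    constant fraction has nothing to explain and is reported as slope 0,
    R^2 = 0, p = 1; zero variance in age is an error.
    """
    f = np.asarray(fractions, dtype=float)
    t = np.asarray(ages, dtype=float)
    if f.size != t.size or f.size < 3:
        raise ValueError("need paired observations, n >= 3")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in age")
    if np.ptp(f) == 0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(t, f)
    return float(res.slope), float(res.rvalue) ** 2, float(res.pvalue)
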