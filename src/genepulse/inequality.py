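"""Inequality of publications among genes.

Gini coefficient and Lorenz curve of per-gene publication counts, pre-/post-
era splits, per-disease-class publication-rank distributions and the
Mann-Whitney rank-shift test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .histories import PublicationHistories


def gini(counts) -> float:
    """Population Gini coefficient of a vector of non-negative counts.

    G = sum_{i,j} |x_i - x_j| / (2 n^2 xbar), the mean absolute pairwise
    difference scaled by twice the mean; 0 for a perfectly even distribution
    and (n-1)/n for a single-holder one. Zero-count entries are included.
    Computed from the sorted vector in O(n log n).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("counts must be a non-empty 1-d sequence")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero vector")
    xs = np.sort(x)
    n = len(xs)
    # identity: sum_{i,j}|xi-xj| = 2 * sum_i (2i - n - 1) * x_(i), i 1-based
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


@dataclass
class LorenzCurve:
    """Cumulative share of publications versus ascending gene rank."""

    ranks: np.ndarray       # fractions of genes, (1/n, 2/n, ..., 1)
    cum_share: np.ndarray   # cumulative share of publications

    def gini_area(self) -> float:
        """Gini estimated as 1 - 2 * (trapezoid area under the curve)."""
        r = np.concatenate([[0.0], self.ranks])
        s = np.concatenate([[0.0], self.cum_share])
        return float(1.0 - 2.0 * np.trapezoid(s, r))


def lorenz(counts) -> LorenzCurve:
    """Lorenz curve of a count vector (genes sorted ascending)."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("counts must be a non-empty 1-d sequence")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0:
        raise ValueError("Lorenz curve undefined for an all-zero vector")
    xs = np.sort(x)
    n = len(xs)
    return LorenzCurve(np.arange(1, n + 1) / n, np.cumsum(xs) / xs.sum())


def era_split(
    histories: PublicationHistories, cutoff_year: int = 2005
) -> tuple[pd.Series, pd.Series]:
    """Per-gene publication totals before and from ``cutoff_year`` on.

    ``pre`` counts years strictly before the cutoff (pre-range baseline
    publications included); ``post`` counts the cutoff year and later. The
    default cutoff 2005 marks the start of the GWAS era; 2007 or 2009 are
    reasonable alternates.
    """
    lo, hi = histories.year_range
    pre = histories.baseline.copy()
    if cutoff_year > lo:
        pre = pre + histories.counts.loc[:, lo : min(cutoff_year - 1, hi)].sum(axis=1)
    if cutoff_year <= hi:
        post = histories.counts.loc[:, max(cutoff_year, lo) : hi].sum(axis=1)
    else:
        post = pd.Series(0, index=histories.genes)
    return pre, post


def publication_ranks(counts: pd.Series) -> pd.Series:
    """Ascending publication ranks: rank 1 = fewest publications.

    Ties break deterministically to the smaller gene id.
    """
    order = counts.sort_index().sort_values(kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ranks.reindex(counts.index)


def rank_distribution(counts: pd.Series, classes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Publication ranks of the genes in each disease class.

    Ranks are assigned over the full gene universe and then split by the
    ``label`` column of ``classes``; distributions are not normalised across
    classes.
    """
    ranks = publication_ranks(counts)
    out = {}
    for label, sub in classes.groupby("label"):
        out[str(label)] = np.sort(ranks.reindex(sub.index).dropna().to_numpy())
    return out


def rank_shift_test(
    pre_ranks, post_ranks, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for a shift in publication ranks.

    Typically applied to the pre- vs post-era ranks of the complex-disease
    genes, with ranks computed within the full universe first.
    """
    pre = np.asarray(pre_ranks, float)
    post = np.asarray(post_ranks, float)
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("rank-shift test needs at least 2 observations per sample")
    res = stats.mannwhitneyu(pre, post, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def era_report(
    histories: PublicationHistories,
    classes: pd.DataFrame | None = None,
    cutoff_year: int = 2005,
    test_class: str = "complex",
) -> dict:
    """Gini before/after the era cutoff plus the rank-shift test.

    Returns overall Gini, per-era Ginis, and (when classes are given) the
    Mann-Whitney statistic and p value for the shift in the test class's
    publication ranks between eras.
    """
    pre, post = era_split(histories, cutoff_year)
    out = {
        "cutoff_year": cutoff_year,
        "gini_total": gini(histories.total().to_numpy()),
        "gini_pre": gini(pre.to_numpy()) if pre.sum() > 0 else np.nan,
        "gini_post": gini(post.to_numpy()) if post.sum() > 0 else np.nan,
    }
    if classes is not None:
        genes = classes.index[classes["label"] == test_class]
        if len(genes) >= 2:
            pre_r = publication_ranks(pre).reindex(genes)
            post_r = publication_ranks(post).reindex(genes)
            u, p = rank_shift_test(pre_r, post_r)
            out["rank_shift_U"] = u
            out["rank_shift_p"] = p
            out["rank_shift_n"] = int(len(genes))
    return out
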