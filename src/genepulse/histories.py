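"""Per-gene publication histories.

The central container of the package: a genes x years matrix of annual
publication counts, together with a per-gene baseline holding publications
that predate the year range (they contribute to cumulative totals but never
to annual counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PublicationHistories:
    """Annual publication counts for a fixed gene universe.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix indexed by gene id with one column per calendar year
        (consecutive, ascending). ``counts.loc[g, y]`` is the number of
        publications on gene ``g`` in year ``y``.
    baseline : pandas.Series, optional
        Publications on each gene before the first year of ``counts``.
        Folded into cumulative totals. Defaults to all zeros.
    """

    counts: pd.DataFrame
    baseline: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        years = list(self.counts.columns)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("history years must be consecutive and ascending")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("publication counts must be non-negative")
        if self.baseline is None:
            self.baseline = pd.Series(0, index=self.counts.index, dtype=int)
        else:
            self.baseline = self.baseline.reindex(self.counts.index, fill_value=0)

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.counts.columns, dtype=int)

    @property
    def year_range(self) -> tuple[int, int]:
        y = self.years
        return int(y[0]), int(y[-1])

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.counts.index

    # -- derived quantities ------------------------------------------------

    def cumulative(self) -> pd.DataFrame:
        """Cumulative publications through each year, baseline included.

        ``cumulative().loc[g, t]`` is :math:`P_{g,t}`, the total number of
        publications on gene ``g`` in year ``t`` and all earlier years.
        """
        return self.counts.cumsum(axis=1).add(self.baseline, axis=0)

    def cumulative_at(self, year: int) -> pd.Series:
        """Cumulative publications per gene through ``year`` (inclusive).

        Years before the matrix return the baseline; years after return the
        final total.
        """
        start, end = self.year_range
        if year < start:
            return self.baseline.copy()
        year = min(year, end)
        return self.counts.loc[:, start:year].sum(axis=1) + self.baseline

    def cohort_means(self, genes=None) -> pd.Series:
        """Mean cumulative publications per year across ``genes`` (all by default).

        This is the cross-gene mean cumulative count P*_t that drives both the
        cohort term and the saturation denominator of the rate model.
        """
        cum = self.cumulative()
        if genes is not None:
            cum = cum.loc[genes]
        return cum.mean(axis=0)

    def window_sum(self, start_year: int, window: int) -> pd.Series:
        """Per-gene publication totals over ``start_year .. start_year+window-1``.

        Raises if the window extends past the data range (an incomplete
        follow-up window would silently bias excess statistics).
        """
        lo, hi = self.year_range
        end_year = start_year + window - 1
        if start_year < lo or end_year > hi:
            raise ValueError(
                f"window [{start_year}, {end_year}] outside data range [{lo}, {hi}]"
            )
        return self.counts.loc[:, start_year:end_year].sum(axis=1)

    def recent_pubs(self, year: int, window: int = 3) -> pd.Series:
        """Publications in the ``window`` calendar years strictly before ``year``."""
        lo, _ = self.year_range
        start = max(year - window, lo)
        if start > year - 1:
            return pd.Series(0, index=self.genes)
        return self.counts.loc[:, start : year - 1].sum(axis=1)

    def subset(self, genes) -> "PublicationHistories":
        return PublicationHistories(
            self.counts.loc[genes].copy(), self.baseline.loc[genes].copy()
        )

    def total(self) -> pd.Series:
        """Grand total publications per gene, baseline included."""
        return self.counts.sum(axis=1) + self.baseline

    def copy(self) -> "PublicationHistories":
        return PublicationHistories(self.counts.copy(), self.baseline.copy())


def histories_from_links(
    links: pd.DataFrame,
    gene_universe,
    year_range: tuple[int, int] = (1950, 2015),
) -> PublicationHistories:
    """Build per-gene annual histories from (gene_id, pmid, year) link rows.

    Every gene in ``gene_universe`` gets a row, all-zero if it has no links.
    Links dated before the range start are folded into the baseline; links
    after the range end are dropped.
    """
    start, end = year_range
    universe = pd.Index(sorted(gene_universe), name="gene_id")
    years = list(range(start, end + 1))
    counts = pd.DataFrame(0, index=universe, columns=years, dtype=int)
    baseline = pd.Series(0, index=universe, dtype=int)
    if len(links):
        links = links[links["gene_id"].isin(universe)]
        early = links[links["year"] < start]
        if len(early):
            baseline = baseline.add(
                early.groupby("gene_id").size(), fill_value=0
            ).astype(int)
        in_range = links[(links["year"] >= start) & (links["year"] <= end)]
        if len(in_range):
            tab = in_range.groupby(["gene_id", "year"]).size().unstack(fill_value=0)
            counts.loc[tab.index, tab.columns] += tab.astype(int)
    return PublicationHistories(counts, baseline)
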