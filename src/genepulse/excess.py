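"""Matched-control publication excess of newly GWAS-associated genes.

Each gene newly associated with complex disease is matched to the never-
associated gene with the closest cumulative publication count in the year
before association (ties resolved by walking back one year at a time; genes
still tied at the earliest year are all kept and averaged). The publication
excess is the gene's publications over the follow-up window minus the mean of
its controls', and is variance-stabilised by dividing by the square root of
the gene's recent publication count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .histories import PublicationHistories

DEFAULT_COVARIATES = ("log10_recent", "neglog10_p", "odds_ratio", "assoc_date")


@dataclass(frozen=True)
class ControlMatch:
    """Control gene(s) matched to one GWAS gene on prior publication history."""

    gwas_gene_id: int
    control_ids: tuple
    match_year: int
    resolved_depth: int


class ControlMatcher:
    """Fast repeated matching against a fixed candidate pool.

    Holds the cumulative-count matrix as a plain array so that matching many
    GWAS genes (each with its own association year) stays cheap.
    """

    def __init__(self, histories: PublicationHistories, candidates) -> None:
        self.histories = histories
        self.candidates = pd.Index(candidates)
        if len(self.candidates) == 0:
            raise ValueError("empty control candidate pool")
        cum = histories.cumulative()
        self._years = np.asarray(cum.columns, dtype=int)
        self._cum = cum.to_numpy(np.int64)
        self._row = {g: i for i, g in enumerate(cum.index)}
        self._cand_rows = np.array([self._row[c] for c in self.candidates])
        self._cand_cum = self._cum[self._cand_rows]

    def match(self, gwas_gene, t0: int) -> ControlMatch:
        """Candidate(s) with the most similar prior history (see module doc).

        Minimises |cumulative difference| at t0-1; ties re-compared at t0-2,
        t0-3, ... down to the first data year (whose cumulative includes the
        pre-range baseline); candidates still tied there are all returned.
        """
        start = int(self._years[0])
        grow = self._row[gwas_gene]
        # comparison years t0-1 .. start, clamped into the data range
        years = list(range(min(t0 - 1, int(self._years[-1])), start - 1, -1)) or [start]
        tied = np.arange(len(self.candidates))
        depth = 0
        for y in years:
            depth += 1
            j = y - start
            d = np.abs(self._cand_cum[tied, j] - self._cum[grow, j])
            tied = tied[d == d.min()]
            if len(tied) == 1:
                break
        ids = tuple(sorted(self.candidates[i] for i in tied))
        return ControlMatch(gwas_gene, ids, t0, depth)


def match_control(
    gwas_gene,
    candidates,
    histories: PublicationHistories,
    t0: int,
    matcher: ControlMatcher | None = None,
) -> ControlMatch:
    """Match a GWAS gene to the candidate(s) with the most similar history.

    Minimises the absolute difference in cumulative publications at t0-1;
    ties are re-compared at t0-2, t0-3, ... down to the first year of the
    data (whose cumulative count includes the pre-range baseline). Candidates
    still tied after the deepest comparison are all returned; downstream
    statistics average over them.
    """
    m = matcher if matcher is not None else ControlMatcher(histories, candidates)
    return m.match(gwas_gene, t0)


def publication_excess(
    histories: PublicationHistories, gene, control_ids, t0: int, window: int = 3
) -> float:
    """Gene window publications minus the mean of its controls' (raises if the
    window runs past the data range)."""
    sums = histories.window_sum(t0, window)
    return float(sums[gene] - sums[list(control_ids)].mean())


def normalize_excess(raw_excess: float, recent_pubs: int) -> float:
    """Variance-stabilised excess: raw / sqrt(recent publications, floored at 1)."""
    if recent_pubs < 0:
        raise ValueError("recent_pubs must be >= 0")
    return float(raw_excess) / np.sqrt(max(recent_pubs, 1))


def apply_robustness_filters(
    records: pd.DataFrame, p_max: float | None = None, or_ci_min: float | None = None
) -> pd.DataFrame:
    """Restrict to high-confidence associations.

    ``p_max`` keeps records whose first-association p value is below it
    (e.g. 1e-8); ``or_ci_min`` keeps records whose odds-ratio CI lower bound
    exceeds it (e.g. 1.1). Both default to off (identity).
    """
    out = records
    if p_max is not None:
        out = out[out["p_value"] < p_max]
    if or_ci_min is not None:
        out = out[out["or_ci_lower"] > or_ci_min]
    return out.reset_index(drop=True)


def excess_location_test(norm_excesses) -> tuple[float, float, float]:
    """Two-sided one-sample t test of the normalised excess against 0.

    Returns (t, p, sample mean).
    """
    x = np.asarray(norm_excesses, float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("location test needs at least 2 observations")
    if np.var(x) == 0:
        raise ValueError("location test degenerate: zero variance sample")
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue), float(x.mean())


def predictor_correlations(
    records: pd.DataFrame,
    predictors=("neglog10_p", "odds_ratio", "assoc_date", "log10_recent"),
) -> pd.DataFrame:
    """Spearman rank correlation of each predictor with the normalised excess.

    Complete cases per predictor; tie-corrected p values.
    """
    rows = []
    for pred in predictors:
        sub = records[[pred, "norm_excess"]].dropna()
        if len(sub) < 3:
            raise ValueError(f"predictor {pred}: fewer than 3 complete cases")
        rho, p = stats.spearmanr(sub[pred], sub["norm_excess"])
        rows.append({"predictor": pred, "rho": float(rho), "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows).set_index("predictor")


def fit_excess_regression(
    records: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """OLS of the normalised excess on the chosen predictors.

    Complete-case rows only. Categorical covariates (e.g. ``trait_class``)
    are dummy-coded. Returns a coefficient table (coef, std err, p, n);
    a rank-deficient design raises an error naming the collinear columns.
    """
    import statsmodels.api as sm

    cols = list(covariates)
    sub = records[cols + ["norm_excess"]].dropna()
    X = pd.DataFrame(index=sub.index)
    for c in cols:
        if sub[c].dtype == object or isinstance(sub[c].dtype, pd.CategoricalDtype):
            X = X.join(pd.get_dummies(sub[c], prefix=c, drop_first=True).astype(float))
        else:
            X[c] = sub[c].astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = [
            c for c in X.columns
            if c != "const" and X[c].nunique() <= 1
        ]
        # fall back: report columns whose removal restores full rank
        if not bad:
            for c in X.columns:
                if c == "const":
                    continue
                if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                    bad.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(sub["norm_excess"].astype(float), X).fit()
    out = pd.DataFrame({"coef": fit.params, "std_err": fit.bse, "p_value": fit.pvalues})
    out.attrs["n"] = int(fit.nobs)
    out.attrs["r_squared"] = float(fit.rsquared)
    return out


def total_excess_timeseries(records: pd.DataFrame, bin_months: int = 6) -> pd.DataFrame:
    """Raw publication excess summed within calendar bins of association date.

    Bins are ``bin_months`` wide starting at January of the earliest year;
    empty bins between the first and last association are reported as 0.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["bin_start", "total_raw_excess", "n"])
    frac = bin_months / 12.0
    dates = records["assoc_date"].astype(float)
    bins = np.floor(dates / frac) * frac
    grouped = records.groupby(bins)["raw_excess"].agg(["sum", "size"])
    full = np.round(np.arange(bins.min(), bins.max() + frac / 2, frac), 6)
    grouped = grouped.reindex(full, fill_value=0)
    return pd.DataFrame(
        {
            "bin_start": grouped.index.to_numpy(float),
            "total_raw_excess": grouped["sum"].to_numpy(float),
            "n": grouped["size"].to_numpy(int),
        }
    )


class MatchedExcessModel:
    """Matched-control publication-excess analysis over a gene universe.

    Parameters
    ----------
    histories : PublicationHistories
        Annual counts for all genes.
    classes : pandas.DataFrame
        Per-gene disease classification (indexed by gene id) with columns
        ``first_gwas_year`` (NaN for genes never GWAS-associated) and,
        optionally, ``first_assoc_p`` / ``first_assoc_or`` /
        ``first_assoc_or_ci`` / ``first_assoc_date`` / ``trait_class``.
    window : int
        Follow-up window in years starting at the association year (3 by
        default; 5 for the robustness variant).
    recent_window : int
        Years strictly before the association year that define "recent"
        publications (the variance-stabilising denominator and a predictor).
    p_max, or_ci_min : float, optional
        Robustness filters on the first association; off by default.
    """

    def __init__(
        self,
        histories: PublicationHistories,
        classes: pd.DataFrame,
        window: int = 3,
        recent_window: int = 3,
        p_max: float | None = None,
        or_ci_min: float | None = None,
    ) -> None:
        self.histories = histories
        self.classes = classes
        self.window = int(window)
        self.recent_window = int(recent_window)
        self.p_max = p_max
        self.or_ci_min = or_ci_min
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def fit(self) -> "MatchedExcessResults":
        """Match controls and compute raw/normalised excesses for every
        eligible GWAS gene (association year early enough for a complete
        follow-up window)."""
        h = self.histories
        lo, hi = h.year_range
        cls = self.classes
        gwas = cls[cls["first_gwas_year"].notna()]
        candidates = cls.index[cls["first_gwas_year"].isna()]
        if len(candidates) == 0:
            raise ValueError("no non-GWAS genes available as controls")
        matcher = ControlMatcher(h, candidates)
        counts = h.counts
        row_of = {g: i for i, g in enumerate(counts.index)}
        cmat = counts.to_numpy(np.int64)
        years = np.asarray(counts.columns, dtype=int)

        def _span_sum(gene, y0, y1):  # inclusive year span, clipped to range
            j0, j1 = max(y0 - years[0], 0), min(y1 - years[0], len(years) - 1)
            if j0 > j1:
                return 0
            return int(cmat[row_of[gene], j0 : j1 + 1].sum())

        rows = []
        n_window_excluded = 0
        for gene, info in gwas.iterrows():
            t0 = int(info["first_gwas_year"])
            if t0 < lo or t0 + self.window - 1 > hi:
                n_window_excluded += 1
                continue
            m = matcher.match(gene, t0)
            gene_sum = _span_sum(gene, t0, t0 + self.window - 1)
            ctrl_sum = np.mean(
                [_span_sum(c, t0, t0 + self.window - 1) for c in m.control_ids]
            )
            raw = float(gene_sum - ctrl_sum)
            recent = _span_sum(gene, t0 - self.recent_window, t0 - 1)
            p = info.get("first_assoc_p", np.nan)
            rows.append(
                {
                    "gene_id": gene,
                    "t0": t0,
                    "window": self.window,
                    "control_ids": ",".join(str(c) for c in m.control_ids),
                    "n_controls": len(m.control_ids),
                    "resolved_depth": m.resolved_depth,
                    "raw_excess": raw,
                    "recent_pubs": recent,
                    "norm_excess": normalize_excess(raw, recent),
                    "log10_recent": float(np.log10(max(recent, 1))),
                    "p_value": p,
                    "neglog10_p": -np.log10(p) if pd.notna(p) and p > 0 else np.nan,
                    "odds_ratio": info.get("first_assoc_or", np.nan),
                    "or_ci_lower": info.get("first_assoc_or_ci", np.nan),
                    "assoc_date": info.get("first_assoc_date", t0 + 0.5),
                    "trait_class": info.get("trait_class", None),
                }
            )
        records = pd.DataFrame(rows)
        records = apply_robustness_filters(records, self.p_max, self.or_ci_min)
        return MatchedExcessResults(self, records, n_window_excluded)


@dataclass
class MatchedExcessResults:
    """Excess records plus the tests and models built on them."""

    model: MatchedExcessModel
    records: pd.DataFrame
    n_window_excluded: int = 0

    def location_test(self) -> tuple[float, float, float]:
        """One-sample t test of the mean normalised excess against zero."""
        return excess_location_test(self.records["norm_excess"])

    def correlations(self, predictors=("neglog10_p", "odds_ratio", "assoc_date", "log10_recent")) -> pd.DataFrame:
        return predictor_correlations(self.records, predictors)

    def regression(self, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
        return fit_excess_regression(self.records, covariates)

    def timeseries(self, bin_months: int = 6) -> pd.DataFrame:
        return total_excess_timeseries(self.records, bin_months)

    def summary(self) -> str:
        n = len(self.records)
        lines = [
            "Matched-control publication excess",
            "=" * 50,
            f"GWAS genes analysed: {n} (window {self.model.window} y; "
            f"{self.n_window_excluded} excluded for incomplete windows)",
        ]
        if n >= 2 and self.records["norm_excess"].var() > 0:
            t, p, mean = self.location_test()
            lines.append(
                f"mean raw excess: {self.records['raw_excess'].mean():.3f} publications"
            )
            lines.append(
                f"mean normalised excess: {mean:.3f}  (one-sample t = {t:.2f}, p = {p:.3g})"
            )
        return "\n".join(lines)
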