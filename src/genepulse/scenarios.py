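"""Frozen simulation study designs used for validation and benchmarking.

Each function wires the generator, the analysis models and a measurement into
one named scenario with fixed study conditions (sample sizes, effect sizes,
eras), so the same designs are exercised by the test suite, the acceptance
script and ad-hoc exploration. Only the random seed is meant to vary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .excess import MatchedExcessModel, MatchedExcessResults
from .ratemodel import (
    HUMAN_ML_PARAMS,
    PublicationRateModel,
    RateModelParams,
    hot_logistic,
)
from .simulate import (
    GwasShock,
    SimulationConfig,
    classes_from_shocks,
    generate_association_table,
    inject_gwas_shocks,
    sample_shocks,
    simulate_histories,
)


def recovery_trial(
    seed: int,
    n_genes: int = 5000,
    year_range: tuple[int, int] = (1950, 2015),
    params: RateModelParams = HUMAN_ML_PARAMS,
    starts: int = 5,
) -> RateModelParams:
    """Simulate histories from ``params`` and refit the rate model.

    The canonical parameter-recovery design: the pure model (heterogeneity 0)
    at the published parameter values, full 1950-2015 span, multi-start ML
    refit. Returns the fitted parameters.
    """
    cfg = SimulationConfig(
        n_genes=n_genes, year_range=year_range, params=params,
        heterogeneity_sd=0.0, seed=seed,
    )
    h = simulate_histories(cfg)
    model = PublicationRateModel(h, fit_years=year_range)
    return model.fit(starts=starts, seed=seed).params


def null_scan_fwer(
    n_reps: int = 200,
    n_genes: int = 1000,
    n_years: int = 30,
    params: RateModelParams = HUMAN_ML_PARAMS,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the Bonferroni hot-gene scan under the null.

    Simulates ``n_reps`` independent datasets from the rate model, scans each
    against the exact model means used to generate it, and returns the
    fraction of datasets with at least one flagged gene-year.
    """
    from .ratemodel import PublicationRateResults

    year_range = (1950, 1950 + n_years - 1)
    n_any = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_genes=n_genes, year_range=year_range, params=params, seed=seed + r
        )
        h = simulate_histories(cfg)
        model = PublicationRateModel(h, fit_years=year_range)
        res = PublicationRateResults(
            model=model, params=params, llf=model.loglike(params),
            converged=True, n_starts=0,
        )
        scan = res.hot_gene_scan(h, alpha=alpha)
        n_any += scan.any_significant
    return n_any / n_reps


def null_excess_records(
    seed: int,
    n_genes: int = 4000,
    n_gwas: int = 1000,
    t0_range: tuple[int, int] = (2005, 2012),
    year_range: tuple[int, int] = (1950, 2015),
    window: int = 3,
) -> pd.DataFrame:
    """Matched-excess records under the null: genes labelled as GWAS hits at
    random with zero injected boost, so any excess is noise.

    Used for calibration checks: the mean normalised excess should be near 0
    and the raw-excess variance should grow with recent publications.
    """
    cfg = SimulationConfig(n_genes=n_genes, year_range=year_range, seed=seed)
    h = simulate_histories(cfg)
    rng = np.random.default_rng(seed + 10_000)
    genes = rng.choice(h.genes, n_gwas, replace=False)
    shocks = [
        GwasShock(int(g), int(rng.integers(t0_range[0], t0_range[1] + 1)), boost=0.0)
        for g in genes
    ]
    classes = classes_from_shocks(h, shocks)
    return MatchedExcessModel(h, classes, window=window).fit().records


def decile_variances(records: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Raw and normalised excess variance within recent-publication deciles."""
    bins = pd.qcut(records["recent_pubs"].rank(method="first"), n_bins, labels=False)
    return records.groupby(bins).agg(
        recent=("recent_pubs", "mean"),
        var_raw=("raw_excess", "var"),
        var_norm=("norm_excess", "var"),
    )


def declining_boost_excess(
    seed: int,
    n_genes: int = 2000,
    n_gwas: int = 200,
    t0_range: tuple[int, int] = (1995, 2012),
    boost_start: float = 12.0,
    boost_end: float = 0.5,
    heterogeneity_sd: float = 0.5,
    year_range: tuple[int, int] = (1950, 2015),
) -> MatchedExcessResults:
    """GWAS shocks whose publication boost declines linearly with the
    association year — the waning-follow-up effect. The fitted excess
    regression should recover a negative association-date coefficient."""
    cfg = SimulationConfig(
        n_genes=n_genes, year_range=year_range,
        heterogeneity_sd=heterogeneity_sd, seed=seed,
    )
    h = simulate_histories(cfg)
    shocks = sample_shocks(
        h.genes, n_gwas, t0_range, boost_start=boost_start, boost_end=boost_end,
        window=3, seed=seed + 20_000,
    )
    h = inject_gwas_shocks(h, shocks, seed=seed + 30_000)
    assoc = generate_association_table(shocks, seed=seed + 40_000)
    classes = classes_from_shocks(h, shocks, assoc)
    return MatchedExcessModel(h, classes).fit()


def declining_hot_panel(
    seed: int,
    n_genes: int = 2000,
    n_gwas: int = 300,
    n_background: int = 150,
    t0_range: tuple[int, int] = (1996, 2013),
    boost_start: float = 20.0,
    boost_end: float = 0.5,
    background_boost: float = 15.0,
    scan_years: tuple[int, int] = (1990, 2015),
    heterogeneity_sd: float = 0.6,
) -> pd.DataFrame:
    """Gene-year panel for the hot-gene logistic under a declining GWAS effect.

    GWAS shocks fade with association year while background publication
    bursts (the non-GWAS discoveries that dominate real hot-gene counts) hit
    a disjoint set of genes at a constant rate, so the scan flags hot
    gene-years in both groups. The fitted logistic should recover a negative
    year x recent-GWAS interaction.
    """
    cfg = SimulationConfig(
        n_genes=n_genes, year_range=(1950, 2015),
        heterogeneity_sd=heterogeneity_sd, seed=seed,
    )
    h = simulate_histories(cfg)
    rng = np.random.default_rng(seed + 50_000)
    gwas_shocks = sample_shocks(
        h.genes, n_gwas, t0_range, boost_start=boost_start, boost_end=boost_end,
        window=3, seed=seed + 60_000,
    )
    gwas_genes = {s.gene_id for s in gwas_shocks}
    pool = np.array([g for g in h.genes if g not in gwas_genes])
    bg_genes = rng.choice(pool, n_background, replace=False)
    background = [
        GwasShock(int(g), int(rng.integers(scan_years[0], scan_years[1] + 1)),
                  boost=background_boost, window=2)
        for g in bg_genes
    ]
    h = inject_gwas_shocks(h, gwas_shocks + background, seed=seed + 70_000)
    classes = classes_from_shocks(h, gwas_shocks)
    non_gwas = classes.index[classes["first_gwas_year"].isna()]
    fit = PublicationRateModel(h, fit_genes=non_gwas).fit(starts=3, seed=seed)
    scan = fit.hot_gene_scan(
        h, first_gwas_year=classes["first_gwas_year"], years=scan_years
    )
    return scan.panel()


def declining_hot_interaction(seed: int, **kwargs) -> float:
    """Fitted year x recent-GWAS interaction coefficient for one panel."""
    panel = declining_hot_panel(seed, **kwargs)
    return float(hot_logistic(panel).loc["year_x_recent_gwas", "coef"])
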