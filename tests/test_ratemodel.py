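import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from genepulse.histories import PublicationHistories
from genepulse.ratemodel import (
    HUMAN_ML_PARAMS,
    PublicationRateModel,
    PublicationRateResults,
    RateModelParams,
    SeparationError,
    fit_ml,
    hot_logistic,
    log_likelihood,
    poisson_tail,
    predict_rate,
)
from genepulse.simulate import SimulationConfig, simulate_histories


class TestPredictRate:
    def test_basal_rate_at_zero_state(self):
        # with no publications anywhere the rate is the basal discovery rate
        assert predict_rate(HUMAN_ML_PARAMS, 0.0, 0.0) == pytest.approx(0.00288)

    def test_denominator_two_at_saturation_scale(self):
        for alpha in (0.5, 1.67, 4.0):
            p = RateModelParams(0.02, 0.2, 0.003, 24.1, alpha)
            expected = (0.02 * 24.1 + 0.2 * 5 + 0.003) / 2.0
            assert predict_rate(p, 24.1, 5.0) == pytest.approx(expected)

    def test_direct_evaluation(self):
        # P* = P_S so the saturation denominator is exactly 2
        val = predict_rate(HUMAN_ML_PARAMS, 24.1, 10.0)
        assert val == pytest.approx((0.0214 * 24.1 + 0.225 * 10 + 0.00288) / 2.0)

    def test_limit_small_cohort_mean(self):
        v = predict_rate(HUMAN_ML_PARAMS, 1e-12, 7.0)
        assert v == pytest.approx(0.225 * 7 + 0.00288, rel=1e-6)

    def test_monotone_in_gene_history(self):
        p_i = np.linspace(0, 100, 50)
        vals = predict_rate(HUMAN_ML_PARAMS, 30.0, p_i)
        assert (np.diff(vals) >= 0).all()

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_rate(HUMAN_ML_PARAMS, -1.0, 0.0)


class TestPoissonTail:
    def test_zero_observed_is_one(self):
        assert poisson_tail(0, 5.0) == 1.0

    def test_small_example_closed_form(self):
        # P(X >= 5) for X ~ Poisson(2) = 1 - 7 e^-2
        assert poisson_tail(5, 2.0) == pytest.approx(1 - 7 * math.exp(-2), rel=1e-12)

    def test_deep_tail_no_underflow(self):
        p = poisson_tail(40, 2.0)
        assert 0 < p < 1e-30

    def test_matches_pmf_summation(self):
        """Partial pmf-sum oracle over a grid of means and counts."""
        for mean in (0.1, 1.0, 2.0, 7.5, 30.0):
            for obs in (0, 1, 3, 10, 40, 100):
                # sum P(X = k) for k = 0..obs-1 with exact-ish fsum, complement
                terms = [math.exp(-mean) * mean**k / math.factorial(k) for k in range(obs)]
                expected = 1.0 - math.fsum(terms)
                assert poisson_tail(obs, mean) == pytest.approx(expected, abs=1e-12)


class TestLogLikelihood:
    def test_single_cell_unit_mean(self):
        h = PublicationHistories(
            pd.DataFrame({2000: [0], 2001: [1]},
                         index=pd.Index([1], name="gene_id"))
        )
        # force mu = 1 for the 2001 cell: P_i = 0, P* = 0 -> mu = k3
        params = RateModelParams(1e-9, 1e-9, 1.0, 10.0, 1.0)
        model = PublicationRateModel(h, fit_years=(2001, 2001))
        assert model.loglike(params) == pytest.approx(-1.0)

    def test_matches_term_by_term_sum(self, rng):
        n, ny = 20, 12
        counts = rng.poisson(1.0, size=(n, ny))
        h = PublicationHistories(
            pd.DataFrame(counts, index=pd.Index(range(1, n + 1), name="gene_id"),
                         columns=list(range(2000, 2000 + ny)))
        )
        params = RateModelParams(0.05, 0.3, 0.1, 8.0, 1.5)
        cum = h.cumulative()
        expected = 0.0
        pstar = cum.mean(axis=0)
        for g in h.genes:
            for j, y in enumerate(range(2000, 2000 + ny)):
                p_prev = cum.at[g, y - 1] if y > 2000 else 0
                s_prev = pstar[y - 1] if y > 2000 else 0.0
                mu = predict_rate(params, s_prev, p_prev)
                expected += stats.poisson.logpmf(counts[g - 1, j], mu)
        got = log_likelihood(params, h, fit_years=(2000, 2011))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_all_zero_counts_limit(self):
        h = PublicationHistories(
            pd.DataFrame(0, index=pd.Index([1, 2], name="gene_id"),
                         columns=[2000, 2001], dtype=int)
        )
        ll = log_likelihood(RateModelParams(1e-9, 1e-9, 1e-9, 10, 1), h,
                            fit_years=(2000, 2001))
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_analytic_gradient_matches_numeric(self, simulated_histories):
        model = PublicationRateModel(simulated_histories)
        x0 = np.log(HUMAN_ML_PARAMS.as_array() * 1.4)
        f = lambda x: model._negll_and_grad(x)[0]
        g = lambda x: model._negll_and_grad(x)[1]
        err = optimize.check_grad(f, g, x0, epsilon=1e-6)
        assert err / np.linalg.norm(g(x0)) < 1e-4


class TestFit:
    def test_fitted_likelihood_dominates_truth(self, simulated_histories):
        model = PublicationRateModel(simulated_histories)
        res = model.fit(starts=3, seed=0)
        assert res.llf >= model.loglike(HUMAN_ML_PARAMS) - 1e-6

    def test_null_component_recovered(self):
        """Data simulated with k2 = 0 refit with a near-zero k2."""
        params = RateModelParams(0.05, 1e-6, 0.05, 30.0, 2.0)
        cfg = SimulationConfig(n_genes=1500, year_range=(1950, 2015),
                               params=params, seed=17)
        h = simulate_histories(cfg)
        res = fit_ml(h, fit_years=(1950, 2015), starts=3, seed=1)
        assert res.params.k2 < 0.01

    def test_all_zero_histories_flagged(self):
        h = PublicationHistories(
            pd.DataFrame(0, index=pd.Index(range(1, 20), name="gene_id"),
                         columns=list(range(2000, 2010)), dtype=int)
        )
        res = fit_ml(h, fit_years=(2000, 2009), starts=2, seed=0)
        assert res.params.k3 <= 1e-5
        assert any("unidentifiable" in n for n in res.notes)

    def test_too_small_fit_is_error(self):
        h = PublicationHistories(
            pd.DataFrame({2000: [1]}, index=pd.Index([1], name="gene_id"))
        )
        with pytest.raises(ValueError):
            fit_ml(h, fit_years=(2000, 2000))


class TestHotGeneScan:
    def test_bonferroni_cutoff_arithmetic(self, simulated_histories):
        model = PublicationRateModel(simulated_histories)
        res = PublicationRateResults(model=model, params=HUMAN_ML_PARAMS,
                                     llf=0.0, converged=True, n_starts=0)
        scan = res.hot_gene_scan(n_genes=20_442, n_years=67)
        assert scan.cutoff == pytest.approx(0.05 / (20_442 * 67))
        assert scan.cutoff == pytest.approx(3.65e-8, rel=2e-3)

    def test_sustained_boost_flagged_every_window_year(self):
        """A 10x publication burst on a moderately studied gene is called hot
        in all three burst years (the complement-factor-H-like pattern)."""
        cfg = SimulationConfig(n_genes=400, year_range=(1950, 2015), seed=31)
        h = simulate_histories(cfg)
        rates = h.counts.loc[:, 2000:2004].mean(axis=1)
        gene = (rates - 3.0).abs().idxmin()  # a roughly 3-publication/year gene
        boost = 10 * max(rates[gene], 1.0)
        from genepulse.simulate import GwasShock, inject_gwas_shocks

        h2 = inject_gwas_shocks(h, [GwasShock(int(gene), 2005, float(boost))], seed=32)
        model = PublicationRateModel(h2, fit_genes=[g for g in h2.genes if g != gene])
        fit = model.fit(starts=3, seed=0)
        scan = fit.hot_gene_scan(h2)
        calls = scan.calls
        flagged = set(calls.loc[calls["gene_id"] == gene, "year"])
        assert {2005, 2006, 2007} <= flagged

    def test_annual_summary_counts(self, simulated_histories):
        model = PublicationRateModel(simulated_histories)
        res = PublicationRateResults(model=model, params=HUMAN_ML_PARAMS,
                                     llf=0.0, converged=True, n_starts=0)
        first = pd.Series(np.nan, index=simulated_histories.genes)
        first.iloc[0] = 2005.0
        scan = res.hot_gene_scan(first_gwas_year=first)
        ann = scan.annual_summary()
        assert ann.loc[ann["year"] == 2005, "n_new_gwas_genes"].item() == 1
        assert (ann["n_hot_recent_gwas"] <= ann["n_hot"]).all()


class TestHotLogistic:
    def _panel(self, rng, beta_inter=-0.5, n_genes=400, n_years=16):
        genes = np.repeat(np.arange(n_genes), n_years)
        year = np.tile(np.arange(n_years, dtype=float), n_genes)
        recent_gwas = (rng.random(genes.size) < 0.15).astype(int)
        log10_recent = rng.uniform(0, 2, genes.size)
        lin = -5 + 1.5 * log10_recent + 0.05 * year + 2.0 * recent_gwas \
            + beta_inter * year * recent_gwas
        hot = rng.random(genes.size) < 1 / (1 + np.exp(-lin))
        return pd.DataFrame(
            {"gene_id": genes, "year": year + 2000, "hot": hot.astype(int),
             "log10_recent": log10_recent, "year_offset": year,
             "recent_gwas": recent_gwas,
             "year_x_recent_gwas": year * recent_gwas}
        )

    def test_recovers_negative_interaction(self, rng):
        tab = hot_logistic(self._panel(rng))
        assert tab.loc["year_x_recent_gwas", "coef"] < 0
        assert tab.loc["year_x_recent_gwas", "p_value"] < 0.05

    def test_constant_outcome_is_separation_error(self, rng):
        panel = self._panel(rng)
        panel["hot"] = 1
        with pytest.raises(SeparationError):
            hot_logistic(panel)

    def test_separated_outcome_raises_and_ridge_recovers(self, rng):
        panel = self._panel(rng)
        panel["hot"] = (panel["recent_gwas"] == 1).astype(int)
        with pytest.raises(SeparationError):
            hot_logistic(panel)
        ridge = hot_logistic(panel, ridge=1.0)
        assert ridge.loc["recent_gwas", "coef"] > 0
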