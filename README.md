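# genepulse

**Publication dynamics of disease genes: inequality, matched-control excess,
and hot-gene detection.**

Biomedical research effort is spread very unevenly across the ~20,000 human
protein-coding genes: a handful of genes draw thousands of publications each
while thousands of genes draw almost none. Genome-wide association studies
(GWAS) link genetic variants — and through them, genes — to complex disease
largely independently of prior annotation, so each new association is a
natural experiment: does being newly implicated in disease actually pull
research attention toward a gene, and has that pull changed over time?

`genepulse` is a toolkit for answering such questions from three standard
tabular inputs (NCBI gene2pubmed-style gene→publication links, an OMIM
genemap-style gene–trait table, and a GWAS-catalog-style association table).
It provides:

* **Inequality analysis** — Gini coefficients and Lorenz curves of per-gene
  publication counts, pre/post-era splits, publication-rank distributions by
  disease class, and a Mann-Whitney rank-shift test.
* **Matched-control publication excess** — every newly associated gene is
  paired with the never-associated gene whose cumulative publication count in
  the year before association is closest (ties resolved by walking back one
  year at a time to the start of the data; genes still tied are averaged).
  The excess of the gene's publications over its control's across the 3-year
  follow-up window is variance-stabilised by `sqrt(recent publications)` and
  modelled against its predictors (association p value, odds ratio,
  association date, prior study intensity) by rank correlation and OLS.
* **A saturating Poisson publication-rate model** (Pfeiffer–Hoffmann) —
  the expected number of publications on gene *i* in year *t+1* is

  ```
  ΔP_{i,t+1} = (k1·P*_t + k2·P_{i,t} + k3) / (1 + (P*_t / P_S)^α)
  ```

  where `P_{i,t}` is the gene's cumulative publication count, `P*_t` the mean
  cumulative count over all genes, `k1` a cohort-growth coupling, `k2` the
  rich-get-richer coefficient, `k3` a basal discovery rate, and `P_S`, `α`
  set the scale and sharpness of corpus-wide saturation. Annual counts are
  Poisson with this mean; the five parameters are fitted by multi-start
  bounded maximum likelihood with analytic gradients. Gene-years whose
  observed counts have a Bonferroni-significant one-sided Poisson tail
  probability (`p < 0.05 / (N_genes · N_years)`) under the fitted model are
  flagged as **hot** — years of exceptional publication activity — and a
  logistic regression relates hotness to recent study intensity, calendar
  year, recent GWAS association and their interaction.
* **A synthetic-data generator** that simulates publication histories from
  the rate model (self-consistently, with optional per-gene heterogeneity),
  injects GWAS "shocks" with configurable boosts, and writes a complete
  mutually consistent input bundle, so the entire pipeline runs and is tested
  without any database download.

## Worked example

Simulate a 2,000-gene corpus (1950–2015) with 200 GWAS associations whose
publication boost declines from 12 to 0.5 extra publications/year over
1995–2012, run every stage, and render the summary:

```yaml
# run.yaml
simulation: {n_genes: 2000, year_range: [1950, 2015], heterogeneity_sd: 0.5}
shocks: {n: 200, t0_range: [1995, 2012], boost_start: 12, boost_end: 0.5}
era_cutoff: 2005
seed: 1
out_dir: demo_run
```

```bash
genepulse run --config run.yaml
genepulse report demo_run
```

prints (abridged):

```
## Publication inequality
- Gini (all years): 0.978
- Gini pre-2005: 0.979; post: 0.984

## Matched-control publication excess
- records: 200
- mean raw excess: 19.893 publications
- mean normalised excess: 19.037 (t = 22.95, p = 8.04e-58)

| predictor | coef | std err | p |
|---|---|---|---|
| log10_recent | -16.673 | 2.309 | 1.13e-11 |
| neglog10_p | -0.039 | 0.046 | 0.404 |
| odds_ratio | -0.705 | 1.305 | 0.589 |
| assoc_date | -2.000 | 0.063 | 1.45e-78 |

## Rate model and hot gene-years
- fitted parameters: P_S=25.42, alpha=1.673, k1=0.007639, k2=0.8806, k3=0.006541
- hot gene-years: 326 (cutoff 3.79e-07)
- hot-gene logistic (coef): ..., year_x_recent_gwas=-0.374
```

Reading it: publications are highly unequal (Gini ≈ 0.98 — the
rich-get-richer term concentrates attention even with identical parameters
for all genes); the injected association effect is detected (mean excess ≈ 20
publications, t-test p ≈ 1e-57); the regression recovers the built-in decline
of the effect with association date (negative `assoc_date` coefficient); and
the hot-gene logistic recovers the negative year × recent-GWAS interaction.

The same stages run on real inputs via
`genepulse ingest --gene2pubmed ... --years ... --omim ... --gwas ...
--efo-terms ... --genes ... --out DIR` followed by `genepulse inequality`,
`genepulse excess` and `genepulse ratemodel fit/scan`, or in one shot with a
`run.yaml` whose `inputs:` block replaces `simulation:`.

As a library, the two central objects are statsmodels-style model/results
pairs:

```python
from genepulse import PublicationRateModel, MatchedExcessModel

fit = PublicationRateModel(histories, fit_genes=never_gwas).fit(seed=0)
print(fit.summary())                      # five ML parameters + loglik
scan = fit.hot_gene_scan(histories, first_gwas_year=classes["first_gwas_year"])

res = MatchedExcessModel(histories, classes, window=3).fit()
t, p, mean = res.location_test()
table = res.regression()                  # coef / std err / p per predictor
```

## Limitations

The analyses quantify publication patterns only: they do not identify why
follow-up research rises or falls, and variant→gene assignment by nearest
gene within 500 kb (the default) can mis-attribute regulatory variants.
Headline statistics from real 2017–2018 database snapshots (e.g. Gini values
near 0.73, class counts) require those external downloads; the test suite
validates the machinery on synthetic data instead. See `docs/methods.md` for
the model, its assumptions and the simulation designs.
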