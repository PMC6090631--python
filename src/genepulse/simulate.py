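"""Synthetic publication histories, disease labels and association tables.

Everything downstream of ingestion can be exercised without any database
download: histories are simulated from the saturating Poisson rate model
(self-consistently — the cohort mean each year is computed from the realized
simulated counts, exactly as fitting consumes data), GWAS association events
are injected as additive Poisson boosts over a follow-up window, and the
whole bundle can be written out in the ingestion dialects and read back
losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .histories import PublicationHistories
from .ratemodel import HUMAN_ML_PARAMS, RateModelParams, predict_rate


@dataclass
class SimulationConfig:
    """Configuration of a publication-history simulation.

    ``heterogeneity_sd`` is the log-scale standard deviation of a per-gene
    log-normal multiplier on the model mean (mean-1 parameterisation); 0
    reproduces the pure model, in which all genes share identical parameters.
    """

    n_genes: int = 1000
    year_range: tuple[int, int] = (1950, 2015)
    params: RateModelParams = field(default_factory=lambda: HUMAN_ML_PARAMS)
    heterogeneity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.year_range[0] >= self.year_range[1]:
            raise ValueError("year_range start must precede end")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if isinstance(self.params, dict):
            self.params = RateModelParams.from_dict(self.params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["year_range"] = tuple(d["year_range"])
        return cls(**d)


@dataclass
class GwasShock:
    """An injected GWAS association event for one gene.

    ``boost`` is added to the Poisson mean of the gene's publications in each
    of the ``window`` years starting at the association year ``t0``.
    """

    gene_id: int
    t0: int
    boost: float
    window: int = 3
    p_value: float | None = None
    odds_ratio: float | None = None
    trait_class: str = "disease"
    month: int = 7

    def __post_init__(self) -> None:
        if self.boost < 0:
            raise ValueError("boost must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")


def simulate_histories(cfg: SimulationConfig) -> PublicationHistories:
    """Draw annual per-gene counts from the saturating Poisson rate model.

    Year by year, the expected count of each gene is the model rate evaluated
    at the gene's realized cumulative count and the realized cross-gene mean
    cumulative count, optionally scaled by the gene's heterogeneity
    multiplier; the count is then a Poisson draw with that mean. Cumulative
    baselines start at zero (no pre-range publications are simulated). Fully
    reproducible from ``cfg.seed``.
    """
    p = cfg.params
    if min(p.k1, p.k2, p.k3) < 0 or p.P_S <= 0 or p.alpha <= 0:
        raise ValueError("simulation requires positive model parameters")
    rng = np.random.default_rng(cfg.seed)
    start, end = cfg.year_range
    years = np.arange(start, end + 1)
    n = cfg.n_genes
    if cfg.heterogeneity_sd > 0:
        z = rng.standard_normal(n)
        mult = np.exp(cfg.heterogeneity_sd * z - 0.5 * cfg.heterogeneity_sd**2)
    else:
        rng.standard_normal(n)  # keep the stream aligned across heterogeneity levels
        mult = np.ones(n)

    counts = np.zeros((n, len(years)), dtype=np.int64)
    cum = np.zeros(n, dtype=np.int64)
    for j in range(len(years)):
        p_star = cum.mean()
        mean = mult * predict_rate(p, p_star, cum.astype(float))
        draw = rng.poisson(mean)
        counts[:, j] = draw
        cum += draw
    gene_index = pd.Index(np.arange(1, n + 1), name="gene_id")
    return PublicationHistories(pd.DataFrame(counts, index=gene_index, columns=list(years)))


def inject_gwas_shocks(
    histories: PublicationHistories,
    shocks: list[GwasShock],
    seed: int = 0,
    multiplicative: bool = False,
) -> PublicationHistories:
    """Add association-driven publication boosts to simulated histories.

    Each shock adds independent Poisson(boost) draws to the gene's counts in
    the window years ``t0 .. t0+window-1`` (or multiplies the realized counts
    by ``1 + boost`` in multiplicative mode). Other gene-years are untouched;
    the input is not modified.
    """
    rng = np.random.default_rng(seed)
    out = histories.copy()
    lo, hi = histories.year_range
    for s in shocks:
        if s.gene_id not in out.counts.index:
            raise KeyError(f"shock gene {s.gene_id} not in histories")
        if not lo <= s.t0 <= hi:
            raise ValueError(f"shock year {s.t0} outside data range [{lo}, {hi}]")
        y_end = min(s.t0 + s.window - 1, hi)
        for y in range(s.t0, y_end + 1):
            if multiplicative:
                base = int(out.counts.at[s.gene_id, y])
                out.counts.at[s.gene_id, y] = rng.poisson(base * (1.0 + s.boost))
            else:
                out.counts.at[s.gene_id, y] += int(rng.poisson(s.boost))
    return out


def sample_shocks(
    genes,
    n_shocks: int,
    t0_range: tuple[int, int],
    boost_start: float,
    boost_end: float | None = None,
    window: int = 3,
    seed: int = 0,
) -> list[GwasShock]:
    """Draw a shock schedule: ``n_shocks`` distinct genes, association years
    uniform over ``t0_range``, boost interpolated linearly from
    ``boost_start`` at the first year to ``boost_end`` at the last (constant
    if ``boost_end`` is None). A declining schedule emulates a GWAS follow-up
    effect that weakens with calendar date."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(list(genes))
    if n_shocks > len(genes):
        raise ValueError("more shocks than genes")
    chosen = rng.choice(genes, size=n_shocks, replace=False)
    y0, y1 = t0_range
    t0s = rng.integers(y0, y1 + 1, size=n_shocks)
    if boost_end is None:
        boosts = np.full(n_shocks, float(boost_start))
    else:
        frac = (t0s - y0) / max(y1 - y0, 1)
        boosts = boost_start + frac * (boost_end - boost_start)
    months = rng.integers(1, 13, size=n_shocks)
    return [
        GwasShock(gene_id=int(g), t0=int(t), boost=float(max(b, 0.0)), window=window,
                  month=int(m))
        for g, t, b, m in zip(chosen, t0s, boosts, months)
    ]


def classes_from_shocks(
    histories: PublicationHistories,
    shocks: list[GwasShock],
    associations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Disease-class table implied by a shock schedule.

    Shocked genes are labelled ``complex`` with their first shock year as the
    first GWAS year; predictors (p value, odds ratio, CI, date) are taken
    from the matching association rows when given. All other genes are
    ``none``. Matches the schema produced by gene classification at ingest.
    """
    idx = pd.Index(histories.genes, name="gene_id")
    out = pd.DataFrame({"label": "none"}, index=idx)
    out["omim_mendelian"] = False
    out["omim_complex"] = False
    for col in (
        "first_gwas_year", "first_assoc_p", "first_assoc_or",
        "first_assoc_or_ci", "first_assoc_date",
    ):
        out[col] = np.nan
    out["trait_class"] = None

    assoc_by_gene: dict[int, pd.DataFrame] = {}
    if associations is not None and len(associations):
        a = associations.copy()
        a["gene_id"] = a["MAPPED_GENE"].str.lstrip("G").astype(int)
        assoc_by_gene = {g: sub for g, sub in a.groupby("gene_id")}

    first: dict[int, GwasShock] = {}
    for s in shocks:
        if s.gene_id not in first or s.t0 < first[s.gene_id].t0:
            first[s.gene_id] = s
    for g, s in first.items():
        out.at[g, "label"] = "complex"
        out.at[g, "first_gwas_year"] = float(s.t0)
        out.at[g, "first_assoc_date"] = s.t0 + (s.month - 1) / 12.0
        out.at[g, "trait_class"] = s.trait_class
        sub = assoc_by_gene.get(g)
        if sub is not None:
            row = sub.sort_values("DATE").iloc[0]
            out.at[g, "first_assoc_p"] = float(row["P-VALUE"])
            out.at[g, "first_assoc_or"] = float(row["OR or BETA"])
            from .ingest import _parse_ci

            ci = _parse_ci(row["95% CI (TEXT)"])
            if ci is not None:
                out.at[g, "first_assoc_or_ci"] = ci[0]
    return out


# -- association tables and fixture bundles -----------------------------------

CATALOG_COLUMNS = [
    "SNPS", "CHR_ID", "CHR_POS", "MAPPED_GENE", "P-VALUE", "OR or BETA",
    "95% CI (TEXT)", "RISK ALLELE FREQUENCY", "DATE", "MAPPED_TRAIT_URI",
    "JOURNAL", "DISEASE/TRAIT",
]

#: synthetic gene geometry: gene g occupies [g*GENE_PITCH, g*GENE_PITCH+GENE_LEN)
GENE_PITCH = 2_000_000
GENE_LEN = 50_000
DISEASE_TRAIT_URI = "http://www.ebi.ac.uk/efo/EFO_0009999"


def _gene_interval(gene_id: int) -> tuple[str, int, int]:
    return "1", gene_id * GENE_PITCH, gene_id * GENE_PITCH + GENE_LEN


def generate_association_table(shocks: list[GwasShock], seed: int = 0) -> pd.DataFrame:
    """GWAS-catalog-dialect rows for a list of shocks.

    Unless a shock specifies them, -log10 p is uniform on [5, 30] and the
    odds ratio log-normal (mu=0.15, sigma=0.2) with a symmetric CI. The
    variant is placed inside the (synthetic) gene body so coordinate mapping
    recovers the gene, and the date is the shock year at month resolution.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(shocks):
        p = s.p_value if s.p_value is not None else 10.0 ** (-rng.uniform(5, 30))
        orr = s.odds_ratio if s.odds_ratio is not None else float(np.exp(rng.normal(0.15, 0.2)))
        half = 0.3 * abs(orr - 1.0) + 0.01
        chrom, g0, g1 = _gene_interval(s.gene_id)
        pos = (g0 + g1) // 2
        rows.append(
            {
                "SNPS": f"rs{100000 + i}",
                "CHR_ID": chrom,
                "CHR_POS": str(pos),
                "MAPPED_GENE": f"G{s.gene_id}",
                "P-VALUE": repr(float(p)),
                "OR or BETA": repr(float(orr)),
                "95% CI (TEXT)": f"[{orr - half!r}-{orr + half!r}]",
                "RISK ALLELE FREQUENCY": "0.25",
                "DATE": f"{s.t0}-{s.month:02d}-01",
                "MAPPED_TRAIT_URI": DISEASE_TRAIT_URI,
                "JOURNAL": "Synthetic J Genomics",
                "DISEASE/TRAIT": s.trait_class,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_fixture_bundle(
    histories: PublicationHistories,
    classes: pd.DataFrame | None,
    associations: pd.DataFrame | None,
    out_dir,
    taxon: int = 9606,
) -> dict[str, Path]:
    """Write a mutually consistent set of ingestion-dialect input files.

    Emits gene2pubmed-dialect links, a pmid->year table, a gene-info table
    with synthetic coordinates, a genemap-dialect table for OMIM-labelled
    genes, a catalog-dialect association table and a disease-term list.
    Reading the bundle back through ingestion reproduces the in-memory
    objects exactly; writing is deterministic given its inputs.

    ``classes`` needs columns ``label`` (mendelian/complex/both/none) indexed
    by gene id; OMIM rows are written for labels involving OMIM membership.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    # gene2pubmed + year table: one fresh pmid per (gene, year, k) publication
    link_rows = []
    year_rows = []
    pmid = 10_000_000
    for gene in histories.genes:
        row = histories.counts.loc[gene]
        for year, c in row.items():
            for _ in range(int(c)):
                link_rows.append((taxon, int(gene), pmid))
                year_rows.append((pmid, int(year), ""))
                pmid += 1
    links = pd.DataFrame(link_rows, columns=["#tax_id", "GeneID", "PubMed_ID"])
    paths["gene2pubmed"] = out / "gene2pubmed.tsv"
    links.to_csv(paths["gene2pubmed"], sep="\t", index=False)
    years = pd.DataFrame(year_rows, columns=["PubMed_ID", "year_reported", "year_e"])
    paths["years"] = out / "pub_years.tsv"
    years.to_csv(paths["years"], sep="\t", index=False)

    # gene universe with synthetic coordinates
    gi = pd.DataFrame(
        [(int(g), f"G{int(g)}", *_gene_interval(int(g))) for g in histories.genes],
        columns=["GeneID", "Symbol", "chrom", "start", "end"],
    )
    paths["genes"] = out / "gene_info.tsv"
    gi.to_csv(paths["genes"], sep="\t", index=False)

    # genemap-dialect OMIM rows
    omim_rows = []
    if classes is not None:
        for gene, row in classes.iterrows():
            label = row["label"]
            if label in ("mendelian", "both"):
                omim_rows.append((int(gene), "Synthetic syndrome (3)", "confirmed"))
            omim_complex = bool(row.get("omim_complex", False))
            if omim_complex:
                omim_rows.append(
                    (int(gene), "{Synthetic susceptibility} (3), multifactorial", "confirmed")
                )
    gm = pd.DataFrame(omim_rows, columns=["Entrez Gene ID", "Phenotypes", "Confidence"])
    paths["omim"] = out / "genemap.tsv"
    gm.to_csv(paths["omim"], sep="\t", index=False)

    # catalog-dialect associations
    assoc = associations if associations is not None else pd.DataFrame(columns=CATALOG_COLUMNS)
    paths["gwas"] = out / "gwas_catalog.tsv"
    assoc.to_csv(paths["gwas"], sep="\t", index=False)

    # disease-term list (descendants of the disease root)
    paths["efo_terms"] = out / "efo_disease_terms.txt"
    paths["efo_terms"].write_text(DISEASE_TRAIT_URI + "\n")
    return paths
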