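"""Readers and filters for the three tabular inputs.

Parses gene->publication links (gene2pubmed dialect) plus a pmid->year table,
an OMIM genemap-style gene-trait table, and a GWAS-catalog-style association
table; maps variants to genes by coordinate (closest gene within 500 kb,
both genes when the variant lies inside two overlapping gene bodies);
restricts associations to disease traits; classifies genes as mendelian /
complex / both / none; and assembles per-gene publication histories.

Coordinates are 0-based half-open internally; catalog positions (1-based)
are converted on read. The gene-info table is the package's own dialect and
already carries 0-based half-open intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histories import PublicationHistories, histories_from_links

logger = logging.getLogger(__name__)

MAX_GENE_DISTANCE = 500_000

OMIM_COLUMNS = {
    "gene": "Entrez Gene ID",
    "phenotypes": "Phenotypes",
    "confidence": "Confidence",
}


class FormatError(ValueError):
    """Raised when an input table is missing required structure."""


@dataclass
class IngestResult:
    histories: PublicationHistories
    classes: pd.DataFrame
    associations: pd.DataFrame
    accounting: dict = field(default_factory=dict)


# -- publication links ---------------------------------------------------------


def parse_gene2pubmed(path, taxon: int = 9606, accounting: dict | None = None) -> pd.DataFrame:
    """Read gene->publication links, keeping one row per (gene, pmid) of ``taxon``.

    The file is tab-separated with columns (tax_id, GeneID, PubMed_ID); a
    leading '#' on the header is permitted. Malformed rows are skipped with a
    warning and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#").strip() for c in raw.columns]
    need = ["tax_id", "GeneID", "PubMed_ID"]
    if list(raw.columns[:3]) != need:
        raise FormatError(f"expected columns {need}, found {list(raw.columns[:3])}")
    n_total = len(raw)
    num = raw[need].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        logger.warning("gene2pubmed: skipped %d malformed rows", int(bad.sum()))
    num = num[~bad].astype(np.int64)
    n_other_taxon = int((num["tax_id"] != taxon).sum())
    links = num[num["tax_id"] == taxon][["GeneID", "PubMed_ID"]]
    links.columns = ["gene_id", "pmid"]
    n_before_dedup = len(links)
    links = links.drop_duplicates(ignore_index=True)
    if accounting is not None:
        accounting.update(
            gene2pubmed_rows=n_total,
            gene2pubmed_malformed=int(bad.sum()),
            gene2pubmed_other_taxon=n_other_taxon,
            gene2pubmed_duplicates=n_before_dedup - len(links),
            gene2pubmed_links=len(links),
        )
    if links.empty:
        raise FormatError(f"no gene2pubmed links for taxon {taxon}")
    return links


def load_year_table(path) -> pd.DataFrame:
    """Read the pmid->year table: columns (PubMed_ID, year_reported, year_e)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "PubMed_ID" not in tab.columns:
        raise FormatError("year table must have a PubMed_ID column")
    out = pd.DataFrame({"pmid": pd.to_numeric(tab["PubMed_ID"], errors="coerce")})
    for col in ("year_reported", "year_e"):
        out[col] = pd.to_numeric(tab.get(col), errors="coerce")
    out = out.dropna(subset=["pmid"])
    out["pmid"] = out["pmid"].astype(np.int64)
    return out.drop_duplicates(subset="pmid")


def assign_pub_years(
    links: pd.DataFrame, year_table: pd.DataFrame, accounting: dict | None = None
) -> pd.DataFrame:
    """Attach a year to each link: the earliest of the reported year and EYear.

    Links whose pmid has no parseable year in the table are dropped with a
    logged count; non-numeric year fields are treated as absent.
    """
    merged = links.merge(year_table, on="pmid", how="left")
    year = merged[["year_reported", "year_e"]].min(axis=1)
    missing = year.isna()
    if missing.any():
        logger.warning("assign_pub_years: dropped %d links with no usable year", int(missing.sum()))
    out = merged.loc[~missing, ["gene_id", "pmid"]].copy()
    out["year"] = year[~missing].astype(int)
    if accounting is not None:
        accounting["links_missing_year"] = int(missing.sum())
        accounting["links_with_year"] = len(out)
    return out.reset_index(drop=True)


# -- OMIM ----------------------------------------------------------------------


def parse_omim_genemap(path, columns: dict | None = None) -> pd.DataFrame:
    """Gene-trait links from a genemap-style table.

    Keeps rows with confidence "confirmed", a numeric gene id, and a
    phenotype that is neither non-disease (bracketed) nor potentially
    spurious ('?'-marked). The multifactorial flag in the phenotype string
    separates complex from Mendelian traits. Returns columns
    (gene_id, trait_kind) with trait_kind in {mendelian, complex_multifactorial}.
    """
    cols = dict(OMIM_COLUMNS, **(columns or {}))
    tab = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [v for v in cols.values() if v not in tab.columns]
    if missing:
        raise FormatError(f"genemap table missing columns: {missing}")
    conf = tab[cols["confidence"]].str.strip().str.lower()
    pheno = tab[cols["phenotypes"]].fillna("")
    gene = pd.to_numeric(tab[cols["gene"]], errors="coerce")
    keep = (
        (conf == "confirmed")
        & gene.notna()
        & ~pheno.str.strip().str.startswith("[")  # non-disease traits
        & ~pheno.str.contains(r"\?", regex=True)  # potentially spurious mappings
        & (pheno.str.strip() != "")
    )
    out = pd.DataFrame(
        {
            "gene_id": gene[keep].astype(np.int64),
            "trait_kind": np.where(
                pheno[keep].str.contains("multifactorial", case=False),
                "complex_multifactorial",
                "mendelian",
            ),
        }
    )
    return out.drop_duplicates(ignore_index=True)


# -- gene coordinates and variant mapping --------------------------------------


def parse_gene_info(path) -> pd.DataFrame:
    """Gene universe table: columns (GeneID, Symbol, chrom, start, end).

    Intervals are 0-based half-open. Defines the fixed gene universe, so
    zero-publication genes exist downstream.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"GeneID": np.int64, "chrom": str})
    need = {"GeneID", "chrom", "start", "end"}
    if not need.issubset(tab.columns):
        raise FormatError(f"gene info table must have columns {sorted(need)}")
    out = tab.rename(columns={"GeneID": "gene_id", "Symbol": "symbol"})
    if "symbol" not in out.columns:
        out["symbol"] = "G" + out["gene_id"].astype(str)
    return out[["gene_id", "symbol", "chrom", "start", "end"]]


def map_variant_to_genes(
    variant_pos: tuple[str, int],
    gene_intervals: pd.DataFrame,
    max_dist: int = MAX_GENE_DISTANCE,
) -> list[int]:
    """Gene id(s) for a variant position (chrom, bp; 0-based).

    Distance is 0 inside a gene body, else base pairs to the nearer interval
    end. Returns the containing genes when the variant lies inside two (or
    more) overlapping gene bodies, otherwise the single nearest gene within
    ``max_dist``; ties between equidistant genes break to the smaller gene id.
    Unknown chromosome returns empty with a warning.
    """
    chrom, pos = variant_pos
    sub = gene_intervals[gene_intervals["chrom"] == str(chrom)]
    if sub.empty:
        logger.warning("variant on unknown chromosome %s", chrom)
        return []
    start = sub["start"].to_numpy(np.int64)
    end = sub["end"].to_numpy(np.int64)
    genes = sub["gene_id"].to_numpy(np.int64)
    dist = np.maximum.reduce([start - pos, pos - (end - 1), np.zeros(len(sub), np.int64)])
    inside = dist == 0
    if inside.sum() >= 2:
        return sorted(int(g) for g in genes[inside])
    best = dist.min()
    if best > max_dist:
        return []
    tied = genes[dist == best]
    return [int(tied.min())]


# -- GWAS catalog --------------------------------------------------------------

_CI_RE = re.compile(
    r"^\s*\[\s*([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*-\s*"
    r"([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*\]\s*$"
)


def _parse_ci(text) -> tuple[float, float] | None:
    if not isinstance(text, str):
        return None
    m = _CI_RE.match(text)
    if not m:
        return None
    return float(m.group(1)), float(m.group(2))


def _float_series(series: pd.Series) -> pd.Series:
    """Correctly rounded string->float conversion (pandas' fast parser is not)."""

    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv)


def _decimal_year(dates: pd.Series) -> pd.Series:
    d = pd.to_datetime(dates, errors="coerce")
    return d.dt.year + (d.dt.month - 1) / 12.0


def parse_gwas_catalog(
    path,
    gene_info: pd.DataFrame | None = None,
    p_threshold: float = 1e-5,
    accounting: dict | None = None,
) -> pd.DataFrame:
    """Variant-trait associations from a catalog-dialect table.

    An effect size is recognised as an odds ratio only when the variant has a
    reported risk-allele frequency and the CI text is a bare numeric interval
    (unit-annotated intervals indicate a beta). Variants are mapped to genes
    by coordinates when ``gene_info`` is given, falling back to the mapped-
    gene symbol column; rows mapping to two overlapping genes are exploded.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    need = {"SNPS", "P-VALUE", "DATE", "MAPPED_TRAIT_URI"}
    if not need.issubset(tab.columns):
        raise FormatError(f"catalog table must have columns {sorted(need)}")
    n_rows = len(tab)
    p = _float_series(tab["P-VALUE"])
    date = pd.to_datetime(tab["DATE"], errors="coerce")
    ok = p.notna() & (p > 0) & (p <= p_threshold) & date.notna()
    if (~ok).any():
        logger.warning("catalog: dropped %d rows (unparseable or p > %.1g)", int((~ok).sum()), p_threshold)
    tab = tab[ok].copy()
    p = p[ok]
    date = date[ok]

    raf = _float_series(tab.get("RISK ALLELE FREQUENCY", pd.Series(index=tab.index, dtype=object)))
    effect = _float_series(tab.get("OR or BETA", pd.Series(index=tab.index, dtype=object)))
    ci = tab.get("95% CI (TEXT)", pd.Series("", index=tab.index)).map(_parse_ci)
    is_or = raf.notna() & effect.notna() & ci.notna() & (effect > 0)
    odds_ratio = effect.where(is_or)
    ci_lo = ci.map(lambda v: v[0] if v else np.nan).where(is_or)
    ci_hi = ci.map(lambda v: v[1] if v else np.nan).where(is_or)

    rows = []
    symbol_map = {}
    if gene_info is not None:
        symbol_map = dict(zip(gene_info["symbol"], gene_info["gene_id"]))
    n_unmapped = 0
    for idx in tab.index:
        gene_ids: list[int] = []
        if gene_info is not None:
            chrom = tab.at[idx, "CHR_ID"] if "CHR_ID" in tab.columns else None
            pos = pd.to_numeric(tab.at[idx, "CHR_POS"], errors="coerce") if "CHR_POS" in tab.columns else np.nan
            if isinstance(chrom, str) and pd.notna(pos):
                gene_ids = map_variant_to_genes((chrom, int(pos) - 1), gene_info)
        if not gene_ids and "MAPPED_GENE" in tab.columns:
            sym = tab.at[idx, "MAPPED_GENE"]
            if isinstance(sym, str) and sym in symbol_map:
                gene_ids = [int(symbol_map[sym])]
        if not gene_ids:
            n_unmapped += 1
            continue
        for g in gene_ids:
            rows.append(
                {
                    "variant_id": tab.at[idx, "SNPS"],
                    "gene_id": g,
                    "trait_id": tab.at[idx, "MAPPED_TRAIT_URI"],
                    "p_value": float(p[idx]),
                    "odds_ratio": float(odds_ratio[idx]) if pd.notna(odds_ratio[idx]) else np.nan,
                    "or_ci_lower": float(ci_lo[idx]) if pd.notna(ci_lo[idx]) else np.nan,
                    "or_ci_upper": float(ci_hi[idx]) if pd.notna(ci_hi[idx]) else np.nan,
                    "pub_date": date[idx],
                    "journal": tab.at[idx, "JOURNAL"] if "JOURNAL" in tab.columns else None,
                    "trait_class": tab.at[idx, "DISEASE/TRAIT"] if "DISEASE/TRAIT" in tab.columns else None,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gene_id", "trait_id", "p_value", "odds_ratio",
            "or_ci_lower", "or_ci_upper", "pub_date", "journal", "trait_class",
        ],
    )
    if len(out):
        out["date_decimal"] = _decimal_year(out["pub_date"])
        out["year"] = pd.to_datetime(out["pub_date"]).dt.year
    else:
        out["date_decimal"] = pd.Series(dtype=float)
        out["year"] = pd.Series(dtype=int)
    if accounting is not None:
        accounting.update(
            catalog_rows=n_rows,
            catalog_dropped=int(n_rows - len(tab)),
            catalog_unmapped=n_unmapped,
            catalog_associations=len(out),
        )
    return out


def load_efo_terms(path) -> set[str]:
    """Flat file of disease-term identifiers, one per line."""
    terms = {line.strip() for line in open(path) if line.strip()}
    return terms


def filter_disease_traits(
    associations: pd.DataFrame, efo_disease_terms: set[str], accounting: dict | None = None
) -> pd.DataFrame:
    """Keep associations whose trait is in the disease-term set."""
    if not efo_disease_terms:
        raise ValueError("empty disease-term set")
    keep = associations["trait_id"].isin(efo_disease_terms)
    if (~keep).any():
        logger.warning("removed %d non-disease-trait associations", int((~keep).sum()))
    if accounting is not None:
        accounting["non_disease_associations"] = int((~keep).sum())
    return associations[keep].reset_index(drop=True)


# -- classification ------------------------------------------------------------


def classify_genes(
    omim: pd.DataFrame, gwas_associations: pd.DataFrame, gene_universe
) -> pd.DataFrame:
    """Label every gene mendelian / complex / both / none.

    mendelian: OMIM-Mendelian and not (OMIM-complex or GWAS);
    complex: (OMIM-complex-only or GWAS) and not OMIM-Mendelian;
    both: OMIM-Mendelian and (OMIM-complex or GWAS); none: otherwise.
    GWAS genes carry their first-association year, and the p value / odds
    ratio / date of the earliest association (smallest p on date ties).
    """
    universe = pd.Index(sorted(gene_universe), name="gene_id")
    omim_mend = set(omim.loc[omim["trait_kind"] == "mendelian", "gene_id"]) & set(universe)
    omim_cplx = set(omim.loc[omim["trait_kind"] == "complex_multifactorial", "gene_id"]) & set(universe)

    first = {}
    if len(gwas_associations):
        assoc = gwas_associations.sort_values(["pub_date", "p_value"], kind="mergesort")
        first = {g: sub.iloc[0] for g, sub in assoc.groupby("gene_id")}
    gwas_genes = set(first) & set(universe)

    labels = []
    for g in universe:
        m = g in omim_mend
        c = g in omim_cplx or g in gwas_genes
        if m and c:
            labels.append("both")
        elif m:
            labels.append("mendelian")
        elif c:
            labels.append("complex")
        else:
            labels.append("none")
    out = pd.DataFrame({"label": labels}, index=universe)
    out["omim_mendelian"] = [g in omim_mend for g in universe]
    out["omim_complex"] = [g in omim_cplx for g in universe]
    for col in (
        "first_gwas_year", "first_assoc_p", "first_assoc_or",
        "first_assoc_or_ci", "first_assoc_date",
    ):
        out[col] = np.nan
    out["trait_class"] = None
    for g in gwas_genes:
        row = first[g]
        out.at[g, "first_gwas_year"] = float(row["year"])
        out.at[g, "first_assoc_p"] = row["p_value"]
        out.at[g, "first_assoc_date"] = row["date_decimal"]
        out.at[g, "trait_class"] = row.get("trait_class")
        if pd.notna(row["odds_ratio"]):
            out.at[g, "first_assoc_or"] = row["odds_ratio"]
            out.at[g, "first_assoc_or_ci"] = row["or_ci_lower"]
        else:
            # fall back to any association with an odds ratio in the first year
            sub = gwas_associations[
                (gwas_associations["gene_id"] == g)
                & (gwas_associations["year"] == int(row["year"]))
                & gwas_associations["odds_ratio"].notna()
            ]
            if len(sub):
                best = sub.sort_values("p_value").iloc[0]
                out.at[g, "first_assoc_or"] = best["odds_ratio"]
                out.at[g, "first_assoc_or_ci"] = best["or_ci_lower"]
    return out


def build_histories(
    links: pd.DataFrame, gene_universe, year_range: tuple[int, int] = (1950, 2015)
) -> PublicationHistories:
    """Per-gene annual and cumulative publication counts over ``year_range``.

    Publications before the range start are folded into the cumulative
    baseline; every universe gene gets a (possibly all-zero) history.
    """
    return histories_from_links(links, gene_universe, year_range)


# -- one-call ingestion --------------------------------------------------------


def ingest_bundle(
    gene2pubmed,
    years,
    omim,
    gwas,
    efo_terms,
    genes,
    taxon: int = 9606,
    year_range: tuple[int, int] = (1950, 2015),
    p_threshold: float = 1e-5,
) -> IngestResult:
    """Read and filter every input and assemble the analysis objects."""
    acct: dict = {}
    gene_info = parse_gene_info(genes)
    universe = gene_info["gene_id"].tolist()
    links = parse_gene2pubmed(gene2pubmed, taxon=taxon, accounting=acct)
    links = assign_pub_years(links, load_year_table(years), accounting=acct)
    histories = build_histories(links, universe, year_range)
    omim_df = parse_omim_genemap(omim)
    assoc = parse_gwas_catalog(gwas, gene_info=gene_info, p_threshold=p_threshold, accounting=acct)
    assoc = filter_disease_traits(assoc, load_efo_terms(efo_terms), accounting=acct)
    classes = classify_genes(omim_df, assoc, universe)
    acct["n_genes"] = len(universe)
    acct["class_counts"] = classes["label"].value_counts().to_dict()
    logger.info("ingest accounting: %s", acct)
    return IngestResult(histories, classes, assoc, acct)
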