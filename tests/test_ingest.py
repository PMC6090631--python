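import numpy as np
import pandas as pd
import pytest

from genepulse.histories import histories_from_links
from genepulse.ingest import (
    FormatError,
    assign_pub_years,
    build_histories,
    classify_genes,
    filter_disease_traits,
    load_year_table,
    map_variant_to_genes,
    parse_gene2pubmed,
    parse_omim_genemap,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseGene2pubmed:
    def test_taxon_filter_and_dedupe(self, tmp_path):
        path = _write(
            tmp_path,
            "g2p.tsv",
            "#tax_id\tGeneID\tPubMed_ID\n"
            "9606\t10\t100\n"
            "9606\t11\t101\n"
            "4932\t12\t102\n"
            "9606\t10\t100\n",  # duplicate link
        )
        acct = {}
        links = parse_gene2pubmed(path, taxon=9606, accounting=acct)
        assert len(links) == 2
        assert set(map(tuple, links.values)) == {(10, 100), (11, 101)}
        assert acct["gene2pubmed_other_taxon"] == 1
        assert acct["gene2pubmed_duplicates"] == 1

    def test_malformed_rows_skipped_with_count(self, tmp_path):
        path = _write(
            tmp_path,
            "g2p.tsv",
            "#tax_id\tGeneID\tPubMed_ID\n9606\t10\t100\n9606\tnot_a_gene\t101\n",
        )
        acct = {}
        links = parse_gene2pubmed(path, accounting=acct)
        assert len(links) == 1
        assert acct["gene2pubmed_malformed"] == 1

    def test_empty_result_is_error(self, tmp_path):
        path = _write(tmp_path, "g2p.tsv", "#tax_id\tGeneID\tPubMed_ID\n4932\t1\t2\n")
        with pytest.raises(FormatError):
            parse_gene2pubmed(path, taxon=9606)


class TestAssignPubYears:
    @pytest.fixture()
    def year_table(self, tmp_path):
        return load_year_table(
            _write(
                tmp_path,
                "years.tsv",
                "PubMed_ID\tyear_reported\tyear_e\n"
                "100\t2007\t2006\n"   # earliest of the two wins
                "101\t2007\t\n"       # only reported year
                "102\t\t\n",          # no year at all -> dropped
            )
        )

    def test_earliest_year_rule(self, year_table):
        links = pd.DataFrame({"gene_id": [1, 1, 1], "pmid": [100, 101, 102]})
        acct = {}
        out = assign_pub_years(links, year_table, accounting=acct)
        got = dict(zip(out["pmid"], out["year"]))
        assert got == {100: 2006, 101: 2007}
        assert acct["links_missing_year"] == 1

    def test_absent_pmid_dropped(self, year_table):
        links = pd.DataFrame({"gene_id": [1], "pmid": [999]})
        out = assign_pub_years(links, year_table)
        assert out.empty


class TestParseOmim:
    HEADER = "Entrez Gene ID\tPhenotypes\tConfidence\n"

    def test_filters_and_multifactorial_flag(self, tmp_path):
        path = _write(
            tmp_path,
            "gm.tsv",
            self.HEADER
            + "1\tSome syndrome (3)\tconfirmed\n"
            + "2\tOther syndrome (3)\tprovisional\n"          # not confirmed
            + "3\t?Uncertain mapping (2)\tconfirmed\n"        # spurious marker
            + "4\t[Blood group] (3)\tconfirmed\n"             # non-disease
            + "5\t{Diabetes susceptibility} (3), multifactorial\tconfirmed\n"
            + "NP_1\tNamed only (3)\tconfirmed\n",            # no numeric gene id
        )
        out = parse_omim_genemap(path)
        kinds = dict(zip(out["gene_id"], out["trait_kind"]))
        assert kinds == {1: "mendelian", 5: "complex_multifactorial"}

    def test_missing_columns_raise(self, tmp_path):
        path = _write(tmp_path, "gm.tsv", "GeneID\tstuff\n1\tx\n")
        with pytest.raises(FormatError):
            parse_omim_genemap(path)


class TestVariantMapping:
    @pytest.fixture()
    def intervals(self):
        return pd.DataFrame(
            {
                "gene_id": [1, 2, 3],
                "chrom": ["1", "1", "2"],
                "start": [1_000_000, 1_040_000, 500_000],
                "end": [1_050_000, 1_100_000, 600_000],
            }
        )

    def test_beyond_500kb_unmapped(self, intervals):
        assert map_variant_to_genes(("2", 1_200_001), intervals) == []

    def test_containing_gene_beats_nearby_gene(self):
        iv = pd.DataFrame(
            {"gene_id": [1, 2], "chrom": ["1", "1"],
             "start": [100, 5_000], "end": [1_000, 6_000]}
        )
        # inside gene 1; gene 2 is ~4 kb away
        assert map_variant_to_genes(("1", 500), iv) == [1]

    def test_inside_two_overlapping_genes_returns_both(self, intervals):
        assert map_variant_to_genes(("1", 1_045_000), intervals) == [1, 2]

    def test_equidistant_tie_breaks_to_smaller_id(self):
        iv = pd.DataFrame(
            {"gene_id": [7, 3], "chrom": ["1", "1"],
             "start": [2_000, 0], "end": [3_000, 1_000]}
        )
        # position 1499: 500 bp past gene 3's last base (999), 501 bp before
        # gene 7's first base (2000) -> asymmetric; use exact midpoint 1500-251
        assert map_variant_to_genes(("1", 1_499), iv) == [3]
        # exact tie: distance 500 to both
        iv2 = pd.DataFrame(
            {"gene_id": [7, 3], "chrom": ["1", "1"],
             "start": [2_000, 0], "end": [3_000, 1_001]}
        )
        assert map_variant_to_genes(("1", 1_500), iv2) == [3]

    def test_unknown_chromosome_empty(self, intervals):
        assert map_variant_to_genes(("X", 100), intervals) == []

    def test_agrees_with_exhaustive_scan(self, rng):
        """Oracle equivalence on random small interval sets."""

        def oracle(pos, iv, max_dist=500_000):
            inside, best = [], []
            best_d = None
            for _, row in iv.iterrows():
                if row["start"] <= pos < row["end"]:
                    d = 0
                    inside.append(int(row["gene_id"]))
                else:
                    d = min(abs(pos - row["start"]), abs(pos - (row["end"] - 1)))
                if best_d is None or d < best_d:
                    best_d, best = d, [int(row["gene_id"])]
                elif d == best_d:
                    best.append(int(row["gene_id"]))
            if len(inside) >= 2:
                return sorted(inside)
            if best_d > max_dist:
                return []
            return [min(best)]

        for _ in range(50):
            n = rng.integers(2, 8)
            starts = rng.integers(0, 2_000_000, n)
            lengths = rng.integers(1, 900_000, n)
            iv = pd.DataFrame(
                {"gene_id": rng.permutation(np.arange(1, n + 1)),
                 "chrom": "1", "start": starts, "end": starts + lengths}
            )
            pos = int(rng.integers(0, 3_000_000))
            assert map_variant_to_genes(("1", pos), iv) == oracle(pos, iv)


class TestTraitFilterAndClassification:
    def test_filter_disease_traits(self):
        assoc = pd.DataFrame(
            {"trait_id": ["efo:disease1", "efo:height", "efo:unknown"],
             "gene_id": [1, 2, 3]}
        )
        out = filter_disease_traits(assoc, {"efo:disease1"})
        assert list(out["gene_id"]) == [1]
        with pytest.raises(ValueError):
            filter_disease_traits(assoc, set())

    @pytest.fixture()
    def gwas_assoc(self):
        return pd.DataFrame(
            {
                "gene_id": [30, 30, 40],
                "p_value": [1e-8, 1e-12, 1e-6],
                "odds_ratio": [np.nan, 1.3, np.nan],
                "or_ci_lower": [np.nan, 1.1, np.nan],
                "pub_date": pd.to_datetime(["2008-06-01", "2010-01-01", "2012-03-01"]),
                "date_decimal": [2008 + 5 / 12, 2010.0, 2012 + 2 / 12],
                "year": [2008, 2010, 2012],
                "trait_class": ["ibd", "ibd", "t2d"],
            }
        )

    def test_labels(self, gwas_assoc):
        omim = pd.DataFrame(
            {"gene_id": [10, 20, 30], "trait_kind":
             ["mendelian", "complex_multifactorial", "mendelian"]}
        )
        classes = classify_genes(omim, gwas_assoc, gene_universe=[10, 20, 30, 40, 50])
        assert classes.loc[10, "label"] == "mendelian"
        assert classes.loc[20, "label"] == "complex"   # OMIM complex only
        assert classes.loc[30, "label"] == "both"      # OMIM mendelian + GWAS
        assert classes.loc[40, "label"] == "complex"   # GWAS only
        assert classes.loc[50, "label"] == "none"
        assert classes.loc[40, "first_gwas_year"] == 2012

    def test_partition_covers_universe(self, gwas_assoc):
        omim = pd.DataFrame({"gene_id": [10], "trait_kind": ["mendelian"]})
        universe = list(range(1, 60))
        classes = classify_genes(omim, gwas_assoc, universe)
        assert classes["label"].value_counts().sum() == len(universe)

    def test_first_association_attributes(self, gwas_assoc):
        classes = classify_genes(
            pd.DataFrame(columns=["gene_id", "trait_kind"]), gwas_assoc, [30, 40]
        )
        # earliest association (2008) defines the year and p; its odds ratio
        # is missing, so the first-year fallback cannot borrow the 2010 one
        assert classes.loc[30, "first_gwas_year"] == 2008
        assert classes.loc[30, "first_assoc_p"] == 1e-8
        assert np.isnan(classes.loc[30, "first_assoc_or"])


class TestBuildHistories:
    def test_zero_history_and_cumulative(self):
        links = pd.DataFrame(
            {"gene_id": [2, 2, 2], "pmid": [1, 2, 3], "year": [2001, 2001, 2003]}
        )
        h = build_histories(links, [1, 2], year_range=(2000, 2005))
        assert h.counts.loc[1].sum() == 0
        assert h.cumulative().loc[2, 2003] == 3

    def test_pre_range_links_fold_into_baseline(self):
        links = pd.DataFrame(
            {"gene_id": [1, 1], "pmid": [1, 2], "year": [1948, 1955]}
        )
        h = build_histories(links, [1], year_range=(1950, 1960))
        assert h.baseline[1] == 1
        assert h.counts.loc[1, 1955] == 1
        assert h.cumulative().loc[1, 1960] == 2

    def test_total_links_conserved(self, rng):
        """Accounting identity: every in-range link lands in exactly one cell."""
        n = 500
        links = pd.DataFrame(
            {
                "gene_id": rng.integers(1, 20, n),
                "pmid": np.arange(n),
                "year": rng.integers(1945, 2021, n),
            }
        )
        h = histories_from_links(links, range(1, 25), year_range=(1950, 2015))
        in_range = ((links["year"] >= 1950) & (links["year"] <= 2015)).sum()
        early = (links["year"] < 1950).sum()
        assert h.counts.to_numpy().sum() == in_range
        assert h.baseline.sum() == early
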