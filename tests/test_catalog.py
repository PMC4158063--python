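"""Catalog stage: filters, ncRNA flags, genome mapping, TPM, fold changes."""

import numpy as np
import pytest

from srdk.catalog import (
    annotate_ncrna,
    collapse_and_filter,
    compare_tissues,
    map_to_genome,
    tpm_normalize,
)
from srdk.config import PipelineConfig
from srdk.core import revcomp
from srdk.io import CollapsedRead, FastaRecord

from .oracles import naive_substring_hits


def _reads(*pairs):
    return [CollapsedRead(seq, count) for seq, count in pairs]


SEQ_A = "ACGTACGTACGTACGTACGTA"  # 21 nt
SEQ_B = "TTGACAGAAGATAGAGAGCAC"  # 21 nt


class TestCollapseAndFilter:
    def test_count_below_threshold_dropped_per_library(self, config):
        catalog, _ = collapse_and_filter(
            {"leaf": _reads((SEQ_A, 2)), "flower": _reads((SEQ_A, 5))}, config
        )
        assert "leaf" not in catalog[SEQ_A].per_library_count
        assert catalog[SEQ_A].per_library_count["flower"] == 5

    def test_count_at_threshold_retained(self, config):
        catalog, _ = collapse_and_filter({"leaf": _reads((SEQ_A, 3))}, config)
        assert catalog[SEQ_A].per_library_count == {"leaf": 3}

    def test_length_and_quality_filters(self, config):
        catalog, stats = collapse_and_filter(
            {
                "leaf": _reads(
                    ("ACGTACGTACGTACGTA", 9),  # 17 nt: below range
                    ("ACGTACGTACGTACGTACGTACGTACGTACG", 9),  # 31 nt: above
                    ("ACGTNCGTACGTACGTACGTA", 9),  # contains N
                    (SEQ_A, 9),
                )
            },
            config,
        )
        assert list(catalog) == [SEQ_A]
        assert stats["leaf"].total_raw == 36
        assert stats["leaf"].total_clean == 9

    def test_histogram_sums_to_one(self, config):
        catalog, stats = collapse_and_filter(
            {"leaf": _reads((SEQ_A, 5), (SEQ_B, 4), ("AAGCTTGGATCCAAGCTTGGATCC", 7))},
            config,
        )
        assert abs(sum(stats["leaf"].length_histogram.values()) - 1.0) < 1e-9

    def test_monotone_in_min_read_count(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        reads = [
            CollapsedRead("".join(bases[rng.integers(0, 4, 21)]), int(rng.integers(1, 10)))
            for _ in range(200)
        ]
        sizes = []
        for threshold in (1, 2, 3, 5, 8):
            cfg = PipelineConfig(min_read_count=threshold)
            catalog, _ = collapse_and_filter({"leaf": reads}, cfg)
            sizes.append(len(catalog))
        assert sizes == sorted(sizes, reverse=True)

    def test_no_libraries_is_an_error(self, config):
        with pytest.raises(ValueError):
            collapse_and_filter({}, config)


class TestAnnotateNcrna:
    def _catalog(self, config, *seqs):
        catalog, _ = collapse_and_filter({"leaf": _reads(*[(s, 5) for s in seqs])}, config)
        return catalog

    def test_exact_substring_flagged(self, config):
        ncrna = [FastaRecord("tRNA1", "", "GGG" + SEQ_A + "CCC")]
        catalog = self._catalog(config, SEQ_A, SEQ_B)
        assert annotate_ncrna(catalog, ncrna) == 1
        assert catalog[SEQ_A].annotation == "ncRNA"
        assert catalog[SEQ_B].annotation == "unannotated"

    def test_reverse_complement_window_flagged(self, config):
        ncrna = [FastaRecord("rRNA1", "", "GG" + revcomp(SEQ_B) + "AA")]
        catalog = self._catalog(config, SEQ_B)
        assert annotate_ncrna(catalog, ncrna) == 1

    def test_empty_reference_flags_nothing(self, config):
        catalog = self._catalog(config, SEQ_A)
        assert annotate_ncrna(catalog, []) == 0


class TestMapToGenome:
    def test_minus_strand_single_hit(self, config):
        genome = [FastaRecord("chr1", "", "TTTT" + revcomp(SEQ_A) + "GGGG")]
        catalog, _ = collapse_and_filter({"leaf": _reads((SEQ_A, 5))}, config)
        map_to_genome(catalog, genome)
        hits = catalog[SEQ_A].genome_hits
        assert len(hits) == 1 and hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (5, 25)

    def test_unique_match_percentage(self, config):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        chrom = "".join(bases[rng.integers(0, 4, 2000)])
        genome = [FastaRecord("chr1", "", chrom)]
        drawn = [chrom[i:i + 21] for i in (100, 500, 900)]
        absent = "A" * 21
        catalog, stats = collapse_and_filter(
            {"leaf": _reads(*[(s, 4) for s in drawn + [absent]])}, config
        )
        map_to_genome(catalog, genome, stats)
        st = stats["leaf"]
        assert st.matched_genome_unique == 3 and st.unique_clean == 4
        assert not catalog[absent].genome_hits

    def test_hit_counts_agree_with_naive_scan(self, config):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        chrom = "".join(bases[rng.integers(0, 4, 3000)])
        genome = [FastaRecord("chr1", "", chrom)]
        queries = [chrom[i:i + 20] for i in (10, 700, 1500)] + [
            "".join(bases[rng.integers(0, 4, 20)]) for _ in range(5)
        ]
        catalog, _ = collapse_and_filter({"leaf": _reads(*[(q, 3) for q in queries])}, config)
        map_to_genome(catalog, genome)
        for q in catalog:
            assert len(catalog[q].genome_hits) == naive_substring_hits(q, {"chr1": chrom})


class TestTpm:
    def test_definition_and_conservation(self, config):
        catalog, stats = collapse_and_filter(
            {"leaf": _reads((SEQ_A, 10), (SEQ_B, 990))}, config
        )
        stats["leaf"].total_clean = 1_000_000  # definition check at a round total
        tpm_normalize(catalog, stats)
        assert catalog[SEQ_A].per_library_tpm["leaf"] == pytest.approx(10.0)

    def test_whole_catalog_tpm_sums_to_one_million(self, config):
        catalog, stats = collapse_and_filter(
            {"leaf": _reads((SEQ_A, 7), (SEQ_B, 13), ("AAGCTTGGATCCAAGCTTGGA", 5))},
            config,
        )
        tpm_normalize(catalog, stats)
        total = sum(r.per_library_tpm["leaf"] for r in catalog.values())
        assert total == pytest.approx(1e6, rel=1e-9)

    def test_zero_total_is_an_error(self, config):
        catalog, stats = collapse_and_filter({"leaf": _reads((SEQ_A, 5))}, config)
        stats["leaf"].total_clean = 0
        with pytest.raises(ZeroDivisionError):
            tpm_normalize(catalog, stats)


class TestCompareTissues:
    def _df(self, config, tpms):
        catalog, _ = collapse_and_filter(
            {t: _reads((SEQ_A, 100)) for t in tpms}, config
        )
        catalog[SEQ_A].per_library_tpm = dict(tpms)
        return compare_tissues(catalog, list(tpms), config).iloc[0]

    def test_strong_enrichment(self, config):
        row = self._df(config, {"leaf": 5.0, "flower": 5.0, "fruit": 25.0})
        assert row["enriched_in"] == "fruit" and bool(row["strongly_enriched"])

    def test_absence_takes_precedence(self, config):
        row = self._df(config, {"leaf": 8.0, "flower": 4.0, "fruit": 0.0})
        assert row["absent_in"] == "fruit"
        assert row["enriched_in"] == ""  # leaf fold change is exactly 2, not > 2

    def test_high_expression_without_enrichment(self, config):
        row = self._df(config, {"leaf": 12.0, "flower": 12.0, "fruit": 12.0})
        assert bool(row["highly_expressed"]) and row["enriched_in"] == ""

    def test_single_tissue_is_an_error(self, config):
        catalog, _ = collapse_and_filter({"leaf": _reads((SEQ_A, 5))}, config)
        with pytest.raises(ValueError):
            compare_tissues(catalog, ["leaf"], config)
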