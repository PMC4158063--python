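"""miRNA identification: mismatch matching, hairpin criteria, loci reports."""

import numpy as np
import pytest

from srdk.catalog import collapse_and_filter, tpm_normalize
from srdk.config import PipelineConfig
from srdk.core import GenomicInterval, revcomp
from srdk.discovery import (
    MiRNALocus,
    find_isoform_pairs,
    genome_distribution,
    match_known,
    mismatch_distance,
    predict_novel,
)
from srdk.catalog import map_to_genome
from srdk.fold import fold, hairpin_metrics
from srdk.io import CollapsedRead, FastaRecord
from srdk.simulate import build_hairpin, simulate_genome


def _embed(precursor, seed=0, pad=400):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    left = "".join(bases[rng.integers(0, 4, pad)])
    right = "".join(bases[rng.integers(0, 4, pad)])
    return FastaRecord("chr1", "", left + precursor + right)


def _catalog(config, genome, *seq_count_pairs):
    catalog, stats = collapse_and_filter(
        {"leaf": [CollapsedRead(s, c) for s, c in seq_count_pairs]}, config
    )
    map_to_genome(catalog, [genome], stats)
    tpm_normalize(catalog, stats)
    return catalog


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    arm = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 45)])
    pre, mature, star, off = build_hairpin(arm, "TACGATTC", 21)
    return pre, mature, star


class TestMismatchDistance:
    def test_identity(self):
        assert mismatch_distance("ACGTACGT", "ACGTACGT") == 0

    def test_substitutions_counted(self):
        assert mismatch_distance("ACGTACGT", "ACGAACGA") == 2

    def test_length_difference_adds_overhang_penalty(self):
        # 1 nt shorter, best offset has 0 substitutions -> distance 1
        assert mismatch_distance("CGTACGT", "ACGTACGT") == 1

    def test_incomparable_beyond_two_nt(self):
        assert mismatch_distance("ACGTA", "ACGTACGTA") is None


class TestMatchKnown:
    def test_identity_with_hairpin_locus(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50))
        ref = [FastaRecord("csi-miR164", "", mature)]
        loci = match_known(catalog, ref, config, genome=[genome])
        assert len(loci) == 1
        locus = loci[0]
        assert locus.mismatches == 0 and locus.status == "known"
        assert locus.mature_seq in locus.precursor_seq
        assert catalog[mature].annotation == "known_miRNA"

    def test_two_mismatches_is_the_boundary(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50))
        two_off = list(mature)
        two_off[4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two_off[4]]
        two_off[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two_off[9]]
        loci = match_known(catalog, [FastaRecord("ref2", "", "".join(two_off))], config,
                           genome=[genome])
        assert len(loci) == 1 and loci[0].mismatches == 2

    def test_three_mismatches_unassigned(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50))
        three_off = list(mature)
        for i in (2, 8, 14):
            three_off[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[three_off[i]]
        loci = match_known(catalog, [FastaRecord("ref3", "", "".join(three_off))], config,
                           genome=[genome])
        assert loci == []

    def test_raising_max_mismatch_never_shrinks_the_known_set(self, config, planted):
        pre, mature, _ = planted
        genome = _embed(pre)
        ref = [FastaRecord("ref", "", mature)]
        previous = -1
        for mm in (0, 1, 2, 3):
            cfg = PipelineConfig(known_max_mismatch=mm)
            catalog = _catalog(cfg, genome, (mature, 50))
            n = len(match_known(catalog, ref, cfg, genome=[genome]))
            assert n >= previous
            previous = n

    def test_empty_reference_returns_empty(self, config, planted):
        pre, mature, _ = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50))
        assert match_known(catalog, [], config, genome=[genome]) == []


class TestPredictNovel:
    def test_planted_hairpin_with_star_accepted(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50), (star, 5))
        loci = predict_novel(catalog, [genome], config)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.mature_seq == mature and locus.star_seq == star
        assert locus.status == "novel" and locus.mirna_id.startswith("csi-miRN")

    def test_missing_star_read_rejected(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50))
        assert predict_novel(catalog, [genome], config) == []

    def test_known_assigned_reads_excluded(self, config, planted):
        pre, mature, star = planted
        genome = _embed(pre)
        catalog = _catalog(config, genome, (mature, 50), (star, 5))
        match_known(catalog, [FastaRecord("ref", "", mature)], config, genome=[genome])
        assert predict_novel(catalog, [genome], config) == []

    def test_novel_and_known_sets_disjoint(self, result):
        known = {l.mature_seq for l in result.known_loci}
        novel = {l.mature_seq for l in result.novel_loci}
        assert not (known & novel)

    def test_reported_matures_sit_on_their_precursor_stems(self, result):
        for locus in result.known_loci + result.novel_loci:
            assert locus.mature_seq in locus.precursor_seq
            structure = fold(locus.precursor_seq)
            start = locus.mature_offset
            metrics = hairpin_metrics(structure, (start, start + len(locus.mature_seq)))
            assert metrics.mature_paired_fraction > 0


class TestIsoformsAndDistribution:
    def _locus(self, mirna_id, offset, pre_interval, arm="5p"):
        structure = fold("GGGAAACCC")
        metrics = hairpin_metrics(structure, (0, 3))
        return MiRNALocus(
            mirna_id=mirna_id, mature_seq="A" * 21, status="known",
            precursor_interval=pre_interval, precursor_seq="A" * 400,
            structure=structure, metrics=metrics, mature_offset=offset, arm=arm,
        )

    def test_separation_between_nearest_ends(self):
        iv = GenomicInterval("chr1", 1000, 1399, "+")
        pairs = find_isoform_pairs(
            [self._locus("miR166j.1", 10, iv, "5p"), self._locus("miR166j.3", 226, iv, "3p")]
        )
        assert len(pairs) == 1
        assert pairs[0].separation == 195
        assert pairs[0].arms == ("5p", "3p")

    def test_single_locus_gives_no_pairs(self):
        iv = GenomicInterval("chr1", 1000, 1399, "+")
        assert find_isoform_pairs([self._locus("m", 10, iv)]) == []

    def test_co_located_loci_flagged_in_one_bin(self):
        a = self._locus("miR169c", 10, GenomicInterval("chr2", 1000, 1100, "+"))
        b = self._locus("miR169i", 10, GenomicInterval("chr2", 50_000, 50_100, "+"))
        df = genome_distribution([a, b], bin_size=100_000)
        assert len(df) == 1 and bool(df.iloc[0]["co_located"])

    def test_empty_loci_empty_table(self):
        assert genome_distribution([], 1000).empty

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            genome_distribution([], 0)

    def test_uniform_planting_passes_chi_square(self):
        from scipy.stats import chisquare

        genome, truth = simulate_genome(
            n_chrom=1, chrom_len=200_000, n_hairpins=60, n_ssr_hairpins=0, seed=3
        )
        starts = [m.precursor_interval.start for m in truth.mirnas]
        bins = np.histogram(starts, bins=10, range=(0, 200_000))[0]
        assert chisquare(bins).pvalue > 0.01
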