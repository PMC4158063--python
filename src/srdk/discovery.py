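"""Known- and novel-miRNA identification from the small-RNA catalog.

Known miRNAs: mismatch-tolerant (default <= 2) ungapped matching against a
reference mature set, with a stem-loop precursor check at a genomic locus.
Novel miRNAs: genome-mapped 20-24 nt reads whose flanking window folds
into a hairpin satisfying community annotation criteria (mature on a stem,
<= 4 duplex mismatches, <= 2-nt asymmetric bulge) with star-read evidence
in at least one library.  Also reports isoform pairs sharing a precursor
and the chromosomal distribution of precursor loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalog import Catalog
from .config import PipelineConfig
from .core import GenomicInterval, revcomp
from .fold import (
    HairpinMetrics,
    NotHairpinError,
    SecondaryStructure,
    fold,
    hairpin_metrics,
    mature_in_loop,
)
from .io import FastaRecord, GffFeature

logger = logging.getLogger(__name__)


@dataclass
class MiRNALocus:
    mirna_id: str
    mature_seq: str
    status: str  # known | novel
    precursor_interval: GenomicInterval
    precursor_seq: str
    structure: SecondaryStructure
    metrics: HairpinMetrics
    mature_offset: int  # 0-based offset of the mature within the precursor
    arm: str  # 5p | 3p
    star_seq: str = ""
    reference_id: str = ""
    mismatches: int = 0
    per_library_tpm: dict[str, float] = field(default_factory=dict)

    @property
    def mature_interval(self) -> GenomicInterval:
        """Genomic interval of the mature miRNA."""
        p = self.precursor_interval
        if p.strand == "+":
            start = p.start + self.mature_offset
        else:
            start = p.end - self.mature_offset - len(self.mature_seq) + 1
        return GenomicInterval(p.seq_id, start, start + len(self.mature_seq) - 1, p.strand)


@dataclass
class IsoformPair:
    locus_a: MiRNALocus
    locus_b: MiRNALocus
    separation: int
    arms: tuple[str, str]


# ---------------------------------------------------------------------------
# mismatch-tolerant comparison against reference matures
# ---------------------------------------------------------------------------

def mismatch_distance(query: str, reference: str, max_len_diff: int = 2) -> int | None:
    """Ungapped penalty between two mature sequences.

    Equal lengths: Hamming distance.  Length difference <= ``max_len_diff``:
    the shorter slides within the longer; penalty = substitutions at the
    best offset + the length difference (overhang).  Larger length
    differences are incomparable (None).
    """
    a, b = (query, reference) if len(query) <= len(reference) else (reference, query)
    diff = len(b) - len(a)
    if diff > max_len_diff:
        return None
    best = None
    for off in range(diff + 1):
        subs = sum(1 for x, y in zip(a, b[off:off + len(a)]) if x != y)
        if best is None or subs < best:
            best = subs
    return best + diff


# ---------------------------------------------------------------------------
# precursor extraction + hairpin validation
# ---------------------------------------------------------------------------

def _genome_index(genome: Sequence[FastaRecord]) -> dict[str, str]:
    return {rec.id: rec.sequence for rec in genome}


def extract_precursor_windows(
    hit: GenomicInterval,
    genome_seqs: Mapping[str, str],
    flank: int,
    near: int = 20,
) -> list[tuple[GenomicInterval, str, int]]:
    """Candidate precursor windows around a mature genome hit.

    Two windows are tried: the full flank upstream of the read (mature on
    the 3' arm) and the full flank downstream (mature on the 5' arm), each
    with a short ``near`` pad on the other side.  Returns
    (interval, precursor sequence on the read strand, mature offset).
    """
    chrom = genome_seqs[hit.seq_id]
    s0, e0 = hit.to_zero_based()
    windows = []
    for left, right in ((flank, near), (near, flank)):
        a = max(0, s0 - left)
        b = min(len(chrom), e0 + right)
        seq = chrom[a:b]
        if hit.strand == "+":
            offset = s0 - a
        else:
            seq = revcomp(seq)
            offset = b - e0
        windows.append(
            (GenomicInterval.from_zero_based(hit.seq_id, a, b, hit.strand), seq, offset)
        )
    return windows


def _validate_hairpin(
    precursor_seq: str,
    mature_offset: int,
    mature_len: int,
    config: PipelineConfig,
) -> tuple[SecondaryStructure, HairpinMetrics] | None:
    structure = fold(precursor_seq, min_loop=config.min_loop)
    interval = (mature_offset, mature_offset + mature_len)
    if mature_in_loop(structure, interval):
        return None
    try:
        metrics = hairpin_metrics(structure, interval)
    except NotHairpinError:
        return None
    return structure, metrics


def _star_supported(
    precursor_seq: str,
    star_interval: tuple[int, int],
    catalog: Catalog,
) -> str | None:
    """Catalog read consistent with the computed star interval (+/- 1 nt)."""
    lo, hi = star_interval
    for shift in (0, -1, 1):
        a, b = lo + shift, hi + shift
        if 0 <= a < b <= len(precursor_seq):
            star_seq = precursor_seq[a:b]
            if star_seq in catalog:
                return star_seq
    return None


def _arm_of(metrics: HairpinMetrics, mature_offset: int) -> str:
    return "5p" if mature_offset < metrics.star_interval[0] else "3p"


def _dedup_overlapping(found: list) -> list:
    """Collapse loci whose precursor windows overlap on the genome.

    A perfect-duplex mature exact-matches the minus strand of its own
    star arm, so one hairpin surfaces as two strand-mirrored hits; the
    first (plus-strand) locus is kept.
    """
    kept: list = []
    for item in found:
        iv = item[0]
        if any(
            iv.seq_id == other[0].seq_id
            and iv.start <= other[0].end
            and other[0].start <= iv.end
            for other in kept
        ):
            continue
        kept.append(item)
    return kept


# ---------------------------------------------------------------------------
# known miRNAs
# ---------------------------------------------------------------------------

def match_known(
    catalog: Catalog,
    reference_mirnas: Sequence[FastaRecord],
    config: PipelineConfig,
    genome: Sequence[FastaRecord] | None = None,
) -> list[MiRNALocus]:
    """Assign catalog sequences to known miRNAs (<= max mismatches).

    Each sequence goes to the reference entry with the fewest mismatches
    (ties broken by reference order).  When a genome is supplied, an
    assignment additionally requires a genomic locus whose flanking window
    folds into a hairpin containing the mature on a stem; loci at multiple
    genomic hits share the reference name with ``-1``, ``-2`` suffixes.
    """
    if not reference_mirnas:
        logger.warning("empty known-miRNA reference; no known assignments possible")
        return []
    genome_seqs = _genome_index(genome) if genome else {}
    loci: list[MiRNALocus] = []
    for seq, rec in catalog.items():
        if rec.annotation != "unannotated":
            continue
        best: tuple[int, int] | None = None  # (mismatches, reference index)
        for idx, ref in enumerate(reference_mirnas):
            d = mismatch_distance(seq, ref.sequence)
            if d is None or d > config.known_max_mismatch:
                continue
            if best is None or d < best[0]:
                best = (d, idx)
        if best is None:
            continue
        mismatches, idx = best
        ref = reference_mirnas[idx]

        if genome is None:
            rec.annotation = "known_miRNA"
            continue

        hit_loci = []
        for hit in rec.genome_hits:
            found = _best_hairpin_at(seq, hit, genome_seqs, catalog, config, require_star=False)
            if found is not None:
                hit_loci.append(found)
        if not hit_loci:
            continue
        hit_loci = _dedup_overlapping(hit_loci)
        rec.annotation = "known_miRNA"
        for n, (interval, pre_seq, offset, structure, metrics, star_seq) in enumerate(hit_loci, 1):
            suffix = f"-{n}" if len(hit_loci) > 1 else ""
            loci.append(
                MiRNALocus(
                    mirna_id=f"{ref.id}{suffix}",
                    mature_seq=seq,
                    status="known",
                    precursor_interval=interval,
                    precursor_seq=pre_seq,
                    structure=structure,
                    metrics=metrics,
                    mature_offset=offset,
                    arm=_arm_of(metrics, offset),
                    star_seq=star_seq or "",
                    reference_id=ref.id,
                    mismatches=mismatches,
                    per_library_tpm=dict(rec.per_library_tpm),
                )
            )
    logger.info("known-miRNA matching: %d loci", len(loci))
    return loci


_PAIRS_OK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _has_complement_region(mature: str, window: str, max_unpairable: int) -> bool:
    """Cheap pre-screen: does the window contain a near reverse complement
    of the mature (wobbles count as pairable)?  A hairpin satisfying the
    duplex criteria necessarily has one, so windows without it are skipped
    before the O(n^3) fold."""
    L = len(mature)
    reversed_mature = mature[::-1]
    for off in range(len(window) - L + 1):
        sub = window[off:off + L]
        bad = 0
        for a, b in zip(reversed_mature, sub):
            # a faces b antiparallel; pairable iff complementary or wobble
            if (a, b) not in _PAIRS_OK:
                bad += 1
                if bad > max_unpairable:
                    break
        else:
            return True
    return False


def _best_hairpin_at(
    seq: str,
    hit: GenomicInterval,
    genome_seqs: Mapping[str, str],
    catalog: Catalog,
    config: PipelineConfig,
    require_star: bool,
):
    """Best valid hairpin among the candidate windows at one genome hit.

    For known miRNAs only the stem-loop placement is required; novel calls
    additionally enforce the duplex criteria and star-read support.
    Returns (interval, precursor_seq, mature_offset, structure, metrics,
    star_seq) or None.
    """
    best = None
    for interval, pre_seq, offset in extract_precursor_windows(
        hit, genome_seqs, config.flank_for_precursor
    ):
        if require_star and not _has_complement_region(
            seq, pre_seq, config.max_duplex_mismatches + 2
        ):
            continue
        validated = _validate_hairpin(pre_seq, offset, len(seq), config)
        if validated is None:
            continue
        structure, metrics = validated
        if require_star:
            if metrics.duplex_mismatches > config.max_duplex_mismatches:
                continue
            if metrics.max_asym_bulge > config.max_asym_bulge:
                continue
        star_seq = _star_supported(pre_seq, metrics.star_interval, catalog)
        if require_star and star_seq is None:
            continue
        candidate = (interval, pre_seq, offset, structure, metrics, star_seq)
        if best is None or metrics.mature_paired_fraction > best[4].mature_paired_fraction:
            best = candidate
    return best


# ---------------------------------------------------------------------------
# novel miRNAs
# ---------------------------------------------------------------------------

def predict_novel(
    catalog: Catalog,
    genome: Sequence[FastaRecord],
    config: PipelineConfig,
    id_prefix: str = "csi-miRN",
) -> list[MiRNALocus]:
    """Call novel miRNA loci from unassigned genome-mapped reads.

    Candidates are unannotated 20-24 nt reads with >= 1 perfect genome
    hit.  A locus is accepted when one of the flanking windows folds into
    a hairpin with the mature on a stem, <= ``max_duplex_mismatches``
    unpaired mature bases, <= ``max_asym_bulge`` nt of duplex asymmetry,
    and a catalog read consistent with the star interval (+/- 1 nt).  A
    locus is called independently at each genomic hit; identical matures
    at several loci share one id with ``-1``, ``-2`` suffixes.
    """
    genome_seqs = _genome_index(genome)
    loci: list[MiRNALocus] = []
    next_serial = 1
    for seq, rec in catalog.items():
        if rec.annotation != "unannotated":
            continue
        if not (20 <= len(seq) <= 24) or not rec.genome_hits:
            continue
        accepted = []
        for hit in rec.genome_hits:
            found = _best_hairpin_at(seq, hit, genome_seqs, catalog, config, require_star=True)
            if found is not None:
                accepted.append(found)
        if not accepted:
            continue
        accepted = _dedup_overlapping(accepted)
        mirna_id = f"{id_prefix}{next_serial:02d}"
        next_serial += 1
        rec.annotation = "novel_miRNA"
        for n, (interval, pre_seq, offset, structure, metrics, star_seq) in enumerate(accepted, 1):
            suffix = f"-{n}" if len(accepted) > 1 else ""
            loci.append(
                MiRNALocus(
                    mirna_id=f"{mirna_id}{suffix}",
                    mature_seq=seq,
                    status="novel",
                    precursor_interval=interval,
                    precursor_seq=pre_seq,
                    structure=structure,
                    metrics=metrics,
                    mature_offset=offset,
                    arm=_arm_of(metrics, offset),
                    star_seq=star_seq,
                    per_library_tpm=dict(rec.per_library_tpm),
                )
            )
    logger.info("novel-miRNA prediction: %d loci", len(loci))
    return loci


# ---------------------------------------------------------------------------
# isoform pairs + genome distribution
# ---------------------------------------------------------------------------

def find_isoform_pairs(loci: Sequence[MiRNALocus]) -> list[IsoformPair]:
    """All pairs of mature loci sharing one precursor.

    Separation is the distance between the nearest ends of the two mature
    intervals on the precursor.
    """
    by_precursor: dict[tuple, list[MiRNALocus]] = {}
    for locus in loci:
        iv = locus.precursor_interval
        by_precursor.setdefault((iv.seq_id, iv.start, iv.end, iv.strand), []).append(locus)
    pairs = []
    for group in by_precursor.values():
        group = sorted(group, key=lambda l: l.mature_offset)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                separation = b.mature_offset - (a.mature_offset + len(a.mature_seq))
                pairs.append(IsoformPair(a, b, separation, (a.arm, b.arm)))
    return pairs


def genome_distribution(
    loci: Sequence[MiRNALocus], bin_size: int
) -> pd.DataFrame:
    """Pre-miRNA counts per chromosome bin, flagging co-located loci."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows: dict[tuple[str, int], list[str]] = {}
    for locus in loci:
        iv = locus.precursor_interval
        b = (iv.start - 1) // bin_size
        rows.setdefault((iv.seq_id, b), []).append(locus.mirna_id)
    out = [
        {
            "seq_id": seq_id,
            "bin_start_1based": b * bin_size + 1,
            "bin_end_1based": (b + 1) * bin_size,
            "n_loci": len(ids),
            "co_located": len(ids) > 1,
            "mirna_ids": ",".join(ids),
        }
        for (seq_id, b), ids in sorted(rows.items())
    ]
    return pd.DataFrame(
        out,
        columns=["seq_id", "bin_start_1based", "bin_end_1based", "n_loci", "co_located", "mirna_ids"],
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def loci_to_gff(loci: Sequence[MiRNALocus]) -> list[GffFeature]:
    feats = []
    for locus in loci:
        pre_id = f"{locus.mirna_id}_pre"
        feats.append(
            GffFeature(locus.precursor_interval, "miRNA_primary_transcript", pre_id,
                       name=pre_id)
        )
        feats.append(
            GffFeature(locus.mature_interval, "miRNA", locus.mirna_id,
                       name=locus.mirna_id, parent=pre_id)
        )
    return feats


def loci_table(loci: Sequence[MiRNALocus], libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        iv = locus.precursor_interval
        rows.append(
            {
                "mirna_id": locus.mirna_id,
                "status": locus.status,
                "arm": locus.arm,
                "mature_seq": locus.mature_seq,
                "star_seq": locus.star_seq,
                "reference_id": locus.reference_id,
                "mismatches": locus.mismatches,
                "seq_id": iv.seq_id,
                "pre_start": iv.start,
                "pre_end": iv.end,
                "strand": iv.strand,
                "precursor_length": locus.metrics.precursor_length,
                "loop_size": locus.metrics.loop_size,
                **{f"tpm_{lib}": round(locus.per_library_tpm.get(lib, 0.0), 3) for lib in libraries},
            }
        )
    return pd.DataFrame(rows)
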