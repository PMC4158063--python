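"""Small-RNA cataloguing: collapse, filter, annotate, map, normalize, compare.

The catalog is the central in-memory container for unique small-RNA
sequences with per-library counts, TPM values, genome hits and an
annotation state.  Accounting mirrors the standard sRNAome bookkeeping:
raw reads -> clean reads (quality + abundance filters) -> genome-matched,
with per-library statistics retained at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .core import GenomicInterval, revcomp
from .io import CollapsedRead, FastaRecord

logger = logging.getLogger(__name__)

ANNOTATIONS = ("unannotated", "ncRNA", "known_miRNA", "novel_miRNA", "phased_siRNA")


@dataclass
class SmallRNASeq:
    """A unique small-RNA sequence across libraries."""

    sequence: str
    per_library_count: dict[str, int] = field(default_factory=dict)
    per_library_tpm: dict[str, float] = field(default_factory=dict)
    genome_hits: list[GenomicInterval] = field(default_factory=list)
    annotation: str = "unannotated"

    def total_count(self) -> int:
        return sum(self.per_library_count.values())


@dataclass
class LibraryStats:
    library: str
    total_raw: int = 0
    total_clean: int = 0
    unique_clean: int = 0
    matched_genome_total: int = 0
    matched_genome_unique: int = 0
    length_histogram: dict[int, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "library": self.library,
            "raw_reads": self.total_raw,
            "clean_reads": self.total_clean,
            "unique_clean": self.unique_clean,
            "match_genome_total": self.matched_genome_total,
            "match_genome_total_pct": _pct(self.matched_genome_total, self.total_clean),
            "match_genome_unique": self.matched_genome_unique,
            "match_genome_unique_pct": _pct(self.matched_genome_unique, self.unique_clean),
        }


def _pct(part: int, whole: int) -> float:
    return round(100.0 * part / whole, 2) if whole else 0.0


Catalog = dict[str, SmallRNASeq]  # keyed by sequence, insertion-ordered


# ---------------------------------------------------------------------------
# collapse + filter
# ---------------------------------------------------------------------------

def collapse_and_filter(
    reads_by_library: Mapping[str, Iterable[CollapsedRead]],
    config: PipelineConfig,
) -> tuple[Catalog, dict[str, LibraryStats]]:
    """Collapse reads into a unique-sequence catalog and apply clean filters.

    Low-quality reads (containing N, or with length outside
    ``read_len_range``) are dropped entirely; a sequence is retained for a
    library only when its count there is >= ``min_read_count``.  A sequence
    survives if it is retained in at least one library.
    """
    if not reads_by_library:
        raise ValueError("at least one library of reads is required")
    lo, hi = config.read_len_range

    raw: dict[str, dict[str, int]] = {lib: {} for lib in reads_by_library}
    stats = {lib: LibraryStats(library=lib) for lib in reads_by_library}
    order: dict[str, None] = {}

    for lib, reads in reads_by_library.items():
        for read in reads:
            stats[lib].total_raw += read.count
            seq = read.sequence
            if "N" in seq or not (lo <= len(seq) <= hi):
                continue  # low-quality
            raw[lib][seq] = raw[lib].get(seq, 0) + read.count
            order.setdefault(seq, None)

    catalog: Catalog = {}
    for seq in order:
        counts = {
            lib: raw[lib][seq]
            for lib in reads_by_library
            if raw[lib].get(seq, 0) >= config.min_read_count
        }
        if counts:
            catalog[seq] = SmallRNASeq(sequence=seq, per_library_count=counts)

    for lib in reads_by_library:
        retained = [
            (seq, rec.per_library_count[lib])
            for seq, rec in catalog.items()
            if lib in rec.per_library_count
        ]
        st = stats[lib]
        st.total_clean = sum(c for _, c in retained)
        st.unique_clean = len(retained)
        if retained:
            lengths = pd.Series([len(seq) for seq, _ in retained])
            st.length_histogram = (
                lengths.value_counts(normalize=True).sort_index().to_dict()
            )
        logger.info(
            "library %s: %d raw reads -> %d clean (%d unique)",
            lib, st.total_raw, st.total_clean, st.unique_clean,
        )
    return catalog, stats


# ---------------------------------------------------------------------------
# ncRNA exclusion
# ---------------------------------------------------------------------------

def annotate_ncrna(catalog: Catalog, ncrna: Sequence[FastaRecord]) -> int:
    """Flag catalog sequences occurring as exact substrings of any reference
    ncRNA (either strand).  Returns the number of sequences flagged."""
    if not ncrna:
        return 0
    haystacks = [rec.sequence for rec in ncrna]
    flagged = 0
    for seq, rec in catalog.items():
        rc = revcomp(seq)
        if any(seq in h or rc in h for h in haystacks):
            rec.annotation = "ncRNA"
            flagged += 1
    logger.info("ncRNA exclusion: %d of %d sequences flagged", flagged, len(catalog))
    return flagged


# ---------------------------------------------------------------------------
# genome mapping
# ---------------------------------------------------------------------------

def map_to_genome(
    catalog: Catalog,
    genome: Sequence[FastaRecord],
    stats: dict[str, LibraryStats] | None = None,
) -> None:
    """Record exact-match genome hits (both strands) for every sequence.

    Multi-mapping sequences keep all hits.  When ``stats`` is given, the
    per-library matched totals and unique-match counts are filled in
    ('match genome' accounting semantics: a read matches if it has >= 1
    perfect hit anywhere).
    """
    for rec in catalog.values():
        rec.genome_hits = []
        for chrom in genome:
            for strand, query in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
                start = chrom.sequence.find(query)
                while start >= 0:
                    rec.genome_hits.append(
                        GenomicInterval.from_zero_based(
                            chrom.id, start, start + len(query), strand
                        )
                    )
                    start = chrom.sequence.find(query, start + 1)
    if stats is not None:
        for lib, st in stats.items():
            matched = [
                rec for rec in catalog.values()
                if lib in rec.per_library_count and rec.genome_hits
            ]
            st.matched_genome_unique = len(matched)
            st.matched_genome_total = sum(r.per_library_count[lib] for r in matched)
            logger.info(
                "library %s: %d/%d unique sequences match the genome",
                lib, st.matched_genome_unique, st.unique_clean,
            )


# ---------------------------------------------------------------------------
# TPM normalization
# ---------------------------------------------------------------------------

def tpm_normalize(catalog: Catalog, stats: Mapping[str, LibraryStats]) -> None:
    """tpm = count / total_clean * 1e6, per library."""
    for lib, st in stats.items():
        if st.total_clean == 0:
            if any(lib in rec.per_library_count for rec in catalog.values()):
                raise ZeroDivisionError(
                    f"library {lib!r} has clean total 0; TPM is undefined"
                )
            continue
        scale = 1e6 / st.total_clean
        for rec in catalog.values():
            if lib in rec.per_library_count:
                rec.per_library_tpm[lib] = rec.per_library_count[lib] * scale


# ---------------------------------------------------------------------------
# tissue comparison
# ---------------------------------------------------------------------------

def compare_tissues(
    catalog: Catalog,
    tissues: Sequence[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-sequence fold-change classification across tissues.

    For each tissue the fold change is TPM(tissue) / max(TPM of the other
    tissues), with a pseudocount applied to the denominator.  Classes:
    ``enriched_in`` (> fold_change_threshold), ``strongly_enriched``
    (> strong threshold), ``absent_in`` (TPM 0 there, > 0 elsewhere; takes
    precedence over enrichment), ``highly_expressed`` (max TPM > 10).
    """
    if len(tissues) < 2:
        raise ValueError("tissue comparison requires at least two tissues")
    pseudo = config.tpm_pseudocount
    rows = []
    for seq, rec in catalog.items():
        tpm = {t: rec.per_library_tpm.get(t, 0.0) for t in tissues}
        absent = [t for t in tissues if tpm[t] == 0.0 and any(v > 0 for v in tpm.values())]
        enriched = None
        strongly = False
        fold = {}
        for t in tissues:
            others = max(tpm[o] for o in tissues if o != t)
            fc = tpm[t] / max(others, pseudo)
            fold[t] = fc
        best = max(tissues, key=lambda t: fold[t])
        if fold[best] > config.fold_change_threshold and best not in absent:
            enriched = best
            strongly = fold[best] > config.strong_fold_change_threshold
        rows.append(
            {
                "sequence": seq,
                **{f"tpm_{t}": tpm[t] for t in tissues},
                **{f"fold_{t}": fold[t] for t in tissues},
                "enriched_in": enriched or "",
                "strongly_enriched": strongly,
                "absent_in": ",".join(absent),
                "highly_expressed": max(tpm.values()) > config.high_tpm_threshold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def catalog_table(catalog: Catalog, libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for seq, rec in catalog.items():
        rows.append(
            {
                "sequence": seq,
                "length": len(seq),
                "annotation": rec.annotation,
                "genome_hits": len(rec.genome_hits),
                **{f"count_{lib}": rec.per_library_count.get(lib, 0) for lib in libraries},
                **{f"tpm_{lib}": round(rec.per_library_tpm.get(lib, 0.0), 3) for lib in libraries},
            }
        )
    return pd.DataFrame(rows)


def stats_table(stats: Mapping[str, LibraryStats]) -> pd.DataFrame:
    return pd.DataFrame([st.as_row() for st in stats.values()])


def length_table(stats: Mapping[str, LibraryStats]) -> pd.DataFrame:
    rows = []
    for lib, st in stats.items():
        for length, frac in sorted(st.length_histogram.items()):
            rows.append({"library": lib, "length": length, "unique_fraction": frac})
    return pd.DataFrame(rows)
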