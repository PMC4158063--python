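"""Readers and writers for the on-disk formats the pipeline touches.

Formats: FASTA (plain and count-collapsed small-RNA dialects), GFF3 for
miRNA loci, BED6, and tab-separated report tables.  Persisted coordinates
are 1-based inclusive throughout.

FASTA parsing is strict by design: the error contract names the offending
line, which generic parsers do not surface, so the reader is implemented
here rather than delegated.  Writing goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .core import FormatError, GenomicInterval, canonical


@dataclass
class FastaRecord:
    id: str
    description: str
    sequence: str  # canonical DNA, upper case


@dataclass
class CollapsedRead:
    """A deduplicated small-RNA sequence with its occurrence count."""

    sequence: str
    count: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file into canonical-DNA records, preserving order.

    U and T are treated as equivalent (stored as T); case is folded.
    Malformed headers or empty sequences raise :class:`FormatError`
    naming the line number.  An empty file yields zero records.
    """
    records: list[FastaRecord] = []
    header_line = 0
    ident = ""
    desc = ""
    chunks: list[str] = []
    in_record = False

    def _flush() -> None:
        if not in_record:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence for record starting at line {header_line}")
        try:
            records.append(FastaRecord(ident, desc, canonical(seq)))
        except ValueError as exc:
            raise FormatError(f"{path}: record at line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                head = line[1:].strip()
                if not head:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                parts = head.split(None, 1)
                ident = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                header_line = lineno
                in_record = True
            else:
                if not in_record:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                chunks.append(line.strip())
    _flush()
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, rna: bool = False) -> None:
    seqs = []
    for rec in records:
        s = rec.sequence.replace("T", "U") if rna else rec.sequence
        seqs.append(SeqRecord(Seq(s), id=rec.id, description=rec.description))
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Collapsed small-RNA FASTA
# ---------------------------------------------------------------------------

def _parse_count(header_id: str, description: str) -> int | None:
    """Two accepted dialects: trailing ``_xN`` in the id, or ``count=N``."""
    if "_x" in header_id:
        tail = header_id.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    for token in description.split():
        if token.startswith("count="):
            value = token[len("count="):]
            if value.isdigit():
                return int(value)
    return None


def read_collapsed_srna(path: str | Path) -> list[CollapsedRead]:
    """Read a collapsed small-RNA FASTA (headers carry read counts).

    Duplicate sequences are merged by summing their counts; first-seen
    order is preserved.  A header without a parsable count is a
    :class:`FormatError`.
    """
    merged: dict[str, int] = {}
    for rec in read_fasta(path):
        count = _parse_count(rec.id, rec.description)
        if count is None or count < 1:
            raise FormatError(
                f"{path}: header {rec.id!r} carries no parsable read count "
                "(expected id_xN or 'count=N')"
            )
        merged[rec.sequence] = merged.get(rec.sequence, 0) + count
    return [CollapsedRead(seq, n) for seq, n in merged.items()]


def write_collapsed_srna(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads, start=1):
            fh.write(f">t{i}_x{read.count}\n{read.sequence}\n")


# ---------------------------------------------------------------------------
# GFF3 for miRNA loci
# ---------------------------------------------------------------------------

@dataclass
class GffFeature:
    interval: GenomicInterval
    feature_type: str  # miRNA_primary_transcript | miRNA
    feature_id: str
    name: str = ""
    parent: str = ""
    attributes: dict[str, str] = field(default_factory=dict)


_GFF_HEADER = "##gff-version 3"


def write_gff3(
    features: Sequence[GffFeature],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Serialize miRNA features to GFF3 (1-based inclusive columns 4/5).

    If ``seq_lengths`` is given, intervals outside their sequence raise
    ``ValueError``.
    """
    lines = [_GFF_HEADER]
    for feat in features:
        iv = feat.interval
        if seq_lengths is not None:
            length = seq_lengths.get(iv.seq_id)
            if length is not None and iv.end > length:
                raise ValueError(
                    f"interval {iv.seq_id}:{iv.start}-{iv.end} exceeds sequence length {length}"
                )
        attrs = {"ID": feat.feature_id}
        if feat.name:
            attrs["Name"] = feat.name
        if feat.parent:
            attrs["Parent"] = feat.parent
        attrs.update(feat.attributes)
        attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
        lines.append(
            "\t".join(
                [
                    iv.seq_id,
                    "srdk",
                    feat.feature_type,
                    str(iv.start),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    attr_str,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns at line {lineno}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                GffFeature(
                    interval=GenomicInterval(cols[0], int(cols[3]), int(cols[4]), cols[6]),
                    feature_type=cols[2],
                    feature_id=attrs.pop("ID", ""),
                    name=attrs.pop("Name", ""),
                    parent=attrs.pop("Parent", ""),
                    attributes=attrs,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(
    intervals: Sequence[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score) triples as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            start0, end0 = iv.to_zero_based()
            fh.write(f"{iv.seq_id}\t{start0}\t{end0}\t{name}\t{score:g}\t{iv.strand}\n")


def read_bed6(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}: expected 6 BED columns at line {lineno}")
            iv = GenomicInterval.from_zero_based(cols[0], int(cols[1]), int(cols[2]), cols[5])
            out.append((iv, cols[3], float(cols[4])))
    return out


# ---------------------------------------------------------------------------
# TSV report tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
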