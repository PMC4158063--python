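"""Shared primitives: coordinates, sequence alphabet handling.

All persisted coordinates are 1-based inclusive (GFF3 convention); all
in-memory arithmetic uses 0-based half-open offsets.  ``GenomicInterval``
stores the persisted convention and offers explicit conversions so the two
never mix silently.

The canonical in-memory alphabet is DNA (T, upper case).  RNA input (U) is
converted on read; RNA display strings are produced on write.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_DNA = str.maketrans("Uu", "Tt")
VALID_CHARS = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U,N}."""


def canonical(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA (U -> T).

    Raises :class:`AlphabetError` on any character outside the
    {A,C,G,T,U,N} alphabet (case-insensitive).
    """
    s = seq.translate(_TO_DNA).upper()
    bad = set(s) - VALID_CHARS
    if bad:
        raise AlphabetError(f"illegal characters in sequence: {sorted(bad)!r}")
    return s


def to_rna(seq: str) -> str:
    """Render a canonical DNA string in the RNA alphabet (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval, 1-based inclusive on both ends."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    # -- conversions ------------------------------------------------------
    @classmethod
    def from_zero_based(
        cls, seq_id: str, start0: int, end0: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from a 0-based half-open [start0, end0) span."""
        return cls(seq_id, start0 + 1, end0, strand)

    def to_zero_based(self) -> tuple[int, int]:
        """Return the 0-based half-open (start, end) of this interval."""
        return self.start - 1, self.end

    # -- relations --------------------------------------------------------
    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        """Overlap by >= 1 nt; by default strands must agree."""
        if self.seq_id != other.seq_id:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )
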