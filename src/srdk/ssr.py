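"""Simple sequence repeat (SSR) detection and pre-miRNA co-localization.

Detects maximal tandem repeats of 1-6 nt units subject to MISA-like
per-unit-length minimum repeat numbers, intersects them with pre-miRNA
loci (>= 1 nt overlap, same strand), and summarizes repeat-unit
composition.  Units are reported on the given strand without
canonicalization (CT, TC, GA, AG are distinct), and nested reports are
suppressed: a run is attributed to its smallest period, so a (CTCT)n run
reports unit CT, never CTCT.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .core import GenomicInterval

UNIT_CLASSES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
CLASS_ORDER = ("mono", "di", "tri", "tetra", "penta", "hexa")


@dataclass(frozen=True)
class SSRLocus:
    interval: GenomicInterval
    unit: str
    repeat_number: int

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeat_number

    @property
    def unit_class(self) -> str:
        return UNIT_CLASSES[len(self.unit)]


def _is_periodic(unit: str) -> bool:
    """True when the unit is itself a repetition of a shorter unit."""
    return unit in (unit + unit)[1:-1]


def detect_ssrs(
    sequence: str,
    min_repeats_by_unit_len: Mapping[int, int],
    seq_id: str = "seq",
    strand: str = "+",
) -> list[SSRLocus]:
    """All maximal tandem repeats meeting the per-unit-length thresholds.

    Maximality is over full units: a reported repeat cannot be extended by
    one more unit copy on either side.  Overlap resolution follows
    smallest-unit priority, then leftmost start.
    """
    n = len(sequence)
    found: list[SSRLocus] = []
    claimed: list[tuple[int, int]] = []  # spans already attributed to a smaller unit
    for u in sorted(min_repeats_by_unit_len):
        min_rep = min_repeats_by_unit_len[u]
        i = 0
        while i + u * min_rep <= n:
            unit = sequence[i:i + u]
            if "N" in unit or _is_periodic(unit):
                i += 1
                continue
            # left-maximality: a full unit copy must not precede
            if i >= u and sequence[i - u:i] == unit:
                i += 1
                continue
            reps = 1
            while sequence[i + reps * u:i + (reps + 1) * u] == unit:
                reps += 1
            if reps >= min_rep:
                span = (i, i + reps * u)
                if not any(a <= span[0] and span[1] <= b for a, b in claimed):
                    found.append(
                        SSRLocus(
                            GenomicInterval.from_zero_based(seq_id, span[0], span[1], strand),
                            unit,
                            reps,
                        )
                    )
                    claimed.append(span)
                i += reps * u
            else:
                i += 1
    found.sort(key=lambda s: (s.interval.start, len(s.unit)))
    return found


def detect_ssrs_genome(
    chrom_id: str,
    sequence: str,
    min_repeats_by_unit_len: Mapping[int, int],
    both_strands: bool = False,
) -> list[SSRLocus]:
    """Scan one chromosome; optionally also report minus-strand units.

    Minus-strand loci cover the same genomic span with the reverse
    complement unit, so plus-only scanning is the default (a tandem repeat
    is tandem on both strands).
    """
    out = detect_ssrs(sequence, min_repeats_by_unit_len, seq_id=chrom_id, strand="+")
    if both_strands:
        from .core import revcomp

        n = len(sequence)
        for ssr in detect_ssrs(revcomp(sequence), min_repeats_by_unit_len, seq_id=chrom_id):
            s0, e0 = ssr.interval.to_zero_based()
            out.append(
                SSRLocus(
                    GenomicInterval.from_zero_based(chrom_id, n - e0, n - s0, "-"),
                    ssr.unit,
                    ssr.repeat_number,
                )
            )
    return out


# ---------------------------------------------------------------------------
# co-localization with pre-miRNA loci
# ---------------------------------------------------------------------------

def colocalize(
    ssrs: Sequence[SSRLocus],
    pre_mirna_loci: Sequence[tuple[str, GenomicInterval]],
) -> pd.DataFrame:
    """SSR occurrences overlapping a precursor by >= 1 nt on the same strand.

    One output row per (SSR occurrence, precursor) pair; the distinct
    precursors hit can be read off the ``precursor_id`` column.
    """
    rows = []
    for ssr in ssrs:
        for locus_id, iv in pre_mirna_loci:
            if ssr.interval.overlaps(iv, same_strand=True):
                rows.append(
                    {
                        "seq_id": ssr.interval.seq_id,
                        "ssr_start": ssr.interval.start,
                        "ssr_end": ssr.interval.end,
                        "strand": ssr.interval.strand,
                        "unit": ssr.unit,
                        "unit_class": ssr.unit_class,
                        "repeat_number": ssr.repeat_number,
                        "length": ssr.length,
                        "precursor_id": locus_id,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "ssr_start", "ssr_end", "strand", "unit", "unit_class",
            "repeat_number", "length", "precursor_id",
        ],
    )


# ---------------------------------------------------------------------------
# repeat-unit composition summary
# ---------------------------------------------------------------------------

def load_unit_counts(path=None) -> pd.DataFrame:
    """Load a (unit, unit_class, count) table.

    Without a path, loads the bundled repeat-unit frequency table for SSRs
    co-localized with sweet-orange pre-miRNAs (published survey counts).
    """
    if path is None:
        ref = resources.files("srdk.data").joinpath("ssr_premirna_units.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def summarize_units(occurrences: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-unit occurrence counts plus composition statistics.

    ``occurrences`` is either a co-localization table (one row per
    occurrence, with ``unit``/``unit_class`` columns) or an aggregated
    (unit, unit_class, count) table.  Composition percentages are rounded
    to one decimal.  Empty input yields an empty table and
    ``{'undefined': True}``.
    """
    if occurrences.empty:
        return pd.DataFrame(columns=["unit", "unit_class", "count"]), {"undefined": True}
    if "count" in occurrences.columns:
        table = occurrences[["unit", "unit_class", "count"]].copy()
        table = table.groupby(["unit", "unit_class"], as_index=False)["count"].sum()
    else:
        table = (
            occurrences.groupby(["unit", "unit_class"])
            .size()
            .reset_index(name="count")
        )
    table["_class_rank"] = table["unit_class"].map({c: i for i, c in enumerate(CLASS_ORDER)})
    table = (
        table.sort_values(["_class_rank", "unit"])
        .drop(columns="_class_rank")
        .reset_index(drop=True)
    )
    total = int(table["count"].sum())
    by_class = table.groupby("unit_class")["count"].sum().to_dict()
    modal = table.loc[table["count"].idxmax()]
    stats = {
        "undefined": False,
        "total": total,
        "by_class": {c: int(by_class.get(c, 0)) for c in CLASS_ORDER},
        "composition_pct": {
            c: round(100.0 * by_class.get(c, 0) / total, 1) for c in CLASS_ORDER
        },
        "modal_unit": str(modal["unit"]),
        "modal_count": int(modal["count"]),
    }
    return table, stats


def composition_share(stats: dict, classes: Sequence[str]) -> float:
    """Composition percentage of a subset of unit classes (1 decimal)."""
    if stats.get("undefined"):
        raise ValueError("composition undefined for empty input")
    subset = sum(stats["by_class"][c] for c in classes)
    return round(100.0 * subset / stats["total"], 1)
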