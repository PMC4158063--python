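"""Degradome (PARE) target calling.

Degradome tags are 20-nt 5'-end signatures of uncapped mRNA fragments; a
tag's 5' position marks a candidate RISC cleavage site.  The module maps
tags onto transcripts (T-plots), aligns miRNAs to transcripts with a
plant-style complementarity penalty, validates cleavage at the site
opposite miRNA position 10/11, and assigns the standard confidence
categories:

* category I  — the cleavage tag is the unique most-abundant tag on the
  transcript,
* category II — not the maximum but still a clear peak (>= ``peak_fraction``
  of the maximum; a shared maximum also falls here),
* category III — everything else with >= 1 tag at the site.

Penalty scheme (CleaveLand-style): mismatch 1.0, G:U wobble 0.5, gap 2.0,
all doubled at miRNA positions 2-13 (5'-counted).  Default cutoff 7.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import revcomp
from .io import CollapsedRead, FastaRecord

logger = logging.getLogger(__name__)

CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled weight

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
# miRNA base -> target base forming a G:U wobble (RNA G:U == DNA G:T)
_WOBBLE = {"G": "T", "T": "G"}


@dataclass
class TPlot:
    """Per-transcript profile of degradome tag 5'-end abundances."""

    transcript_id: str
    position_counts: np.ndarray

    @property
    def total_tags(self) -> int:
        return int(self.position_counts.sum())


@dataclass
class TargetCall:
    mirna_id: str
    transcript_id: str
    alignment: str
    penalty: float
    cleavage_site: int  # 0-based transcript position of the 3'-fragment 5' end
    cleavage_count: int
    category: str
    library: str
    site_start: int = 0  # 0-based start of the binding window on the transcript
    trigger_id: str = ""  # provenance when the query is a phased siRNA

    def as_row(self) -> dict:
        return {
            "mirna_id": self.mirna_id,
            "transcript_id": self.transcript_id,
            "library": self.library,
            "penalty": self.penalty,
            "cleavage_site_1based": self.cleavage_site + 1,
            "cleavage_count": self.cleavage_count,
            "category": self.category,
            "alignment": self.alignment,
            "trigger_id": self.trigger_id,
        }


# ---------------------------------------------------------------------------
# T-plots
# ---------------------------------------------------------------------------

def build_tplot(
    degradome_tags: Iterable[CollapsedRead],
    transcripts: Sequence[FastaRecord],
) -> dict[str, TPlot]:
    """Map tags exactly onto transcript sense strands.

    Every exact occurrence of a tag increments the T-plot of that
    transcript at the tag's 5' position; a tag matching several
    transcripts is counted in each.
    """
    tplots = {
        t.id: TPlot(t.id, np.zeros(len(t.sequence), dtype=np.int64))
        for t in transcripts
    }
    for tag in degradome_tags:
        for t in transcripts:
            pos = t.sequence.find(tag.sequence)
            while pos >= 0:
                tplots[t.id].position_counts[pos] += tag.count
                pos = t.sequence.find(tag.sequence, pos + 1)
    return tplots


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------

def score_alignment(mirna_seq: str, site_seq: str) -> tuple[float, str]:
    """Score an ungapped miRNA/target duplex.

    ``site_seq`` is the transcript window (sense strand, 5'->3') that the
    miRNA binds antiparallel, so miRNA position 1 (its 5' end) faces the
    window's 3'-most base.  The alignment string marks each miRNA position
    '|' (Watson-Crick), 'o' (G:U wobble) or 'x' (mismatch), 5'->3'.
    """
    if len(mirna_seq) != len(site_seq):
        raise ValueError("ungapped alignment requires equal lengths")
    penalty = 0.0
    marks = []
    # target base opposite miRNA position p (1-based): site_seq reversed
    opposite = site_seq[::-1]
    for p, (m, t) in enumerate(zip(mirna_seq, opposite), start=1):
        if _COMP.get(m) == t:
            cost, mark = 0.0, "|"
        elif _WOBBLE.get(m) == t:
            cost, mark = WOBBLE_PENALTY, "o"
        else:
            cost, mark = MISMATCH_PENALTY, "x"
        if CORE_START <= p <= CORE_END:
            cost *= 2
        penalty += cost
        marks.append(mark)
    return penalty, "".join(marks)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_penalties(mirna: str, transcript: str) -> np.ndarray:
    """Penalty of every ungapped binding window along a transcript.

    Returns an array of length ``len(transcript) - len(mirna) + 1`` where
    entry w scores the window starting at w (vectorized equivalent of
    :func:`score_alignment` over all windows).
    """
    L = len(mirna)
    n = len(transcript)
    if n < L:
        return np.empty(0)
    tcodes = _encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(tcodes, L)
    # miRNA position p (1-based) faces window column L - p
    weights = np.array(
        [2.0 if CORE_START <= p <= CORE_END else 1.0 for p in range(1, L + 1)]
    )
    penalties = np.zeros(windows.shape[0])
    for p in range(1, L + 1):
        m = mirna[p - 1]
        col = windows[:, L - p]
        comp = col == ord(_COMP[m]) if m in _COMP else np.zeros(len(col), bool)
        wob = col == ord(_WOBBLE[m]) if m in _WOBBLE else np.zeros(len(col), bool)
        cost = np.where(comp, 0.0, np.where(wob, WOBBLE_PENALTY, MISMATCH_PENALTY))
        penalties += cost * weights[p - 1]
    return penalties


# ---------------------------------------------------------------------------
# category classification
# ---------------------------------------------------------------------------

def classify_category(tplot: TPlot, cleavage_site: int, peak_fraction: float = 0.5) -> str:
    """Assign I/II/III from the T-plot profile at a validated site."""
    counts = tplot.position_counts
    maximum = int(counts.max()) if counts.size else 0
    if maximum == 0:
        raise ValueError(f"transcript {tplot.transcript_id}: all-zero T-plot, no evidence")
    site_count = int(counts[cleavage_site])
    if site_count < 1:
        raise ValueError("cleavage site carries no tag; classification undefined")
    unique_max = site_count == maximum and int((counts == maximum).sum()) == 1
    if unique_max:
        return "I"
    if site_count >= peak_fraction * maximum:
        return "II"
    return "III"


# ---------------------------------------------------------------------------
# target calling
# ---------------------------------------------------------------------------

def call_targets(
    mirnas: Mapping[str, str],
    tplots: Mapping[str, TPlot],
    transcripts: Sequence[FastaRecord],
    config: PipelineConfig,
    library: str = "",
    trigger_of: Mapping[str, str] | None = None,
) -> list[TargetCall]:
    """Call degradome-validated targets for a set of query small RNAs.

    For every query x transcript window with penalty <= threshold, the
    predicted cleavage site is the transcript position opposite the bond
    between miRNA positions 10 and 11 (the 5' end of the 3' fragment).  A
    call is emitted iff the T-plot carries >= 1 tag within +/- 1 nt of
    that site (the reported site is the max-count position in the window,
    accommodating 10th-vs-11th-nucleotide ambiguity).
    """
    calls: list[TargetCall] = []
    for mirna_id, mirna_seq in mirnas.items():
        L = len(mirna_seq)
        for t in transcripts:
            tplot = tplots.get(t.id)
            if tplot is None or tplot.total_tags == 0:
                continue
            penalties = _scan_penalties(mirna_seq, t.sequence)
            for w in np.flatnonzero(penalties <= config.penalty_threshold):
                w = int(w)
                predicted = w + L - 10  # opposite miRNA position 10, 0-based
                lo = max(0, predicted - config.cleavage_window)
                hi = min(len(t.sequence), predicted + config.cleavage_window + 1)
                if lo >= hi:
                    continue
                window_counts = tplot.position_counts[lo:hi]
                if window_counts.max() < 1:
                    continue
                site = lo + int(window_counts.argmax())
                penalty, alignment = score_alignment(mirna_seq, t.sequence[w:w + L])
                calls.append(
                    TargetCall(
                        mirna_id=mirna_id,
                        transcript_id=t.id,
                        alignment=alignment,
                        penalty=penalty,
                        cleavage_site=site,
                        cleavage_count=int(tplot.position_counts[site]),
                        category=classify_category(tplot, site, config.peak_fraction),
                        library=library,
                        site_start=w,
                        trigger_id=(trigger_of or {}).get(mirna_id, ""),
                    )
                )
    logger.info("library %s: %d target calls for %d queries", library, len(calls), len(mirnas))
    return calls


def calls_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in calls])


def category_summary(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Targets per category per library (distinct miRNA-transcript pairs)."""
    if not calls:
        return pd.DataFrame(columns=["library", "category", "n_targets"])
    df = calls_table(calls)
    return (
        df.drop_duplicates(["mirna_id", "transcript_id", "library", "category"])
        .groupby(["library", "category"])
        .size()
        .reset_index(name="n_targets")
    )
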