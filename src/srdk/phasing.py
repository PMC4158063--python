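"""Phased secondary-siRNA (phasiRNA) prediction.

22-nt miRNAs loaded into AGO1 can convert their cleaved targets into
substrates for RDR6/DCL4, which releases 21-nt siRNAs in exact 21-nt
registers running from the cleavage site toward the transcript 3' end.
This module selects candidate triggers (length 22, optionally 5' U, with
degradome-validated cleavage), enumerates the register windows, quantifies
them against the small-RNA catalog, names them
``<trigger>-<transcript>-<k>``, and feeds the supported phasiRNAs back
through the degradome machinery to call their own targets.  Transcripts
spawning several supported registers and lacking coding annotation are
flagged as candidate TAS genes.

Register 1 starts at the first nucleotide of the 3' cleavage fragment;
only exact 21-nt sense-strand matches count as support (near-phased reads
are reported in diagnostics only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalog import Catalog
from .config import PipelineConfig
from .degradome import TargetCall, TPlot, call_targets
from .io import FastaRecord

logger = logging.getLogger(__name__)


@dataclass
class PhasedSiRNA:
    name: str
    trigger_id: str
    transcript_id: str
    k: int  # phase index, 1-based
    window: tuple[int, int]  # 0-based half-open transcript span, length 21
    sequence: str
    per_library_tpm: dict[str, float] = field(default_factory=dict)
    supported: bool = False

    def __post_init__(self) -> None:
        if self.window[1] - self.window[0] != len(self.sequence):
            raise ValueError("window length must equal sequence length")
        if self.k < 1:
            raise ValueError("phase index k must be >= 1")


def make_name(trigger_id: str, transcript_id: str, k: int) -> str:
    return f"{trigger_id}-{transcript_id}-{k}"


def parse_name(name: str, trigger_ids: Sequence[str] | None = None) -> tuple[str, str, int]:
    """Invert :func:`make_name`.

    Trigger ids may themselves contain hyphens (csi-miR...), so when
    ``trigger_ids`` is supplied the longest matching trigger prefix wins;
    otherwise the split assumes a hyphen-free transcript id.
    """
    stem, _, k_str = name.rpartition("-")
    if not k_str.isdigit():
        raise ValueError(f"phasiRNA name {name!r} does not end in a phase index")
    k = int(k_str)
    if trigger_ids:
        for trig in sorted(trigger_ids, key=len, reverse=True):
            if stem.startswith(trig + "-"):
                return trig, stem[len(trig) + 1:], k
        raise ValueError(f"no known trigger id prefixes {name!r}")
    trigger, _, transcript = stem.rpartition("-")
    if not trigger or not transcript:
        raise ValueError(f"cannot split phasiRNA name {name!r}")
    return trigger, transcript, k


# ---------------------------------------------------------------------------
# trigger selection
# ---------------------------------------------------------------------------

def select_triggers(
    mirnas: Mapping[str, str],
    target_calls: Sequence[TargetCall],
    config: PipelineConfig,
) -> dict[str, str]:
    """Candidate phasing triggers among identified miRNAs.

    Criteria: mature length exactly ``trigger_length`` (22 nt), a 5'
    uridine when ``require_trigger_5pU``, and at least one
    degradome-validated target call.
    """
    validated = {c.mirna_id for c in target_calls}
    triggers = {}
    for mirna_id, seq in mirnas.items():
        if len(seq) != config.trigger_length:
            continue
        if config.require_trigger_5pU and not seq.startswith("T"):
            continue
        if mirna_id not in validated:
            continue
        triggers[mirna_id] = seq
    logger.info("%d phasing trigger(s) selected from %d miRNAs", len(triggers), len(mirnas))
    return triggers


# ---------------------------------------------------------------------------
# register enumeration + quantification
# ---------------------------------------------------------------------------

def enumerate_phases(
    transcript_seq: str,
    cleavage_site: int,
    phase_length: int = 21,
    phase_offset: int = 0,
) -> list[tuple[int, int]]:
    """Ordered full-length register windows on the 3' cleavage fragment.

    Window k (1-based) spans [c + L*(k-1), c + L*k) where c is the 0-based
    cleavage site (first nucleotide of the 3' fragment) plus any configured
    offset.  Only complete windows are returned.
    """
    if not (0 <= cleavage_site < len(transcript_seq)):
        raise ValueError("cleavage_site outside the transcript")
    start = cleavage_site + phase_offset
    windows = []
    while start + phase_length <= len(transcript_seq):
        windows.append((start, start + phase_length))
        start += phase_length
    return windows


def quantify_phases(
    trigger_id: str,
    transcript: FastaRecord,
    cleavage_site: int,
    catalog: Catalog,
    config: PipelineConfig,
) -> list[PhasedSiRNA]:
    """Quantify every register window against the small-RNA catalog.

    A phase is *supported* iff a catalog sequence exactly equals the
    window's sense-strand sequence; TPM values are copied per library.
    Unsupported phases are retained (``supported=False``) for diagnostics
    but excluded from the main report.
    """
    phases = []
    for k, (a, b) in enumerate(
        enumerate_phases(transcript.sequence, cleavage_site, config.phase_length),
        start=1,
    ):
        window_seq = transcript.sequence[a:b]
        rec = catalog.get(window_seq)
        phase = PhasedSiRNA(
            name=make_name(trigger_id, transcript.id, k),
            trigger_id=trigger_id,
            transcript_id=transcript.id,
            k=k,
            window=(a, b),
            sequence=window_seq,
            supported=rec is not None,
        )
        if rec is not None:
            phase.per_library_tpm = dict(rec.per_library_tpm)
            rec.annotation = "phased_siRNA"
        phases.append(phase)
    return phases


def predict_phasirnas(
    triggers: Mapping[str, str],
    target_calls: Sequence[TargetCall],
    transcripts: Sequence[FastaRecord],
    catalog: Catalog,
    config: PipelineConfig,
) -> list[PhasedSiRNA]:
    """Run register enumeration + quantification at every validated
    cleavage site of every trigger."""
    by_id = {t.id: t for t in transcripts}
    seen: set[tuple[str, str, int]] = set()
    out: list[PhasedSiRNA] = []
    for call in target_calls:
        if call.mirna_id not in triggers:
            continue
        key = (call.mirna_id, call.transcript_id, call.cleavage_site)
        if key in seen:
            continue
        seen.add(key)
        out.extend(
            quantify_phases(
                call.mirna_id, by_id[call.transcript_id], call.cleavage_site,
                catalog, config,
            )
        )
    return out


# ---------------------------------------------------------------------------
# phasiRNA target calling + TAS candidates
# ---------------------------------------------------------------------------

def call_phasi_targets(
    phased_sirnas: Sequence[PhasedSiRNA],
    tplots: Mapping[str, TPlot],
    transcripts: Sequence[FastaRecord],
    config: PipelineConfig,
    library: str = "",
) -> list[TargetCall]:
    """Call degradome targets of supported phasiRNAs (same contract as
    miRNA target calling), annotated with trigger provenance."""
    queries = {p.name: p.sequence for p in phased_sirnas if p.supported}
    trigger_of = {p.name: p.trigger_id for p in phased_sirnas if p.supported}
    return call_targets(
        queries, tplots, transcripts, config, library=library, trigger_of=trigger_of
    )


def flag_candidate_tas(
    triggers: Mapping[str, str],
    phased_sirnas: Sequence[PhasedSiRNA],
    coding_status: Mapping[str, str] | None = None,
    min_registers: int = 3,
) -> pd.DataFrame:
    """Flag transcripts behaving like TAS genes.

    A transcript qualifies iff (a) it is targeted by a selected trigger
    (i.e. spawns register windows here), (b) it has >= ``min_registers``
    supported registers, and (c) its coding status is 'non_coding' or
    'unannotated' (missing from ``coding_status`` counts as unannotated).
    """
    rows = []
    df_keys = sorted({(p.trigger_id, p.transcript_id) for p in phased_sirnas})
    for trigger_id, transcript_id in df_keys:
        if trigger_id not in triggers:
            continue
        n_supported = sum(
            1 for p in phased_sirnas
            if p.trigger_id == trigger_id and p.transcript_id == transcript_id and p.supported
        )
        status = (coding_status or {}).get(transcript_id, "unannotated")
        rows.append(
            {
                "transcript_id": transcript_id,
                "trigger_id": trigger_id,
                "supported_registers": n_supported,
                "coding_status": status,
                "candidate_tas": n_supported >= min_registers
                and status in ("non_coding", "unannotated"),
            }
        )
    return pd.DataFrame(rows)


def phasirna_table(
    phased_sirnas: Sequence[PhasedSiRNA], libraries: Sequence[str], supported_only: bool = True
) -> pd.DataFrame:
    rows = []
    for p in phased_sirnas:
        if supported_only and not p.supported:
            continue
        rows.append(
            {
                "name": p.name,
                "trigger_id": p.trigger_id,
                "transcript_id": p.transcript_id,
                "k": p.k,
                "window_start_1based": p.window[0] + 1,
                "window_end_1based": p.window[1],
                "sequence": p.sequence,
                "supported": p.supported,
                **{f"tpm_{lib}": round(p.per_library_tpm.get(lib, 0.0), 3) for lib in libraries},
            }
        )
    return pd.DataFrame(rows)
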