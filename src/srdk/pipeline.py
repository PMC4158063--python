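"""End-to-end orchestration of the analysis stages.

Wires the stages together in study order: catalog (collapse/filter,
ncRNA exclusion, genome mapping, TPM), miRNA identification (known then
novel), degradome target calling per library, phasiRNA prediction, and
SSR co-localization.  Each stage remains usable on its own; this module
only sequences them and bundles the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import catalog as cat
from . import degradome as deg
from . import discovery as disc
from . import phasing as pha
from . import ssr as ssrmod
from .config import PipelineConfig
from .io import CollapsedRead, FastaRecord


@dataclass
class PipelineResult:
    catalog: cat.Catalog
    stats: dict[str, cat.LibraryStats]
    known_loci: list[disc.MiRNALocus]
    novel_loci: list[disc.MiRNALocus]
    tplots: dict[str, dict[str, deg.TPlot]]  # library -> transcript -> TPlot
    target_calls: list[deg.TargetCall]
    triggers: dict[str, str]
    phasirnas: list[pha.PhasedSiRNA]
    phasi_calls: list[deg.TargetCall]
    tas_candidates: pd.DataFrame
    ssr_loci: list[ssrmod.SSRLocus]
    colocalized: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def all_loci(self) -> list[disc.MiRNALocus]:
        return self.known_loci + self.novel_loci

    def mirna_seqs(self) -> dict[str, str]:
        """id -> mature sequence across known and novel loci (first locus
        wins for multi-locus ids)."""
        out: dict[str, str] = {}
        for locus in self.all_loci:
            out.setdefault(locus.mirna_id, locus.mature_seq)
        return out


def run_pipeline(
    srna_libs: Mapping[str, Sequence[CollapsedRead]],
    degradome_libs: Mapping[str, Sequence[CollapsedRead]],
    genome: Sequence[FastaRecord],
    transcripts: Sequence[FastaRecord],
    mirna_ref: Sequence[FastaRecord],
    ncrna: Sequence[FastaRecord],
    config: PipelineConfig | None = None,
    coding_status: Mapping[str, str] | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()

    # 1. small-RNA catalog
    catalog, stats = cat.collapse_and_filter(srna_libs, config)
    cat.annotate_ncrna(catalog, ncrna)
    cat.map_to_genome(catalog, genome, stats)
    cat.tpm_normalize(catalog, stats)

    # 2. miRNA identification
    known = disc.match_known(catalog, mirna_ref, config, genome=genome)
    novel = disc.predict_novel(catalog, genome, config)
    mirnas = {}
    for locus in known + novel:
        mirnas.setdefault(locus.mirna_id, locus.mature_seq)

    # 3. degradome target calling per library
    tplots: dict[str, dict[str, deg.TPlot]] = {}
    calls: list[deg.TargetCall] = []
    for lib, tags in degradome_libs.items():
        tplots[lib] = deg.build_tplot(tags, transcripts)
        calls.extend(deg.call_targets(mirnas, tplots[lib], transcripts, config, library=lib))

    # 4. phasing
    triggers = pha.select_triggers(mirnas, calls, config)
    phasirnas = pha.predict_phasirnas(triggers, calls, transcripts, catalog, config)
    phasi_calls = []
    for lib in degradome_libs:
        phasi_calls.extend(
            pha.call_phasi_targets(phasirnas, tplots[lib], transcripts, config, library=lib)
        )
    tas = pha.flag_candidate_tas(
        triggers, phasirnas, coding_status, config.phase_min_registers
    )

    # 5. SSR co-localization
    ssr_loci = []
    for chrom in genome:
        ssr_loci.extend(
            ssrmod.detect_ssrs_genome(chrom.id, chrom.sequence, config.ssr_min_repeats)
        )
    loci = known + novel
    coloc = ssrmod.colocalize(
        ssr_loci, [(l.mirna_id, l.precursor_interval) for l in loci]
    )

    return PipelineResult(
        catalog=catalog,
        stats=stats,
        known_loci=known,
        novel_loci=novel,
        tplots=tplots,
        target_calls=calls,
        triggers=triggers,
        phasirnas=phasirnas,
        phasi_calls=phasi_calls,
        tas_candidates=tas,
        ssr_loci=ssr_loci,
        colocalized=coloc,
    )
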