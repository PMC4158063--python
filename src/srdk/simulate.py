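"""Self-contained synthetic dataset generator with ground-truth manifests.

Emulates the statistical structure of a plant sRNAome/degradome study:

* a genome carrying planted miRNA hairpins (perfect-complement arms,
  stem >= 16 bp, loop >= 3 nt), a subset of which contain SSR tracts in
  the loop — including one (CUU)15 tract, the longest repeat the real
  survey reports;
* per-tissue collapsed small-RNA libraries with a 24-nt-dominant length
  distribution, manifest-driven miRNA counts (including >4-fold
  tissue-differential pairs and sub-threshold decoys), and star reads at
  a fixed fraction of mature counts;
* per-tissue degradome libraries (20-nt 5' tags) with peaks opposite
  miRNA position 10/11 engineered to the intended category I/II/III;
* a 22-nt 5'-U trigger with a downstream ladder of 21-nt phased reads.

Determinism: one global seed; every generator derives its own sub-stream,
so identical seeds give byte-identical files.

SSR-carrying hairpins use a pyrimidine (C/T) 5' arm so that loop bases
cannot pair with both arms at once; under base-pair maximization this
keeps the planted stem strictly optimal and the (CUU)n loop unpaired,
which is what makes the loop-size-vs-repeat-number relationship
observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, revcomp
from .io import CollapsedRead, FastaRecord, write_collapsed_srna, write_fasta
from .ssr import detect_ssrs

BASES = np.array(list("ACGT"))
TISSUES = ("leaf", "flower", "fruit")
DEGRADOME_TAG_LEN = 20  # MmeI signature length
STAR_FRACTION = 0.1
ARM_LEN = 45
MATURE_ARM_OFFSET = 10
# background read-length distribution (count-weighted mode 24 nt)
LENGTH_WEIGHTS = {21: 0.15, 22: 0.10, 23: 0.15, 24: 0.45}
OTHER_LENGTHS = tuple(x for x in range(18, 31) if x not in LENGTH_WEIGHTS)

_DEFAULT_SSR_THRESHOLDS = {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 2}


class CapacityError(RuntimeError):
    """Requested features cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# ground truth manifest
# ---------------------------------------------------------------------------

@dataclass
class PlantedMiRNA:
    mirna_id: str
    precursor_interval: GenomicInterval
    precursor_seq: str
    mature_seq: str
    star_seq: str
    mature_offset: int
    counts: dict[str, int]
    is_reference: bool = False
    reference_id: str = ""
    reference_seq: str = ""  # may differ from mature by <= 2 substitutions
    recoverable: bool = True
    is_trigger: bool = False
    ssr: tuple[str, int] | None = None  # (unit, repeat number) in the loop


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based start of the binding window
    cleavage_site: int  # 0-based
    category: str  # intended I / II / III
    query_seq: str = ""


@dataclass
class PlantedTrigger:
    mirna_id: str
    transcript_id: str
    cleavage_site: int
    n_registers: int


@dataclass
class GroundTruth:
    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    trigger: PlantedTrigger | None = None
    ssrs: list[tuple[str, str, int]] = field(default_factory=list)  # (precursor id, unit, reps)
    coding_status: dict[str, str] = field(default_factory=dict)

    def mirna(self, mirna_id: str) -> PlantedMiRNA:
        return next(m for m in self.mirnas if m.mirna_id == mirna_id)


@dataclass
class SyntheticDataset:
    genome: list[FastaRecord]
    transcripts: list[FastaRecord]
    mirna_ref: list[FastaRecord]
    ncrna: list[FastaRecord]
    srna_libs: dict[str, list[CollapsedRead]]
    degradome_libs: dict[str, list[CollapsedRead]]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_fasta(self.transcripts, outdir / "transcripts.fa")
        write_fasta(self.mirna_ref, outdir / "mirna_ref.fa")
        write_fasta(self.ncrna, outdir / "ncrna.fa")
        for tissue, reads in self.srna_libs.items():
            write_collapsed_srna(reads, outdir / f"{tissue}.srna.fa")
        for tissue, tags in self.degradome_libs.items():
            write_collapsed_srna(tags, outdir / f"{tissue}.degradome.fa")
        truth_tables(self.truth, outdir)


def truth_tables(truth: GroundTruth, outdir: Path) -> None:
    pd.DataFrame(
        [
            {
                "mirna_id": m.mirna_id,
                "seq_id": m.precursor_interval.seq_id,
                "pre_start": m.precursor_interval.start,
                "pre_end": m.precursor_interval.end,
                "strand": m.precursor_interval.strand,
                "mature_seq": m.mature_seq,
                "star_seq": m.star_seq,
                "is_reference": m.is_reference,
                "reference_id": m.reference_id,
                "recoverable": m.recoverable,
                "is_trigger": m.is_trigger,
                **{f"count_{t}": m.counts.get(t, 0) for t in TISSUES},
            }
            for m in truth.mirnas
        ]
    ).to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "transcript_id": t.transcript_id,
                "site_start_1based": t.site_start + 1,
                "cleavage_site_1based": t.cleavage_site + 1,
                "category": t.category,
            }
            for t in truth.targets
        ]
    ).to_csv(outdir / "truth_targets.tsv", sep="\t", index=False)
    pd.DataFrame(truth.ssrs, columns=["precursor_id", "unit", "repeat_number"]).to_csv(
        outdir / "truth_ssrs.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=length)])


def build_hairpin(
    arm1: str, loop: str, mature_len: int, mature_offset: int = MATURE_ARM_OFFSET
) -> tuple[str, str, str, int]:
    """Assemble arm1 + loop + revcomp(arm1) and derive mature/star.

    The mature sits on the 5' arm at ``mature_offset``; the star is the
    partner span shifted by the canonical 2-nt 3' overhang.  Returns
    (precursor, mature, star, mature_offset).
    """
    precursor = arm1 + loop + revcomp(arm1)
    ms = mature_offset
    me = ms + mature_len
    if me > len(arm1):
        raise ValueError("mature must fit inside the 5' arm")
    stem = len(arm1) + len(loop)
    # in a perfect stem, position x on arm1 pairs with 2*stem - 1 - x ... no:
    # arm1 position x pairs with precursor position (len(precursor) - 1 - x)
    partner = lambda x: len(precursor) - 1 - x  # noqa: E731
    p_lo, p_hi = partner(me - 1), partner(ms)
    star = precursor[p_lo + 2:p_hi + 3]
    return precursor, precursor[ms:me], star, ms


# ---------------------------------------------------------------------------
# genome + hairpin planting
# ---------------------------------------------------------------------------

_COUNT_PROFILES = [
    # (leaf, flower, fruit) manifest counts; index order = hairpin order
    (40, 40, 400),    # fruit-enriched > 4x
    (240, 60, 60),    # leaf-enriched > 4x
    (80, 60, 0),      # absent in fruit
    (300, 300, 300),  # abundant everywhere (trigger profile)
    (2, 2, 2),        # sub-threshold decoy: filtered everywhere
    (60, 50, 70),
    (90, 120, 80),
    (50, 45, 55),
    (150, 30, 60),
    (70, 70, 70),
]


def simulate_genome(
    n_chrom: int = 2,
    chrom_len: int = 30_000,
    n_hairpins: int = 10,
    n_ssr_hairpins: int = 3,
    seed: int = 0,
    ssr_thresholds: dict[int, int] | None = None,
) -> tuple[list[FastaRecord], GroundTruth]:
    """Generate a genome with planted miRNA hairpins and SSR tracts.

    Hairpins are perfect-complement stems (>= 16 bp) around loops >= 3 nt,
    placed uniformly at random without overlap.  ``n_ssr_hairpins`` of
    them carry an SSR tract in the loop, the first always (CUU)15; each
    hairpin region is resampled until the SSR detector reports exactly the
    planted tracts, so the manifest matches detector semantics.
    """
    if not (n_hairpins >= n_ssr_hairpins >= 0):
        raise ValueError("need n_hairpins >= n_ssr_hairpins >= 0")
    thresholds = ssr_thresholds or _DEFAULT_SSR_THRESHOLDS
    rng = _rng(seed, 1)
    chroms = {f"chr{i + 1}": list(_random_seq(rng, chrom_len)) for i in range(n_chrom)}
    truth = GroundTruth()

    ssr_loops = [("CTT", 15), ("CTT", 4), ("TA", 6), ("CTT", 5), ("AG", 5)]
    mature_lens = [21, 21, 21, 22, 21, 20, 24, 21, 23, 21]

    # uniform non-overlapping placement over all chromosomes
    max_pre_len = 2 * ARM_LEN + 3 * max((len(u) * r for u, r in ssr_loops), default=8) + 8
    margin = 300
    placements: list[tuple[str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    chrom_ids = sorted(chroms)
    for _ in range(n_hairpins):
        for attempt in range(1000):
            cid = chrom_ids[int(rng.integers(0, n_chrom))]
            pos = int(rng.integers(margin, chrom_len - margin - max_pre_len))
            span = (pos - 100, pos + max_pre_len + 100)
            if all(b <= span[0] or a >= span[1] for a, b in occupied[cid]):
                occupied[cid].append(span)
                placements.append((cid, pos))
                break
        else:
            raise CapacityError("cannot place hairpins without overlap; genome too small")

    for idx in range(n_hairpins):
        cid, pos = placements[idx]
        mature_len = mature_lens[idx % len(mature_lens)]
        is_trigger = mature_len == 22
        with_ssr = idx < n_ssr_hairpins
        if with_ssr:
            unit, reps = ssr_loops[idx % len(ssr_loops)]
            loop = unit * reps
            arm_alphabet = "CT"  # keeps the repeat loop unpaired (see module docstring)
        else:
            unit, reps = "", 0
            loop = None
            arm_alphabet = "ACGT"

        for attempt in range(200):
            arm1 = _random_seq(rng, ARM_LEN, arm_alphabet)
            if is_trigger:
                arm1 = arm1[:MATURE_ARM_OFFSET] + "T" + arm1[MATURE_ARM_OFFSET + 1:]
            this_loop = loop if loop is not None else _random_seq(rng, 8)
            precursor, mature, star, offset = build_hairpin(arm1, this_loop, mature_len)
            found = {(s.unit, s.repeat_number) for s in detect_ssrs(precursor, thresholds)}
            expected = {(unit, reps)} if with_ssr else set()
            if found != expected:
                continue
            if any(m.mature_seq == mature for m in truth.mirnas):
                continue
            break
        else:
            raise CapacityError("could not sample a clean hairpin; relax SSR thresholds")

        chroms[cid][pos:pos + len(precursor)] = list(precursor)
        interval = GenomicInterval.from_zero_based(cid, pos, pos + len(precursor), "+")
        mirna_id = f"planted{idx + 1:02d}"
        counts = dict(zip(TISSUES, _COUNT_PROFILES[idx % len(_COUNT_PROFILES)]))
        if is_trigger:  # triggers need robust expression in every tissue
            counts = {t: max(c, 200) for t, c in counts.items()}
        planted = PlantedMiRNA(
            mirna_id=mirna_id,
            precursor_interval=interval,
            precursor_seq=precursor,
            mature_seq=mature,
            star_seq=star,
            mature_offset=offset,
            counts=counts,
            recoverable=max(counts.values()) >= 3,
            is_trigger=is_trigger,
            ssr=(unit, reps) if with_ssr else None,
        )
        truth.mirnas.append(planted)
        if with_ssr:
            truth.ssrs.append((mirna_id, unit, reps))

    genome = [FastaRecord(cid, "", "".join(chroms[cid])) for cid in chrom_ids]
    return genome, truth


def make_reference_set(
    truth: GroundTruth, seed: int = 0, n_known: int = 5, n_decoys: int = 2
) -> list[FastaRecord]:
    """Reference mature set: a subset of planted matures (one perturbed by
    two substitutions, exercising mismatch-tolerant matching) plus decoys."""
    rng = _rng(seed, 2)
    records = []
    known = [m for m in truth.mirnas if m.recoverable][:n_known]
    for i, m in enumerate(known):
        ref_seq = m.mature_seq
        if i == 1:  # perturb one reference by 2 substitutions
            s = list(ref_seq)
            for p in (3, 15):
                s[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[p]]
            ref_seq = "".join(s)
        m.is_reference = True
        m.reference_id = f"csi-miR{900 + i}"
        m.reference_seq = ref_seq
        records.append(FastaRecord(m.reference_id, "", ref_seq))
    for d in range(n_decoys):
        records.append(FastaRecord(f"csi-miR{990 + d}", "", _random_seq(rng, 21)))
    return records


def make_ncrna_set(seed: int = 0, n: int = 3, length: int = 120) -> list[FastaRecord]:
    rng = _rng(seed, 3)
    return [FastaRecord(f"ncRNA{i + 1}", "rRNA-like", _random_seq(rng, length)) for i in range(n)]


# ---------------------------------------------------------------------------
# transcripts + planted target sites
# ---------------------------------------------------------------------------

def simulate_transcripts(
    truth: GroundTruth,
    seed: int = 0,
    n_transcripts: int = 16,
    transcript_len: int = 600,
    n_phase_registers: int = 9,
) -> list[FastaRecord]:
    """Random transcripts with planted miRNA binding sites.

    Sites are perfect reverse complements of the planted matures, so the
    penalty score is 0; the intended category is engineered later by the
    degradome generator.  The 22-nt trigger's target transcript is marked
    non-coding and seeds the phasing cascade; one phased register's own
    target site is planted in a further transcript.
    """
    rng = _rng(seed, 4)
    seqs = {f"T{i + 1:02d}": list(_random_seq(rng, transcript_len)) for i in range(n_transcripts)}
    ids = sorted(seqs)
    truth.coding_status = {tid: "coding" for tid in ids}

    recoverable = [m for m in truth.mirnas if m.recoverable]
    trigger = next((m for m in recoverable if m.is_trigger), None)
    known = [m for m in recoverable if m.is_reference and not m.is_trigger]
    novel = [m for m in recoverable if not m.is_reference and not m.is_trigger]

    site_pos = 100
    plan: list[tuple[PlantedMiRNA, str, str]] = []
    if len(known) >= 2 and novel:
        plan = [
            (known[0], ids[0], "I"),
            (known[1], ids[1], "II"),
            (novel[0], ids[2], "III"),
        ]
    if trigger is not None:
        tas_id = ids[3]
        plan.append((trigger, tas_id, "I"))
        truth.coding_status[tas_id] = "non_coding"

    for mirna, tid, category in plan:
        site = revcomp(mirna.mature_seq)
        seqs[tid][site_pos:site_pos + len(site)] = list(site)
        cleavage = site_pos + len(site) - 10
        truth.targets.append(
            PlantedTarget(mirna.mirna_id, tid, site_pos, cleavage, category, mirna.mature_seq)
        )
        if mirna.is_trigger:
            truth.trigger = PlantedTrigger(mirna.mirna_id, tid, cleavage, n_phase_registers)

    # one phased register's own target: the k=7 register sequence of the
    # cascade targets a further transcript with a category-I site
    if truth.trigger is not None:
        tas_seq = "".join(seqs[truth.trigger.transcript_id])
        c = truth.trigger.cleavage_site
        k = min(7, truth.trigger.n_registers)
        phasi_seq = tas_seq[c + 21 * (k - 1):c + 21 * k]
        phasi_target_id = ids[4]
        site = revcomp(phasi_seq)
        seqs[phasi_target_id][site_pos:site_pos + len(site)] = list(site)
        cleavage = site_pos + len(site) - 10
        truth.targets.append(
            PlantedTarget(
                f"{truth.trigger.mirna_id}-{truth.trigger.transcript_id}-{k}",
                phasi_target_id, site_pos, cleavage, "I", phasi_seq,
            )
        )
    return [FastaRecord(tid, "", "".join(seqs[tid])) for tid in ids]


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

def _background_length(rng: np.random.Generator) -> int:
    lengths = list(LENGTH_WEIGHTS) + [0]
    probs = list(LENGTH_WEIGHTS.values()) + [1.0 - sum(LENGTH_WEIGHTS.values())]
    pick = rng.choice(len(lengths), p=probs)
    if lengths[pick] == 0:
        return int(rng.choice(OTHER_LENGTHS))
    return int(lengths[pick])


def simulate_srna_libraries(
    truth: GroundTruth,
    genome: Sequence[FastaRecord],
    ncrna: Sequence[FastaRecord],
    tissues: Sequence[str] = TISSUES,
    depth: int = 100_000,
    seed: int = 0,
    star_fraction: float = STAR_FRACTION,
) -> dict[str, list[CollapsedRead]]:
    """Per-tissue collapsed sRNA libraries.

    Planted matures carry their manifest counts exactly; star reads are
    emitted at ``star_fraction`` of the mature count.  Background reads
    (``depth`` driving their number) draw lengths from the 24-nt-dominant
    categorical distribution and sequences from random genome windows
    (60%, avoiding planted precursors), the ncRNA references (a small
    fixed share) or random strings.
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000 total counts per tissue")
    unknown = set(tissues) - set(TISSUES)
    if any(t not in TISSUES for m in truth.mirnas for t in m.counts) or unknown:
        raise ValueError(f"unknown tissue label(s): {sorted(unknown)}")
    rng = _rng(seed, 5)
    genome_seqs = [g.sequence for g in genome]
    exclude: dict[str, list[tuple[int, int]]] = {}
    for m in truth.mirnas:
        s0, e0 = m.precursor_interval.to_zero_based()
        exclude.setdefault(m.precursor_interval.seq_id, []).append((s0 - 50, e0 + 50))
    chrom_ids = [g.id for g in genome]

    n_background = max(depth // 50, 20)
    n_ncrna_reads = min(30, n_background // 10)

    background: list[str] = []
    while len(background) < n_background - n_ncrna_reads:
        length = _background_length(rng)
        if rng.random() < 0.6 and genome_seqs:
            gi = int(rng.integers(0, len(genome_seqs)))
            pos = int(rng.integers(0, len(genome_seqs[gi]) - length))
            if any(a < pos + length and pos < b for a, b in exclude.get(chrom_ids[gi], [])):
                continue
            seq = genome_seqs[gi][pos:pos + length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = _random_seq(rng, length)
        background.append(seq)
    for _ in range(n_ncrna_reads):
        src = ncrna[int(rng.integers(0, len(ncrna)))].sequence
        length = _background_length(rng)
        pos = int(rng.integers(0, len(src) - length))
        background.append(src[pos:pos + length])

    libs: dict[str, list[CollapsedRead]] = {}
    for tissue in tissues:
        reads: list[CollapsedRead] = []
        for m in truth.mirnas:
            count = m.counts.get(tissue, 0)
            if count > 0:
                reads.append(CollapsedRead(m.mature_seq, count))
                star_count = int(round(star_fraction * count))
                if star_count > 0:
                    reads.append(CollapsedRead(m.star_seq, star_count))
        for seq in background:
            count = 1 + int(rng.poisson(4))
            reads.append(CollapsedRead(seq, count))
        libs[tissue] = reads
    return libs


# ---------------------------------------------------------------------------
# degradome libraries
# ---------------------------------------------------------------------------

def simulate_degradome(
    truth: GroundTruth,
    transcripts: Sequence[FastaRecord],
    tissues: Sequence[str] = TISSUES,
    depth: int = 5000,
    signal_to_noise: float = 20.0,
    seed: int = 0,
) -> dict[str, list[CollapsedRead]]:
    """Per-tissue degradome libraries of 20-nt 5' tags.

    Background tags fall uniformly over transcript positions.  At each
    planted target site the tag starting at the cleavage site receives
    ``signal_to_noise`` times the expected per-position background (floored
    at 1); category II/III sites additionally get a stronger decoy peak 40
    nt downstream so the cleavage tag is a clear-but-not-maximum peak (II)
    or a minor signal (III).
    """
    if signal_to_noise <= 0:
        raise ValueError("signal_to_noise must be positive")
    for t in truth.targets:
        seq = next(tr.sequence for tr in transcripts if tr.id == t.transcript_id)
        if len(seq) - t.cleavage_site < 2 * DEGRADOME_TAG_LEN:
            raise ValueError(
                f"target {t.mirna_id}->{t.transcript_id}: < 40 nt downstream of cleavage"
            )
    rng = _rng(seed, 6)
    total_positions = sum(max(len(t.sequence) - DEGRADOME_TAG_LEN + 1, 0) for t in transcripts)
    lam = depth / max(total_positions, 1)
    signal = max(int(math.ceil(signal_to_noise * max(lam, 1.0))), 2)

    libs: dict[str, list[CollapsedRead]] = {}
    for _tissue in tissues:
        counts: dict[str, int] = {}

        def _add(seq: str, n: int) -> None:
            if n > 0 and len(seq) == DEGRADOME_TAG_LEN:
                counts[seq] = counts.get(seq, 0) + n

        for tr in transcripts:
            npos = len(tr.sequence) - DEGRADOME_TAG_LEN + 1
            if npos <= 0:
                continue
            n_tags = rng.poisson(lam * npos)
            for pos in rng.integers(0, npos, size=int(n_tags)):
                _add(tr.sequence[int(pos):int(pos) + DEGRADOME_TAG_LEN], 1)
        for t in truth.targets:
            seq = next(tr.sequence for tr in transcripts if tr.id == t.transcript_id)
            c = t.cleavage_site
            if t.category == "I":
                _add(seq[c:c + DEGRADOME_TAG_LEN], signal)
            elif t.category == "II":
                _add(seq[c:c + DEGRADOME_TAG_LEN], signal)
                _add(seq[c + 40:c + 40 + DEGRADOME_TAG_LEN], int(math.ceil(1.5 * signal)))
            else:  # III: cleavage tag present but a minor signal
                _add(seq[c:c + DEGRADOME_TAG_LEN], 2)
                _add(seq[c + 40:c + 40 + DEGRADOME_TAG_LEN], 3 * signal)
        libs[_tissue] = [CollapsedRead(s, n) for s, n in counts.items()]
    return libs


# ---------------------------------------------------------------------------
# phasing cascade
# ---------------------------------------------------------------------------

def simulate_phasing_cascade(
    truth: GroundTruth,
    transcripts: Sequence[FastaRecord],
    srna_libs: dict[str, list[CollapsedRead]],
    require_trigger_5pU: bool = True,
    min_count: int = 30,
    cascade_tissues: Sequence[str] = ("leaf", "flower"),
) -> dict[str, list[CollapsedRead]]:
    """Add the 21-nt phased read ladder downstream of the trigger cleavage.

    Register k (1..K) is the transcript window starting at c + 21*(k-1)
    (0-based offset from the cleavage site c); each register read receives
    a count well above the abundance filter, decreasing with k.
    """
    if truth.trigger is None:
        return srna_libs
    trig = truth.mirna(truth.trigger.mirna_id)
    if len(trig.mature_seq) != 22:
        raise ValueError("phasing trigger must be 22 nt")
    if require_trigger_5pU and not trig.mature_seq.startswith("T"):
        raise ValueError("phasing trigger must carry a 5' U")
    seq = next(t.sequence for t in transcripts if t.id == truth.trigger.transcript_id)
    c = truth.trigger.cleavage_site
    K = truth.trigger.n_registers
    if c + 21 * K > len(seq):
        raise CapacityError(f"{K} phased registers do not fit in the target transcript")
    for k in range(1, K + 1):
        window = seq[c + 21 * (k - 1):c + 21 * k]
        count = max(min_count, 60 - 3 * k)
        for tissue in cascade_tissues:
            srna_libs[tissue].append(CollapsedRead(window, count))
    return srna_libs


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 30_000,
    n_hairpins: int = 10,
    n_ssr_hairpins: int = 3,
    srna_depth: int = 100_000,
    degradome_depth: int = 5000,
    signal_to_noise: float = 20.0,
    n_phase_registers: int = 9,
    with_cascade: bool = True,
) -> SyntheticDataset:
    """Generate the full study-shaped dataset with one global seed."""
    genome, truth = simulate_genome(n_chrom, chrom_len, n_hairpins, n_ssr_hairpins, seed)
    mirna_ref = make_reference_set(truth, seed)
    ncrna = make_ncrna_set(seed)
    transcripts = simulate_transcripts(truth, seed, n_phase_registers=n_phase_registers)
    srna_libs = simulate_srna_libraries(truth, genome, ncrna, TISSUES, srna_depth, seed)
    degradome_libs = simulate_degradome(
        truth, transcripts, TISSUES, degradome_depth, signal_to_noise, seed
    )
    if with_cascade:
        srna_libs = simulate_phasing_cascade(truth, transcripts, srna_libs)
    return SyntheticDataset(
        genome=genome,
        transcripts=transcripts,
        mirna_ref=mirna_ref,
        ncrna=ncrna,
        srna_libs=srna_libs,
        degradome_libs=degradome_libs,
        truth=truth,
    )
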