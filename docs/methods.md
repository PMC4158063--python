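# Methods

This note records the models, defaults and design choices behind `srdk`,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and alphabet

All persisted coordinates (GFF3, BED score columns aside, report tables)
are 1-based inclusive; all in-memory arithmetic is 0-based half-open,
with `GenomicInterval` providing the only conversion points. The
canonical in-memory alphabet is DNA (T, upper case): genomes and reads
arrive as DNA, and a single alphabet avoids mixed U/T comparison bugs.
RNA (U) appears only on input (converted on read) and in display output
(dot-bracket/Vienna text, `to_rna`). Collapsed small-RNA FASTA accepts
two count dialects (`id_xN` and `count=N`) because deposited
intermediate formats vary between studies.

## Small-RNA catalog

"Low quality" reads are operationalized as reads containing N or with
length outside `read_len_range` (default 18–30 nt, matching the common
practice of discarding sub-18-nt tags). The abundance filter keeps a
sequence in a library only when its count there is at least
`min_read_count` (default 3); a sequence survives overall if any library
retains it. Genome mapping is exact-match only, both strands, all hits
kept; the per-library statistics report matched totals over both the
unique-sequence and the count-weighted denominators, since published
accounting tables use both.

TPM is `count / total_clean × 10⁶` with `total_clean` the post-filter
library total, so the catalog-wide TPM sum is exactly 10⁶ per library —
a conservation property the tests assert on every run. Fold change
between tissues divides a tissue's TPM by the maximum of the other
tissues with a 0.5-TPM pseudocount in the denominator only; a sequence
with zero TPM in one tissue and positive elsewhere is classed "absent"
and absence takes precedence over enrichment labels. Thresholds (2× for
enrichment, 4× for strong enrichment, 10 TPM for high expression) are
configuration fields.

## Hairpin folding

The folder maximizes the number of nested base pairs (Nussinov dynamic
program) with Watson–Crick plus G:U pairs and a minimum hairpin loop of
3 nt. Base-pair maximization, not thermodynamic MFE, is deliberate: it
is dependency-free, exactly testable against brute-force enumeration,
and sufficient for verifying stem-loop precursor criteria. Users who
want MFE parity with Vienna-style folders can pass any callable
returning a dot-bracket string via the `external_folder` hook; all
downstream metrics work from the dot-bracket alone. The O(n³) fill is
JIT-compiled with numba (a pure-Python fill with identical semantics is
used when numba is unavailable); inputs are capped at 600 nt, well above
any precursor window the pipeline folds.

Determinism: when several structures achieve the maximum, the traceback
pairs the closing base with the smallest admissible partner index,
making outputs reproducible. A useful consequence is that for a perfect
complementary stem whose loop can pair with at most one arm, the
traceback recovers exactly the planted stem.

Hairpin metrics place the miRNA\* as the mature's pairing-partner span
shifted by the canonical 2-nt 3′ overhang (DCL geometry).
`duplex_mismatches` counts unpaired mature positions;
`max_asym_bulge` is the largest difference between opposing unpaired
runs between consecutive paired mature positions; `loop_size` is the
hairpin loop lying between the two arms. A mature mapping entirely to an
unpaired region raises a not-a-hairpin error.

## miRNA identification

Known matching is ungapped with sliding for length differences of at
most 2 nt; the penalty is substitutions plus the length difference, and
must not exceed `known_max_mismatch` (default 2). Ties go to the earlier
reference entry. With a genome available, an assignment also requires a
genomic hit whose flanking window folds into a hairpin containing the
mature on a stem.

Novel calling considers unassigned, genome-mapped 20–24-nt reads. Around
each hit two windows are folded — the full `flank_for_precursor`
(default 150 nt, enough for >350-nt precursors) upstream or downstream
of the read, each with a 20-nt pad on the other side — and the best
valid hairpin is kept. Acceptance requires ≤ 4 duplex mismatches, ≤ 2-nt
asymmetric bulge, and a catalog read equal to the computed star sequence
within ±1 nt of the star interval in at least one library (consistent
with community annotation criteria for plant miRNAs). Both window
candidates are pre-screened with a cheap near-reverse-complement scan
before the cubic fold; a hairpin that satisfies the duplex criteria
necessarily contains such a region, so the screen only removes windows
that could not validate.

A perfect-duplex mature exact-matches the minus strand of its own star
arm, so one hairpin naturally surfaces as two strand-mirrored genomic
hits; overlapping precursor windows for the same mature are collapsed,
keeping the plus-strand locus. Identical matures at genuinely distinct
loci share one id with `-1`, `-2` suffixes. Novel ids are `csi-miRN##`
in discovery order.

## Degradome targets

T-plots record, per transcript, the summed counts of 20-nt tags whose
exact match starts at each position; a tag matching several transcripts
counts in each. The alignment penalty is the CleaveLand-convention plant
scheme — mismatch 1.0, G:U 0.5, gap 2.0, doubled at miRNA positions 2–13
— with a default cutoff of 7.0; alignments are ungapped by default. The
predicted cleavage site is the transcript position opposite miRNA
position 10 counted from the 5′ end; because cleavage is reported
against "position 10 or 11" in the literature, a ±1-nt window is
accepted and the max-count position within it becomes the reported site.

Categories: I requires the cleavage count to be the *unique* transcript
maximum; II requires at least `peak_fraction` (default 0.5 — "a clear
peak" quantified) of the maximum, and includes sites tied at a shared
maximum; III is the remainder with at least one tag. The category is
monotone in the cleavage count with the rest of the T-plot held fixed.

## Phasing

Triggers are miRNAs of exactly `trigger_length` (22) nt, optionally
required to start with U (default on; this is switchable because the
5′-U evidence in the literature is strongest for specific triggers), and
must have at least one degradome-validated target call — predicted sites
without tag evidence do not seed cascades. Register 1 begins at the
first nucleotide of the 3′ cleavage fragment; a configurable offset
exists because the exact first base is a convention. Only exact 21-nt
sense-strand catalog matches support a register; near-phased reads
appear in the diagnostics table only, and no phasing P-value is computed
— abundance plus register membership is the entire criterion, matching
the simple in-house-script design this pipeline reproduces. Names
`trigger-transcript-k` are bijective given the trigger id list (trigger
ids may themselves contain hyphens). TAS candidates are transcripts
targeted by a trigger with ≥ `phase_min_registers` (default 3) supported
registers and non-coding/unannotated status.

## SSR detection

Maximal tandem repeats of 1–6-nt units with MISA-like minimum repeat
numbers (mono 8, di 4, tri 3, tetra 3, penta 3, hexa 2 — chosen so a
(CUU)₃ tract is still reportable). Units are reported on the given
strand without canonicalization, because published unit tables list CT,
TC, GA, AG as distinct rows. Nested reports are suppressed
(smallest-period unit wins) and within one unit length the leftmost
phase of a run wins. Co-localization is ≥ 1-nt overlap with a precursor
interval on the same strand. Composition percentages are rounded to one
decimal; the bundled `data/ssr_premirna_units.tsv` transcribes the
published repeat-unit counts for SSRs co-localized with sweet-orange
pre-miRNAs and is used by the summary-only mode and the acceptance
script.

## Synthetic data

The generator emulates the structural features the detectors rely on,
at desk scale rather than study scale:

* **Genome** (default two 30-kb chromosomes): uniform random background
  with 10 planted hairpins — perfect-complement 45-bp arms around ≥ 3-nt
  loops, placed uniformly without overlap. Three hairpins carry an SSR
  tract in the loop, always including (CUU)₁₅; SSR-bearing hairpins use
  a pyrimidine 5′ arm so the repeat loop cannot pair with both arms,
  keeping the planted stem the traceback optimum and the loop size
  proportional to the repeat number (this is what makes the
  loop-size-vs-(CUU)ₙ monotonicity observable). Each hairpin region is
  resampled until the SSR detector reports exactly the planted tracts,
  so the manifest and detector semantics agree by construction.
* **Reference set**: five planted matures become "known" references
  (one perturbed by two substitutions to exercise mismatch-tolerant
  matching) plus random decoys; the rest are left for novel discovery.
  One planted mature is emitted at sub-threshold counts (2 per tissue)
  as a decoy that must never be recovered.
* **sRNA libraries** (leaf/flower/fruit): planted matures carry their
  manifest counts exactly — including a >4-fold fruit/leaf pair and an
  absent-in-fruit profile — with star reads at 10 % of mature counts
  (the literature reports star reads qualitatively as "lower level";
  10 % is this package's quantification). Background unique reads
  (~depth/50) draw lengths from a categorical distribution with mode
  24 nt ({21: 0.15, 22: 0.10, 23: 0.15, 24: 0.45, other 18–30: 0.15} —
  the published length profiles are qualitative, these proportions are
  an artifact choice), sequences from random genome windows (60 %,
  avoiding planted precursors so background cannot shadow a locus),
  ncRNA windows (a small fixed share) or random strings, and counts
  1 + Poisson(4) so ~9 % fall under the abundance filter.
* **Degradome** (20-nt tags, the MmeI signature length): uniform
  background at `depth` tags per tissue; planted sites receive
  `signal_to_noise` × expected-per-position-background tags (category
  I), the same plus a 1.5× decoy peak 40 nt downstream (category II —
  a clear but non-maximal peak), or 2 tags against a 3× decoy
  (category III).
* **Cascade**: the 22-nt 5′-U trigger's target transcript (marked
  non-coding) gets 9 phased 21-nt reads at exact registers in leaf and
  flower, counts well above the filter; the k = 7 register additionally
  gets its own category-I target site on another transcript.

One global seed drives everything; each generator stage derives its own
sub-stream, so identical seeds give byte-identical files.

**What passing tests show — and don't.** Recovery of planted features
demonstrates that the detectors implement their stated criteria
correctly and consistently with the generator's geometry (cleavage
position arithmetic, register tiling, star placement, category
definitions). It does not demonstrate performance on real data: real
hairpins have imperfect stems and multi-branch folds, real degradome
background is position-biased rather than uniform, sequencing errors and
isomiRs are absent, and the headline counts of any real study (numbers
of known/novel miRNAs, per-tissue target counts, genome-wide SSR census)
depend on the actual genome and libraries and are not reproduction
targets at this scale.

## Numerical and degenerate-input choices

* Folding tie-break: smallest partner index during traceback; fold is
  deterministic and idempotent.
* Empty inputs: empty FASTA yields zero records; an empty ncRNA
  reference flags nothing; an all-zero T-plot refuses classification; a
  library with clean total 0 but retained reads is a normalization
  error.
* Rounding: composition percentages to 1 decimal; TPM values printed to
  3 decimals in report tables, full precision in memory.
* The per-tissue problem sizes (30-kb chromosomes, ~2 000 unique
  background reads, 5 000 degradome tags) keep a full pipeline run in a
  few seconds while leaving every statistic well away from its decision
  boundaries at the default signal-to-noise of 20.

## Known limitations

* Single-hit, 3′-ward phasing only; the two-hit miR390/TAS3 mechanism
  (5′-ward processing between two binding sites) is out of scope.
* No gapped target alignments by default (the gap penalty exists but
  gapped scanning is off); no phasing score statistic.
* The folder ignores thermodynamics; G:U-rich stems score as well as
  G:C stems.
* SAM/BAM, compressed genomes and web resources are not supported;
  references are user-supplied FASTA files.
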