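# Methods

svlens extracts structural-variant (SV) evidence from long-read alignments
(PacBio / Oxford Nanopore style BAMs), interprets each read's SV structure,
lays reads out for IGV-style static figures, and force-calls genotypes for
candidate SVs.  This note describes the model behind each stage, the
parameters that matter, and what the synthetic fixtures do and do not
establish.

## Evidence model

Long-read aligners represent an SV-bearing read in one of two ways:

* **within one record** — a mid-read CIGAR `D` (deletion) or `I` (insertion)
  operation, or a long terminal soft clip marking a breakpoint the aligner
  could not represent;
* **as split mapping** — a primary alignment plus supplementary alignments
  (cross-referenced by the `SA` tag), where each adjacency between
  query-consecutive segments joins two reference loci.

Both channels are read per alignment record; supplementary partners outside
the queried window (e.g. the other chromosome of a translocation) are
fetched genome-wide through the `SA` tag so that a read group always holds
the read's complete segment set, ordered by strand-corrected query offset.

### Read filters

A segment is kept when it passes all of (defaults in parentheses):

| parameter        | meaning                                   | default |
|------------------|-------------------------------------------|---------|
| `min_mean_baseq` | arithmetic mean of Phred base qualities   | 20      |
| `min_identity`   | `1 − NM / aligned_length`, clamped to [0,1] | 0.60  |
| `min_map_len`    | reference span of the segment, bases      | 100     |
| `min_mapq`       | mapping quality                           | 0       |

Mean quality is averaged on the Phred scale (not in error-probability
space): the filter is a rough evidence gate, not a probability calculation,
and the Phred mean is the conventional reading of "mean read quality".
Records without stored base qualities (common for HiFi BAMs) pass the
quality gate with a warning — rejecting them would discard entire files.
Filters apply per segment; a read survives if at least one segment
survives, so a ragged supplementary cannot veto a clean primary.  When two
segments of one read overlap in query space, the lower-mapq segment is
trimmed (ties trim the query-later one).

## Split-adjacency classification

For query-consecutive segments *a*, *b* let `qgap` be the signed query gap
and `rgap` the signed reference gap.  Because a minus-strand read traverses
the reference right-to-left, `rgap` is strand-aware:

    rgap = b.ref_start − a.ref_end      (both segments on '+')
    rgap = a.ref_start − b.ref_end      (both segments on '−')

Without this, a read and its reverse-complement alignment would classify
differently; with it, classification is provably invariant under
reverse-complementing (tested exhaustively).  Rules, in precedence order,
with `L = min_sv_length` (default 50 bp, the conventional SV floor):

1. different chromosomes → **TRA**;
2. opposite strands → **INV**, length = distance between the two junction
   loci;
3. `rgap ≤ −L` (reference re-visit) → **DUP**, length `−rgap`;
4. `rgap − qgap ≥ L` → **DEL**, length `rgap − qgap`;
5. `qgap − rgap ≥ L` → **INS**, length `qgap − rgap`.

The DUP-before-INS precedence is deliberate: a tandem duplication *is* an
insertion of upstream sequence, so a re-visit configuration satisfies both
signatures and the more specific one wins.  Inverted duplications present
as INV.  CIGAR `D`/`I` operations ≥ L yield DEL/INS structures through the
same types.  A multi-event read keeps every breakpoint but is labeled by
its largest event (one color per read; no evidence dropped).  Breakpoints
of equal type and chromosome pair cluster by single linkage within 1000 bp,
with median consensus positions.

## Layout

Display spans (min segment start to max segment end, gap included) are
sorted by start and placed first-fit: each span goes to the lowest row
whose last occupant ends at least `gap` (default 5 bp) before it.  With
`gap = 0` this is optimal for interval graphs — the row count equals the
maximum overlap depth, which the tests verify against a sweep-line oracle.
Over-covered regions subsample to `max_rows` (default 200) keeping all
SV-supporting reads first and filling with reference reads drawn
deterministically from a seed keyed per record, so batch results are
independent of thread count.

## Force-call genotyping

For a candidate SV the evaluation window is the SV interval padded by
`max_bp_disparity` (default 1000 bp); INS uses a window around its
breakend, TRA one window per breakend.  A read is **informative** when

* its aligned span covers ≥ `min_overlap_frac` (default 0.5) of the
  assessment interval — the SV interval for DEL/INV, a ±500 bp breakend
  neighborhood for INS/TRA/DUP — and
* it aligns ≥ `min_region_align_len` (default 100 bp) inside the window.

An informative read **supports** the candidate when it carries a same-type
structure whose breakpoints all lie within `max_bp_disparity` of the
candidate's; otherwise it counts as reference.  Two refinements:

* **DEL length agreement.**  A supporting deletion's event length must
  match the candidate's within `max(0.5 × SVLEN, 1000 bp)`, so a nested or
  neighboring deletion of very different size is not absorbed as support.
* **INS clip evidence.**  A read with a terminal soft clip ≥ `min_sv_length`
  anchored within the disparity tolerance of an insertion breakend counts
  as support: such reads are too short to traverse the inserted sequence,
  and their clip is direct evidence of it.  Without this, homozygous
  insertions whose length approaches the read length are systematically
  under-called.
* **DUP anchoring.**  A tandem duplication is decided at its re-visit
  junction (the interval end).  A read is informative only if it is
  anchored at or upstream of the unit start (within 500 bp slack) and
  covers the junction neighborhood.  Reads that begin *inside* the
  duplicated unit are allele-ambiguous — on the alt allele they may
  originate from the second copy, which rejoins downstream sequence with no
  junction — and treating them as reference evidence systematically drags
  homozygous-DUP allele frequency below the hom threshold.

Allele frequency is `AF = support / (support + reference)` over informative
reads only (not raw window depth).  Genotype assignment is strict:
`AF > 0.8 → 1/1`, else `AF > 0.3 → 0/1`, else `0/0`; `./.` is reserved for
zero informative reads.  Both thresholds are exposed (`het_af`, `hom_af`).

## Depth, pileup, isoforms, annotation

* `region_depth` bins per-base coverage of filtered reads; CIGAR `D`/`N`
  ops contribute nothing, regardless of the SV length floor — coverage is
  an alignment fact, not an SV call.  Binned mass exactly conserves the
  total reference-consuming bases (tested).
* `pileup_bases` counts bases per column (plus `DEL` and left-anchored
  `INS` counts) for windows up to 1000 bp, warning above 200 bp where
  per-base display stops being legible; reference bases come from an
  indexed FASTA when given.
* `extract_isoforms` turns CIGAR `N`-separated runs into exon chains, one
  chain per read; chains are not collapsed into transcripts — rendering
  groups identical chains visually.
* `overlap_features` intersects BED or GenePred tracks (genes, repeats,
  segmental duplications) with the view window; tracks are user-supplied
  paths, nothing is bundled.

## Rendering

Figures (PNG/PDF via matplotlib) follow IGV's grammar: one lane per layout
row; split SV segments in the type color (REF gray, DEL red, INS purple,
DUP green, INV blue, TRA orange) joined by dashed connectors with the event
length printed at the junction midpoint; CIGAR-joined events use solid
connectors; clip markers at read ends; two side-by-side panes for TRA with
reads paired across panes; per-sample stacking for multi-BAM input.  Every
figure gets a JSON sidecar carrying the exact reads, rows, types, lengths
and labels drawn — rendering never alters analysis results, and the tests
assert sidecar content against fresh module output instead of pixels.

## Synthetic fixtures

`simulate_locus` / `simulate_cohort` build a diploid donor per locus by
applying SVs to a random reference (DEL removes, INS inserts novel
sequence, DUP tandem-duplicates, INV reverse-complements, TRA exchanges
arms between two contigs), sample reads uniformly at the configured depth
with substitution errors, and synthesize the alignments directly from the
known donor→reference block map: deletions/insertions up to 5 kb become
CIGAR ops, larger events and all DUP/INV/TRA junctions become split
records with SA tags, and reads ending inside insertions get terminal soft
clips.  Everything is deterministic given the seed (byte-identical BAMs).

Default study conditions for the genotype-recovery experiment: 100 loci
(types cycling DEL/INS/DUP/INV/TRA → 20 each, genotypes alternating
0/1 and 1/1), 30 kb reference per locus, 30× depth, 10 kb reads, 0.2%
substitution error (HiFi-like), event lengths uniform on 200–2000 bp.
These sizes keep the full recovery experiment under a minute on one CPU
while leaving dozens of informative reads per locus.

**What the fixtures do not emulate:** alignment ambiguity in repeats,
indel sequencing errors (so CIGARs away from the SV are clean), ONT-style
error profiles, reference bias, and multi-SV interactions at one locus.
Passing recovery tests therefore demonstrates the correctness of the
evidence→classification→genotype pipeline, not calling performance on real
genomes.

## Numerical / degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; 1-based
  conversion happens only at region-string/VCF boundaries.
* Identity without an `NM` tag falls back to the CIGAR match fraction.
* Equality passes the evidence filters (`≥` thresholds); equality does
  *not* pass the AF thresholds (`>`), matching their "exceeds/surpasses"
  semantics.
* Clustering and subsampling ties break on read name for determinism.
* Empty regions yield empty results, not errors; a missing BAM index is a
  hard, actionable error.
* VCF records with unusable `SVTYPE` pass through with `./.` and a warning;
  record counts are always preserved.

## Known limitations

No realignment, local assembly, or breakpoint re-fitting; no de novo
genome-wide calling (classification is restricted to queried windows); no
transcript quantification; BND orientation is not used in TRA matching
(chromosome pair + positions only); the DUP anchoring rule assumes tandem
orientation.
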