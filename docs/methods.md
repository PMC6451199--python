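# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive),
VCF (1-based), and BED/bedGraph (0-based half-open) are converted at the
parser boundary and nowhere else. Discrepancy positions (`ref_pos`) are
reported 1-based to match VCF habits: the mismatched base, the anchor base
immediately left of an insertion, or the first deleted base. Chromosome
ids must match exactly across input files; there is no alias resolution —
a silent mismatch is worse than a hard error.

## The coding/non-coding partition

Coding space is the per-base union of all CDS features across all
transcripts and genes; UTRs and introns are non-coding. This single
genome-wide union is what makes `L_cds + L_nc` equal the genome length
exactly, per chromosome and globally — an invariant the tests enforce.
N bases count toward whatever region they fall in. The union is held as
sorted disjoint interval arrays with binary-search point/range queries;
unit tests check it against per-base boolean-array oracles.

## Discrepancy normalization

VCF records arrive anchored (shared leading base); the anchor is stripped,
leaving a pure insertion (empty REF) or deletion (empty ALT). Multi-allelic
records are split per ALT. Equal-length multi-base substitutions are
decomposed into per-base mismatches, because mismatches are counted as
base events; length-changing substitutions are reduced to the minimal
mismatch(es)-plus-one-indel decomposition. No left-alignment or
re-normalization against the reference is attempted beyond anchor removal:
input coordinates are trusted as produced by the upstream comparison tool.
The Quast-style TSV dialect (chrom, ref pos, ref allele or `.`, contig,
contig pos, alt allele or `.`) maps `.` to the empty allele; for insertion
rows the stated reference position is taken as the anchor base, which makes
the two readers produce identical discrepancy lists for equivalent content
(a cross-reader test enforces this).

Indel size classes follow the convention of long-read assembly evaluation:
small ≤ 5 bp, large > 5 and ≤ 85 bp. Anything longer is tracked as
"structural" and excluded from small/large tallies while remaining usable
for track building.

## Region assignment and effect annotation

A mismatch or deletion is coding iff *any* affected reference base is
coding; an insertion is coding iff its anchor base is. For each coding
discrepancy, effects are computed per overlapping transcript:

* **Mismatches.** The spliced CDS is reconstructed in translation order
  (reverse-complemented for minus-strand transcripts); the reading-frame
  phase of the first CDS segment gives the bases to skip before the first
  complete codon. The call is synonymous iff the standard genetic code
  (translation table 1) translates the reference and alternate codons
  identically. Codons that cannot be reconstructed (position before the
  phase offset, spliced CDS shorter than a codon, or an N in the codon)
  are excluded from the syn/non-syn tallies and reported separately as
  unresolved. Organelle genetic codes are not handled; organelle sequences
  are assumed removed upstream.
* **Indels.** An indel fully inside a transcript's CDS is in-frame iff its
  length is a multiple of 3, else frameshift. An indel that only partially
  overlaps the CDS is counted as coding (any-base rule) but labelled
  frameshift conservatively, since its effect on the frame cannot be
  bounded without knowing the breakpoint resolution.

Counting rules: region tallies are per discrepancy (a mismatch overlapping
three transcripts is one coding mismatch); effect lists are per transcript.
A mismatch is tallied non-synonymous if any transcript call is
non-synonymous; an indel is tallied in-frame only if every coding
transcript call is in-frame. An mRNA is *affected* by any coding
discrepancy; a protein is *altered* only by a non-synonymous mismatch or
an indel — this "synonymous-only leaves the protein intact" reading is
what makes affected-mRNA counts ≥ altered-protein counts, the ordering
observed in published evaluation tables.

## Statistics

* fold-likelihood ratio: `(n_nc / L_nc) / (n_cds / L_cds)`; displayed
  rounded to one decimal, retained at full precision; a zero coding count
  yields an infinite density contrast, reported as such rather than as a
  number.
* combined accuracy: `100 × (1 − (n_mismatch + n_indel) / L)` — an
  *event-count* definition (an 85 bp deletion is one event, not 85 errored
  bases). This is this package's documented definition; published
  non-coding accuracy cells computed by other means are not reproduced.
* per-100-kbp rates take their denominator explicitly because upstream
  tools print rates over *aligned* length while region-level rates use
  `L_cds`/`L_nc`.
* co-location matches on (chromosome, position, mismatch-vs-indel
  category), each discrepancy matched at most once; allele-strict matching
  is available behind a flag. Matching location but not allele mirrors the
  "same locations" notion used when comparing two assemblies of the same
  strain.

## Mis-assembly breakpoints

Adjacent alignment blocks of one contig are compared: different reference
chromosomes → translocation; opposite strands → inversion; otherwise the
discordance is `|observed reference distance − contig distance|`, which
unifies "further apart than expected" and "overlapping by the same length"
into one magnitude. Discordance > 12,000 bp (twice a 6 kb minimum read
length) → relocation; 85 bp < d ≤ 12,000 bp → local; else consistent.
The upper bound is inclusive for the local class so no distance falls
between classes. Blocks under the minimum identity (default 99.5 %) are
dropped before pairing, mirroring the identity filter applied by the
upstream aligner. Whether the relocation distance should be measured in
the reference or contig frame when they disagree is not standardized; the
unified magnitude above is this package's documented convention, and it is
invariant under globally reversing a contig (tested).

## Window correlations

Per-base tracks: indel anchors, mismatch positions, coding bases, repeat
bases, non-coding non-repeat bases, G/C bases, depth, and zero-depth bases.
Indel tracks mark the anchor base only, keeping them structurally
comparable to mismatch tracks. "Coverage gap" means depth exactly 0 by
default (a threshold is configurable); chromosomes absent from the coverage
input simply omit their coverage tracks with a warning.

Window counts sum track values over `[i·s, i·s + w)` with the trailing
partial window dropped. Defaults `w = 500 bp`, `s = 250 bp` are the
midpoints of the procedure's stated ranges (100–1,000 bp windows, 50–500 bp
steps); no per-chromosome length scaling is applied, and the values used
are recorded in the output metadata. The correlation statistic is one
Pearson r per block of `B = 200` consecutive window counts, the block
advancing one count per step — the blockwise reading of "average
correlation for 200 consecutive counts". Spearman is available behind a
flag. Blocks where either series has zero variance are *undefined* (NaN +
mask), never zero: feature deserts such as telomeres must not fabricate
signal.

## The synthetic fixture generator

What it emulates: a small AT-rich haploid genome (defaults: 2 × 500 kb,
non-coding GC 0.15, coding GC ≈ 0.25, overall ≈ 20 % — the
*P. falciparum*-like regime), ~50 % coding across 300 valid ORFs (ATG
start, stop, no internal stops, spliced length ≡ 0 mod 3; ~30 % of genes
split by one intron to exercise splicing and phase), 10 % tandem
low-complexity repeats in intergenic space, piecewise-constant short-read
coverage with planted zero-depth gaps, and discrepancies injected per
region class: mismatch rates 3×10⁻⁴ (coding) and 5×10⁻⁴ (non-coding) per
bp, indel rates 2×10⁻⁵ and 4×10⁻⁴ — a planted non-coding/coding indel
density ratio ρ\* = 20, echoing the order of magnitude reported for
AT-rich genomes, with absolute rates chosen so the default 1 Mb fixture
carries > 500 variants and a coding indel expectation (~11) far enough
from zero for stable ratio recovery. Indel lengths follow P(ℓ) ∝ ℓ⁻³ over
1–85 bp, making small (≤5 bp) indels ≈ 99 % of the total as observed in
long-read assemblies. Coding mismatches are drawn uniformly over CDS
bases, so the synonymous:non-synonymous split follows the genetic-code
structure rather than being forced.

Ground-truth labels are computed at plant time from the construction
itself (the known ORF, strand, and codon), independently of the annotation
machinery — injection is the oracle. Planted events keep ≥ 2 bp separation
so labels stay unambiguous; coding indels are placed fully inside a single
CDS segment and non-coding indels fully clear of CDS, so edge-rule
ambiguity is exercised by targeted unit tests, not by the fixture.
All randomness flows through one `numpy.random.Generator`; a seed fully
determines every output byte.

What it does **not** emulate: read-level errors, realistic repeat
families, homopolymer-biased indel hotspots, overlapping genes, alternate
isoforms, organelle genomes, or N-containing references. A green
recovery test therefore establishes the correctness of the coordinate,
strand, phase, and counting logic — not robustness to messy real-world
annotation.

Breakpoint fixtures are engineered two-block contigs whose junction
discordance is exact by construction, so threshold boundaries (85/86,
12,000/12,001 bp) are tested to the base. Requests that contradict the
class thresholds are rejected rather than silently adjusted.

## Numerical and degenerate-input choices

* Zero coding discrepancies → infinite fold ratio (signalled, not NaN).
* Empty discrepancy lists, empty VCFs, chromosomes shorter than one
  window, and count series shorter than one block all produce empty/zero
  results with warnings, never exceptions.
* Statistical tests bound ratio recovery with delta-method Poisson
  intervals (sd of log ratio ≈ √(1/λ_cds + 1/λ_nc)), including the
  first-order small-count bias of a Poisson-count ratio when averaging
  across seeds; tolerances are derived from the planted rates, not fitted
  to observed outcomes.

## Known limitations

* Overlapping genes are supported by the annotation layer (per-transcript
  effects, counted-once regions) but not generated by the simulator.
* Effect annotation is codon-local: stop-gain downstream consequences,
  splice-site disruption, and domain-level impact are out of scope.
* The event-count accuracy definition undercounts the per-base impact of
  long indels by design; use size classes and indel-length sums when
  base-level impact matters.
* `read_gff3` loads models through an in-memory feature database; genomes
  with millions of features would want a disk-backed database instead.
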