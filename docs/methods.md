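# Methods

## The problem

Microexons — exons of at most 51 nt, and in the ultra-short class only
1–15 nt — are systematically missed by gene annotation pipelines: a 3-nt
exon inside a multi-kilobase intron looks like alignment noise. When the
annotation skips a coding microexon, the gene model either loses a few amino
acids (if the microexon length is a multiple of 3) or frameshifts
downstream, producing a truncated protein and spuriously long UTRs. This
package detects such microexons in raw genomic DNA, without RNA-seq, and
repairs the annotations that missed them.

## Microexon-tags

The microexon itself is too short to carry any usable sequence signal, so
the unit of comparison and prediction is the **microexon-tag**: the
microexon plus flanking coding sequence, 108 nt in total, translating to
36 aa. The tag is assembled in CDS space (UTR bases never enter a tag) and
always begins on a codon boundary, so the microexon's coding **phase** (CDS
nt upstream of it, mod 3) is implicit in the tag. A tag spans 3 exonic
blocks in the common case — left flank, microexon, right flank — and up to
5 when a flanking exon is itself shorter than the flank, with a hard cap at
5 blocks. When the flank runs into the start or stop codon the tag is
truncated there and flagged; only then is it shorter than 108 nt.

**Flank split.** Only the total length (108) and in-frame translation are
fixed by the tag definition; how the 108 − size flank nt are divided is a
convention. We use the near-symmetric split: target left flank
L₀ = ⌊(108 − size)/2⌋, reduced by up to 2 nt so the tag starts on a codon
boundary (equivalently L ≡ phase mod 3); the right flank takes the
remainder. The same convention is used when compiling models and when
reading microexon coordinates off scanner chains, so the choice is
self-consistent throughout; it is recorded implicitly in every model file
via the block sizes.

## Cluster models

Tags are grouped by (microexon size, phase) — a cluster must code for the
same insertion at the same codon position — and clustered within each group
by single-linkage over pairwise global alignment of the 36-aa translations
(BLOSUM62, gap open −11 / extend −1; normalized similarity = score divided
by the self-score of the shorter sequence; default threshold 0.6). Single
linkage over a fixed pairwise graph is independent of input order. The
alignment scheme and threshold are not dictated by the tag definition; they
are exposed as options, and the substitution table is data
(`Bio.Align.substitution_matrices`), not code.

Each cluster is compiled into a position frequency matrix (PFM) over the
108 columns, with truncated members contributing only to the columns they
cover (per-column coverage is stored next to the counts), and a log₂-odds
PWM:

    pwm[b][j] = log2( ((pfm[b][j] + α·bg[b]) / (coverage_j + α)) / bg[b] )

with pseudocount weight α = 1 distributed by the background (default
uniform 0.25, overridable by genome composition). `max_score` /
`min_score` are the column-wise best/worst sums; a model's consensus scores
exactly `max_score`. The model's block sizes are the majority block
structure among untruncated members (an error lists the members when there
is no majority, or when every member is truncated — a truncated-only
cluster has no anchor for the 108-column frame). Models are serialized as
versioned JSON with full float precision.

## Scanning

Scanning places the model's blocks on the target and chains them across
candidate introns. Between consecutive blocks the genomic gap must be 0
(intron absent — only in `allow_intronless` mode) or an intron of
35–10 000 nt beginning GT and ending AG on the prediction strand (GC donors
behind a flag). Splice dinucleotides are a hard constraint, not a score
term. Blocks are scored by summing the PWM over their columns; N bases
contribute 0 (background).

Two thresholds shape the search:

* **per-block threshold** (default 0.7 × the block's maximum score),
  applied to every block of at least `min_scored_block` = 10 nt. Shorter
  blocks — in particular 1–9 nt microexons — carry roughly 2 bits per
  position and cannot be meaningfully score-filtered: a single mismatch in
  a 3-nt block swamps any fractional threshold. They are therefore located
  purely by the splice-site chaining geometry between their scored
  neighbours. The threshold is part of the prediction semantics, applied
  identically in `scan` and in the brute-force oracle.
* **global threshold** on the min–max normalized chain score
  (raw − min)/(max − min) ∈ [0, 1], default 0.8. The "prediction score"
  reported in outputs is this normalized score and is labelled as such.

The production scanner anchors chains on the longest scored block's hit
list and extends junction by junction, enumerating acceptor/donor
positions; scored blocks are matched against their precomputed hit lists,
short blocks against all dinucleotide-compatible placements. Overlapping
chains of the same model and strand are resolved greedily: highest raw
score, then leftmost, then fewest absent introns. Both strands are scanned
by running the forward algorithm on the reverse complement and mapping
coordinates back; output coordinates are always on the input's forward
strand.

`brute_force_scan` re-derives predictions by exhaustive enumeration of
every block-0 start position and every admissible gap assignment, with no
anchoring and no early pruning, then applies the same semantic filters. It
is the scanner's independent oracle (identical position/strand/score sets
on seeded instances up to 2 kb) and refuses inputs over 5 kb.

Input length bounds of 200 nt – 1 Mnt mirror the prediction service the
method was designed for; they are defaults of `ScanOptions` and the CLI and
can be lifted by library callers (`min_len=0, max_len=None`).

## Annotation reconciliation

A microexon is classified against the closest annotated transcript —
maximal exonic-base overlap with the tag, ties to the lexicographically
smallest transcript id, falling back to the nearest transcript within
10 kb — as `annotated` (coincides exactly with an annotated coding exon),
`intronic_novel` (strictly inside an annotated intron: the skipping
misannotation), or `exon_overlapping` (inside or across a larger exon:
alternative splicing or misannotation; status only, no automatic surgery).
Intron-located novel microexons are repaired: the microexon becomes a new
internal exon, the transcript id gains an `x` suffix (extended past
collisions), and the CDS is recomputed by translating from the original
start codon through the corrected chain to the first in-frame stop. An
insertion that introduces a premature stop is emitted with a
`nonsense_after_insertion` flag rather than suppressed. Percent overlap
between structures is exonic-base Jaccard × 100 — symmetric, in [0, 100] —
which approximates, but has not been verified bit-exact against, the
pctOverlap measure used by transcript-assembly comparison tools.

## Junction validation

A microexon is RNA-seq-supported iff **both** flanking introns appear in
the splice-junction evidence with exactly matching coordinates and
compatible strand (no slop: aligners report precise introns). Junction
files use the STAR `SJ.out.tab` 9-column dialect; replicates are unioned
with unique-read counts summed, and the default `min_unique` is 1 (the
weakest reading of "read support"; support in any replicate counts).
Intronless-mode predictions have no flanking introns and are unsupported by
definition. Empty categories report NA, not 0.

## Synthetic data

The simulator plants one tag per locus: the cluster consensus (or a
user-supplied model's), mutated at a per-base rate, split by GT–AG introns
of 60–200 nt (or contiguous with probability `fraction_intronless`), inside
200–500 nt of i.i.d. background, one chromosome per locus, strands drawn
uniformly. It emits the truth annotation, a skipped annotation in which the
microexon is removed and its flanks joined by one long intron, junction
files in which both flanking introns appear with probability
`junction_support_rate` (otherwise at most one side), and a truth table.
All randomness flows through a single seeded generator; identical configs
give byte-identical files.

What the generator does **not** model: repeats and paralogy (so decoy
specificity results do not bound false-positive rates on real genomes),
intron length distributions beyond uniform, splice-site motifs beyond the
dinucleotides, sequencing noise, and expression variation. Passing tests
demonstrate the algorithms' correctness on their own terms, not recall on
real plant genomes.

## Numerical and degenerate-input choices

* Zero-coverage PFM columns get log-odds 0 for every base (pure
  pseudocount), so they neither help nor hurt a placement.
* Consensus ties break in fixed A,C,G,T order; prediction ordering is fully
  deterministic (position, then score descending, then cluster id, then
  strand).
* Normalized scores are clamped to [0, 1] against float epsilon.
* Model JSON round trips are exact to ≤ 1e-9 (floats serialized at full
  precision).
* Problem sizes used by the acceptance script — 45-combination tag sweep,
  50 planted loci (+100 decoys) for recovery, 100 oracle instances ≤ 2 kb,
  30 repair loci, 1000 junction loci — are desk-scale choices that keep a
  full run around two seconds while leaving each estimate's sampling error
  well inside its check.

## Known limitations

* **Tied placements of tiny microexons.** At mutation rate 0, a planted
  1–3 nt microexon occasionally (order 2% of loci) has a second placement
  with an identical, maximal score: a chance copy of the microexon motif
  with canonical dinucleotides inside one of its own introns, with the same
  flank placements and hence the same tag span. The two chains are
  indistinguishable in principle; the deterministic tie-break may report
  the non-planted one. This is inherent to ultra-short exons, not a search
  failure — the oracle returns the same tie.
* Clustering cost is quadratic in group size; groups beyond a few thousand
  tags would need a pre-filter.
* The scanner iterates per sequence; whole-genome scans parallelize
  naturally per chromosome but no orchestration is included.
* GFF3 handling covers the gene/mRNA/exon/CDS dialect with ID/Parent
  attributes; GTF and exotic attribute schemes are out of scope.
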