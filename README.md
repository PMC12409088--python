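# microtag

Microexon-tag models, genomic scanning and gene-annotation repair.

Microexons — coding exons of ≤ 51 nt, and in the ultra-short class just
1–15 nt — are routinely missing from plant genome annotations: conventional
gene predictors and spliced aligners cannot place a 3-nt exon inside a long
intron, so the annotation either skips it (deleting amino acids) or
frameshifts downstream of it (truncating the protein). `microtag` is a
toolkit for finding these exons in raw genomic DNA **without RNA-seq** and
for repairing the annotations that missed them. It is aimed at genome
annotators, comparative genomicists and anyone curating gene models in
newly assembled plant (or other eukaryote) genomes.

## The method

The microexon itself is too short to align, so the unit of modelling is the
**microexon-tag**: the microexon plus flanking coding sequence, 108 nt
≙ 36 aa, spliced across 3–5 exons and always starting on a codon boundary.
Tags from many genes are grouped by (microexon size, phase), clustered by
pairwise global alignment of their translations, and each cluster is
compiled into a position weight matrix over the tag's W = 108 columns,

    pwm[b][j] = log2( ((pfm[b][j] + α·bg[b]) / (cov_j + α)) / bg[b] ),

where `pfm` holds column base counts, `cov_j` per-column member coverage,
`bg` the background base frequencies and α a pseudocount (default 1).
The tag columns are partitioned into exonic **blocks**; scanning a genomic
sequence places each block (scored by its PWM sub-matrix) and chains the
placements across candidate introns: every gap between blocks is either 0
(intron absent, optional mode) or 35–10 000 nt starting `GT` and ending
`AG` on the prediction strand. The microexon's coordinates are read off its
block in the winning chain, and a chain is reported when its min–max
normalized score (raw − min)/(max − min) reaches the global threshold
(default 0.8). Both strands are scanned; 1–9 nt microexon blocks are placed
by splice-site geometry alone, since a handful of PWM columns cannot be
score-filtered meaningfully.

Around the scanner the package provides: tag extraction from genome + GFF3
(`tag_extraction`), cluster-model building and JSON serialization
(`cluster_model`), annotation reconciliation — classifying each microexon
as annotated / intron-located novel / exon-overlapping, and splicing novel
ones into their host transcript as `<id>x` with recomputed CDS and protein
(`annotation_update`) — validation against STAR `SJ.out.tab` splice
junctions, supported ⇔ both flanking introns observed
(`junction_validation`), a fully seeded synthetic-data generator
(`synthetic_data`), and an exhaustive brute-force oracle used to verify the
scanner (`scanner.brute_force_scan`). See `docs/methods.md` for the model
details and design choices.

## Worked example

Simulate three loci with planted microexon-tags, then scan the genome with
the generated cluster models:

```sh
microtag simulate --seed 11 --n-loci 3 --n-models 2 --outdir demo
microtag scan --models demo/models.json --fasta demo/genome.fa --out demo/predictions.tsv
```

`demo/predictions.tsv` (coordinates 1-based):

```text
seqid      cluster_id  strand  microexon_start  microexon_end  block_starts  block_ends   intron_starts  intron_ends  raw_score  normalized_score  splice_flags
locus0001  SYN01       +       535              537            335,535,661   385,537,714  386,538        534,660      195.1943   1.0               canonical,canonical
locus0002  SYN02       -       654              658            442,654,823   493,658,873  494,659        653,822      195.1943   1.0               canonical,canonical
locus0003  SYN01       -       586              588            339,586,724   392,588,774  393,589        585,723      195.1943   1.0               canonical,canonical
```

Each row is one chained tag placement: on `locus0001` a 3-nt microexon at
535–537 on the forward strand, flanked by two canonical GT–AG introns
(386–534 and 538–660), with a raw PWM score of 195.19 bits — the model's
maximum, hence normalized score 1.0, as expected for unmutated planted
tags. The truth table written by the simulator (`demo/truth.tsv`) confirms
the placements:

```text
locus_id  chrom      strand  cluster_id  microexon_start  microexon_end  size  phase
L0001     locus0001  +       SYN01       535              537            3     0
L0002     locus0002  -       SYN02       654              658            5     0
L0003     locus0003  -       SYN01       586              588            3     0
```

From here, `microtag update-gff` classifies predictions against an
annotation and emits repaired `x`-suffixed transcripts with recomputed CDS
and protein, and `microtag validate` summarizes junction support per
category. `microtag build-model` runs the reverse direction: from a genome,
GFF3 and microexon list to a cluster-model file.

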