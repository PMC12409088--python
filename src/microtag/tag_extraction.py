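"""Microexon-tag extraction.

A microexon-tag is the spliced signature of a coding microexon: the microexon
itself plus portions of its flanking coding exons, 108 nt in total (36 aa)
when the surrounding CDS is long enough, shorter when the flanks run into the
start or stop codon. Tags span 3 exons in the common case and up to 5 when a
flanking exon is itself short. The tag always begins on a codon boundary of
the source CDS, so its translation is in frame; the microexon's coding phase
(upstream CDS length mod 3) is thereby encoded in the tag.

Flank split convention: for tag length T and microexon size s the target left
flank is L0 = floor((T - s) / 2), reduced by up to 2 nt so the tag starts on a
codon boundary; the right flank takes the remainder. The same convention is
used when compiling cluster models and when mapping scanner hits back to
microexon coordinates, so the choice is self-consistent end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomic_model import (
    GeneModel,
    GenomicInterval,
    Microexon,
    MicrotagError,
    spliced_sequence,
    transcript_to_genomic,
    translate_full,
)

DEFAULT_TAG_LEN = 108
MAX_BLOCKS = 5


class NotInternalError(MicrotagError):
    """The microexon has no coding exon on one of its sides."""


class TagSpanError(MicrotagError):
    """The tag would need more than MAX_BLOCKS exon blocks."""


@dataclass
class MicroexonTag:
    """A spliced microexon signature of <= ``tag_len`` nt (<= 36 aa)."""

    microexon: Microexon
    blocks: list[tuple[GenomicInterval, int]]  # transcript orientation
    microexon_block_index: int
    nt_sequence: str
    aa_sequence: str
    phase: int
    truncated_left: bool
    truncated_right: bool
    transcript_id: str
    chrom: str
    strand: str
    tag_id: str = ""
    species: str = ""

    @property
    def left_flank_len(self) -> int:
        return sum(n for _, n in self.blocks[: self.microexon_block_index])

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.blocks)

    @property
    def untruncated(self) -> bool:
        return not (self.truncated_left or self.truncated_right)


def canonical_left_flank(size: int, phase: int, tag_len: int = DEFAULT_TAG_LEN) -> int:
    """Left flank length of an untruncated tag for a given microexon size and
    phase: the near-symmetric split shifted onto a codon boundary.

    The tag's first base sits at CDS offset (upstream - L); requiring that to
    be 0 mod 3 with upstream = phase (mod 3) fixes L mod 3 = phase.
    """
    l0 = (tag_len - size) // 2
    return l0 - ((l0 - phase) % 3)


def microexon_phase(model: GeneModel, me: GenomicInterval) -> int:
    """Coding phase of a microexon: CDS nt strictly upstream of it
    (5'->3' in transcript orientation) mod 3."""
    upstream = 0
    for seg in model.cds:
        if seg.start == me.start and seg.end == me.end:
            return upstream % 3
        upstream += seg.length
    raise MicrotagError(
        f"{me.chrom}:{me.start}-{me.end} is not a CDS segment of "
        f"{model.transcript_id}"
    )


def extract_tag(
    model: GeneModel,
    me: Microexon,
    genome: dict[str, str],
    tag_len: int = DEFAULT_TAG_LEN,
) -> MicroexonTag:
    """Extract the microexon-tag around ``me`` from its source gene model.

    The microexon must be internal (at least one coding exon on each side).
    Flanks are measured in CDS space — UTR bases never enter a tag — and are
    truncated at the start/stop codon, setting the corresponding flags.
    """
    if tag_len % 3 != 0:
        raise ValueError("tag_len must be a multiple of 3")
    me_idx = None
    for i, seg in enumerate(model.cds):
        if seg.start == me.interval.start and seg.end == me.interval.end:
            me_idx = i
            break
    if me_idx is None:
        raise MicrotagError(
            f"microexon {me.interval.chrom}:{me.interval.start}-{me.interval.end} "
            f"is not a CDS segment of {model.transcript_id}"
        )
    if me_idx == 0 or me_idx == len(model.cds) - 1:
        raise NotInternalError(
            f"microexon in {model.transcript_id} is terminal "
            "(no flanking coding exon on one side)"
        )

    size = me.size
    upstream = sum(seg.length for seg in model.cds[:me_idx])
    downstream = model.cds_length - upstream - size
    phase = upstream % 3

    flank_total = tag_len - size
    l0 = flank_total // 2
    l_target = l0 - ((l0 - upstream) % 3)  # tag start on a codon boundary
    r_target = flank_total - l_target
    left = min(l_target, upstream)
    right = min(r_target, downstream)
    truncated_left = upstream < l_target
    truncated_right = downstream < r_target

    # coding-space span of the tag, mapped back through the CDS chain
    cds_start = upstream - left
    span_len = left + size + right
    blocks: list[tuple[GenomicInterval, int]] = []
    block_idx = None
    off = 0
    covered = 0
    for i, seg in enumerate(model.cds):
        lo = max(cds_start - off, 0)
        hi = min(cds_start + span_len - off, seg.length)
        if lo < hi:
            if model.strand == "+":
                iv = GenomicInterval(seg.chrom, seg.start + lo, seg.start + hi, "+")
            else:
                iv = GenomicInterval(seg.chrom, seg.end - hi, seg.end - lo, "-")
            blocks.append((iv, hi - lo))
            if i == me_idx:
                block_idx = len(blocks) - 1
            covered += hi - lo
        off += seg.length
    assert covered == span_len and block_idx is not None

    if len(blocks) > MAX_BLOCKS:
        raise TagSpanError(
            f"tag for {model.transcript_id} would span {len(blocks)} exon "
            f"blocks (limit {MAX_BLOCKS}): "
            + ", ".join(f"{iv.start}-{iv.end}" for iv, _ in blocks)
        )

    shim = GeneModel(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=[iv for iv, _ in blocks],
        cds=[iv for iv, _ in blocks],
    )
    nt = spliced_sequence(shim, genome, "cds")
    aa = translate_full(nt).aa if len(nt) >= 3 else ""

    return MicroexonTag(
        microexon=Microexon(
            interval=me.interval,
            phase=phase,
            parent_transcript=model.transcript_id,
            cluster_id=me.cluster_id,
        ),
        blocks=blocks,
        microexon_block_index=block_idx,
        nt_sequence=nt,
        aa_sequence=aa,
        phase=phase,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=model.strand,
    )


# ---------------------------------------------------------------------------
# tag table I/O

_TAG_COLUMNS = [
    "tag_id",
    "species",
    "transcript_id",
    "chrom",
    "strand",
    "block_starts",
    "block_ends",
    "microexon_block_index",
    "microexon_size",
    "phase",
    "nt_sequence",
    "aa_sequence",
    "truncated_left",
    "truncated_right",
]


def write_tags(tags: list[MicroexonTag], path) -> None:
    """Tag table TSV; block coordinates are GFF-style 1-based closed lists."""
    rows = []
    for i, t in enumerate(tags):
        rows.append(
            {
                "tag_id": t.tag_id or f"tag{i + 1:05d}",
                "species": t.species or ".",
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "block_starts": ",".join(str(iv.start + 1) for iv, _ in t.blocks),
                "block_ends": ",".join(str(iv.end) for iv, _ in t.blocks),
                "microexon_block_index": t.microexon_block_index,
                "microexon_size": t.microexon.size,
                "phase": t.phase,
                "nt_sequence": t.nt_sequence,
                "aa_sequence": t.aa_sequence,
                "truncated_left": t.truncated_left,
                "truncated_right": t.truncated_right,
            }
        )
    pd.DataFrame(rows, columns=_TAG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tags(path) -> list[MicroexonTag]:
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    missing = set(_TAG_COLUMNS) - set(df.columns)
    if missing:
        raise MicrotagError(f"tag table missing columns: {sorted(missing)}")
    tags = []
    for row in df.itertuples(index=False):
        starts = [int(x) - 1 for x in str(row.block_starts).split(",")]
        ends = [int(x) for x in str(row.block_ends).split(",")]
        strand = row.strand
        ivs = [GenomicInterval(row.chrom, s, e, strand) for s, e in zip(starts, ends)]
        if strand == "-":  # stored genomically ascending -> transcript order
            ivs_tx = sorted(ivs, key=lambda iv: iv.start, reverse=True)
        else:
            ivs_tx = sorted(ivs, key=lambda iv: iv.start)
        blocks = [(iv, iv.length) for iv in ivs_tx]
        bi = int(row.microexon_block_index)
        tags.append(
            MicroexonTag(
                microexon=Microexon(
                    interval=blocks[bi][0],
                    phase=int(row.phase),
                    parent_transcript=row.transcript_id,
                ),
                blocks=blocks,
                microexon_block_index=bi,
                nt_sequence=row.nt_sequence,
                aa_sequence="" if pd.isna(row.aa_sequence) else row.aa_sequence,
                phase=int(row.phase),
                truncated_left=bool(row.truncated_left),
                truncated_right=bool(row.truncated_right),
                transcript_id=row.transcript_id,
                chrom=row.chrom,
                strand=strand,
                tag_id=row.tag_id,
                species="" if row.species == "." else row.species,
            )
        )
    return tags


__all__ = [
    "DEFAULT_TAG_LEN",
    "MAX_BLOCKS",
    "MicroexonTag",
    "NotInternalError",
    "TagSpanError",
    "canonical_left_flank",
    "microexon_phase",
    "extract_tag",
    "write_tags",
    "read_tags",
]
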