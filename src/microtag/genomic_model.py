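"""Core genomic types and I/O: intervals, gene models, FASTA/GFF3, translation.

Internal coordinates are 0-based half-open throughout; GFF3 is consumed and
emitted in its native 1-based closed convention, BED in 0-based half-open.
Exon and CDS lists of a :class:`GeneModel` are ordered 5'->3' in *transcript*
orientation, so minus-strand models hold genomically descending intervals.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
_BAD_BASE = re.compile("[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MicrotagError(Exception):
    """Base class for all errors raised by this package."""


class FastaError(MicrotagError):
    pass


class Gff3Error(MicrotagError):
    pass


class CoordinateError(MicrotagError):
    pass


class TranslationError(MicrotagError):
    pass


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A,C,G,T,N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Microexon:
    """A very short internal coding exon (<= 51 nt; ultra-short class 1-15 nt)."""

    interval: GenomicInterval
    phase: int
    parent_transcript: str = ""
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.size <= 51:
            raise CoordinateError(
                f"microexon size {self.size} outside 1..51 nt"
            )
        if self.phase not in (0, 1, 2):
            raise CoordinateError(f"invalid phase {self.phase}")

    @property
    def size(self) -> int:
        return self.interval.length

    @property
    def is_ultra_short(self) -> bool:
        return self.size <= 15


@dataclass
class GeneModel:
    """One transcript: ordered exon and CDS intervals in transcript orientation.

    ``partial`` flags a CDS whose length is not a multiple of 3; ``invalid``
    flags structural problems found at parse time (e.g. CDS outside exons).
    ``start_codon_pos`` is the transcript-space offset (nt) of the first CDS
    base.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    partial: bool = False
    invalid: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def span(self) -> GenomicInterval:
        starts = [iv.start for iv in self.exons]
        ends = [iv.end for iv in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def start_codon_pos(self) -> int:
        if not self.cds:
            raise CoordinateError(f"{self.transcript_id}: no CDS")
        first = self.cds[0]
        anchor = first.start if self.strand == "+" else first.end - 1
        return genomic_to_transcript(self.exons, self.strand, anchor)

    def introns(self) -> list[GenomicInterval]:
        """Introns between consecutive exons, in transcript orientation."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    def validate(self) -> "GeneModel":
        """Set ``partial``/``invalid`` flags from the exon/CDS structure."""
        genomic = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                self.invalid = True
                self.flags.append(f"overlapping exons {a} / {b}")
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                self.invalid = True
                self.flags.append(f"CDS {c.start}-{c.end} outside exons")
        if self.cds and self.cds_length % 3 != 0:
            self.partial = True
        return self


def transcript_to_genomic(
    exons: list[GenomicInterval], strand: str, tx_start: int, tx_len: int
) -> list[GenomicInterval]:
    """Map transcript-space range [tx_start, tx_start+tx_len) onto genomic
    intervals, returned in transcript orientation."""
    if tx_len <= 0:
        raise CoordinateError("empty transcript range")
    out = []
    off = 0
    remaining_start, remaining_end = tx_start, tx_start + tx_len
    for iv in exons:
        lo = max(remaining_start - off, 0)
        hi = min(remaining_end - off, iv.length)
        if lo < hi:
            if strand == "+":
                out.append(
                    GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi, strand)
                )
            else:
                out.append(
                    GenomicInterval(iv.chrom, iv.end - hi, iv.end - lo, strand)
                )
        off += iv.length
    if off < remaining_end:
        raise CoordinateError(
            f"transcript range {tx_start}+{tx_len} beyond spliced length {off}"
        )
    return out


def genomic_to_transcript(
    exons: list[GenomicInterval], strand: str, pos: int
) -> int:
    """Transcript-space offset of genomic base ``pos`` (must be exonic)."""
    off = 0
    for iv in exons:
        if iv.start <= pos < iv.end:
            within = pos - iv.start if strand == "+" else iv.end - 1 - pos
            return off + within
        off += iv.length
    raise CoordinateError(f"position {pos} not exonic")


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path) -> dict[str, str]:
    """Read a multi-record FASTA into {id: upper-case sequence}.

    The alphabet is restricted to A, C, G, T, N; anything else (U, gaps,
    IUPAC ambiguity codes) is rejected with its record and 1-based offset.
    """
    genome: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _store() -> None:
        if current is None:
            return
        seq = "".join(chunks).upper()
        m = _BAD_BASE.search(seq)
        if m:
            raise FastaError(
                f"record {current!r}: illegal character {m.group()!r} "
                f"at position {m.start() + 1} (alphabet is A,C,G,T,N)"
            )
        if not seq:
            raise FastaError(f"record {current!r} is empty")
        genome[current] = seq

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _store()
                current = line[1:].split()[0] if len(line) > 1 else ""
                if not current:
                    raise FastaError(f"line {lineno}: empty FASTA header")
                if current in genome:
                    raise FastaError(f"line {lineno}: duplicate record {current!r}")
                chunks = []
            else:
                if current is None:
                    raise FastaError(
                        f"line {lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _store()
    if not genome:
        raise FastaError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file into GeneModels.

    1-based closed GFF3 coordinates become internal 0-based half-open ones,
    and minus-strand exon/CDS lists are reordered 5'->3' in transcript
    orientation. Structural problems set the ``invalid`` flag rather than
    dropping the model.
    """
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3Error(f"line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise Gff3Error(f"line {lineno}: non-numeric coordinates") from exc
            attributes = _parse_attributes(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = attributes.get("ID", "")
                if not tid:
                    raise Gff3Error(f"line {lineno}: mRNA without ID attribute")
                transcripts[tid] = {
                    "gene_id": attributes.get("Parent", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                }
            elif ftype in ("exon", "CDS"):
                for parent in attributes.get("Parent", "").split(","):
                    rec = transcripts.get(parent)
                    if rec is None:
                        # feature before its mRNA or orphan; register lazily
                        rec = transcripts.setdefault(
                            parent,
                            {
                                "gene_id": parent,
                                "chrom": chrom,
                                "strand": strand,
                                "exons": [],
                                "cds": [],
                            },
                        )
                    iv = GenomicInterval(chrom, start1 - 1, end1, strand)
                    rec["exons" if ftype == "exon" else "cds"].append(iv)

    models = []
    for tid, rec in transcripts.items():
        exons = sorted(rec["exons"], key=lambda iv: iv.start)
        cds = sorted(rec["cds"], key=lambda iv: iv.start)
        if not exons and cds:
            exons = list(cds)  # CDS-only transcript
        if rec["strand"] == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        model = GeneModel(
            gene_id=rec["gene_id"],
            transcript_id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            cds=cds,
        )
        models.append(model.validate())
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def write_gff3(models: list[GeneModel], path, source: str = "microtag") -> None:
    """Emit gene/mRNA/exon/CDS features (1-based closed), CDS frame included."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id, ms in by_gene.items():
        chrom, strand = ms[0].chrom, ms[0].strand
        lo = min(m.span.start for m in ms)
        hi = max(m.span.end for m in ms)
        buf.write(
            f"{chrom}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n"
        )
        for m in ms:
            buf.write(
                f"{chrom}\t{source}\tmRNA\t{m.span.start + 1}\t{m.span.end}\t.\t"
                f"{strand}\t.\tID={m.transcript_id};Parent={gene_id}\n"
            )
            for iv in sorted(m.exons, key=lambda iv: iv.start):
                buf.write(
                    f"{chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{strand}\t.\tParent={m.transcript_id}\n"
                )
            cum = 0
            frames = {}
            for iv in m.cds:  # transcript orientation for frame arithmetic
                frames[(iv.start, iv.end)] = (3 - cum % 3) % 3
                cum += iv.length
            for iv in sorted(m.cds, key=lambda iv: iv.start):
                fr = frames[(iv.start, iv.end)]
                buf.write(
                    f"{chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{strand}\t{fr}\tParent={m.transcript_id}\n"
                )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# sequence assembly and translation

def spliced_sequence(
    model: GeneModel, genome: dict[str, str], which: str = "cds"
) -> str:
    """Concatenated exonic (or CDS) sequence in transcript orientation.

    Minus-strand intervals are reverse complemented; intervals out of
    chromosome bounds raise a CoordinateError naming the interval.
    """
    if which not in ("exon", "cds"):
        raise ValueError("which must be 'exon' or 'cds'")
    intervals = model.exons if which == "exon" else model.cds
    parts = []
    for iv in intervals:
        chrom_seq = genome.get(iv.chrom)
        if chrom_seq is None:
            raise CoordinateError(f"unknown sequence {iv.chrom!r}")
        if iv.end > len(chrom_seq):
            raise CoordinateError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence "
                f"end ({len(chrom_seq)})"
            )
        seg = chrom_seq[iv.start : iv.end]
        parts.append(reverse_complement(seg) if model.strand == "-" else seg)
    return "".join(parts)


@dataclass(frozen=True)
class TranslationResult:
    aa: str
    stopped: bool  # an in-frame stop codon truncated the translation
    trailing_nt: int  # 1-2 nt left over after the last full codon


def translate_full(cds: str) -> TranslationResult:
    """Translate with the standard genetic code, stopping at the first stop."""
    if not cds:
        raise TranslationError("empty coding sequence")
    if len(cds) < 3:
        raise TranslationError(f"coding sequence of {len(cds)} nt (< one codon)")
    trailing = len(cds) % 3
    core = cds[: len(cds) - trailing] if trailing else cds
    aa_all = str(Seq(core).translate())
    stopped = "*" in aa_all
    aa = aa_all.split("*", 1)[0]
    return TranslationResult(aa=aa, stopped=stopped, trailing_nt=trailing)


def translate(cds: str) -> str:
    return translate_full(cds).aa


__all__ = [
    "MicrotagError",
    "FastaError",
    "Gff3Error",
    "CoordinateError",
    "TranslationError",
    "GenomicInterval",
    "Microexon",
    "GeneModel",
    "TranslationResult",
    "reverse_complement",
    "read_genome",
    "write_genome",
    "read_gff3",
    "write_gff3",
    "spliced_sequence",
    "translate",
    "translate_full",
    "transcript_to_genomic",
    "genomic_to_transcript",
]
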