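"""RNA-seq splice-junction support for microexons.

A microexon is considered supported by RNA-seq iff *both* of its flanking
introns appear in the splice-junction evidence (STAR ``SJ.out.tab`` files)
with exactly matching coordinates and compatible strand. Support proportions
are aggregated per detection category (predicted only / annotated only /
detected by both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genomic_model import GenomicInterval, MicrotagError
from .scanner import Prediction

SJ_COLUMNS = [
    "chrom",
    "intron_first",  # 1-based first intronic base
    "intron_last",  # 1-based last intronic base
    "strand_code",  # 0 undefined, 1 '+', 2 '-'
    "motif_code",
    "annotated",
    "unique_reads",
    "multi_reads",
    "max_overhang",
]

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}


class JunctionFormatError(MicrotagError):
    pass


@dataclass(frozen=True)
class JunctionRecord:
    """One observed intron: internal 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (undefined)
    unique_reads: int
    multi_reads: int = 0


class JunctionSet:
    """Union of junctions across replicates, keyed by (chrom, start, end)."""

    def __init__(self, records: list[JunctionRecord] | None = None) -> None:
        self._by_coord: dict[tuple[str, int, int], JunctionRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: JunctionRecord) -> None:
        key = (rec.chrom, rec.start, rec.end)
        prev = self._by_coord.get(key)
        if prev is None:
            self._by_coord[key] = rec
        else:
            strand = prev.strand if prev.strand != "." else rec.strand
            self._by_coord[key] = JunctionRecord(
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                strand=strand,
                unique_reads=prev.unique_reads + rec.unique_reads,
                multi_reads=prev.multi_reads + rec.multi_reads,
            )

    def __len__(self) -> int:
        return len(self._by_coord)

    def __iter__(self):
        return iter(self._by_coord.values())

    def contains(self, chrom: str, start: int, end: int, strand: str = ".") -> bool:
        rec = self._by_coord.get((chrom, start, end))
        if rec is None:
            return False
        return strand == "." or rec.strand == "." or rec.strand == strand


def read_junctions(paths, min_unique: int = 1) -> JunctionSet:
    """Union of STAR SJ.out.tab files, keeping junctions whose summed unique
    read count reaches ``min_unique``.

    STAR reports 1-based first/last intronic bases; internally an intron
    (first=101, last=180) becomes the half-open interval [100, 180).
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    merged = JunctionSet()
    for path in paths:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise JunctionFormatError(
                        f"{path}:{lineno}: expected 9 tab-separated columns, "
                        f"got {len(cols)}"
                    )
                try:
                    first, last = int(cols[1]), int(cols[2])
                    strand_code = int(cols[3])
                    unique = int(cols[6])
                    multi = int(cols[7])
                except ValueError as exc:
                    raise JunctionFormatError(
                        f"{path}:{lineno}: non-numeric field"
                    ) from exc
                if first > last or unique < 0 or multi < 0:
                    raise JunctionFormatError(
                        f"{path}:{lineno}: invalid junction "
                        f"({first} > {last} or negative counts)"
                    )
                merged.add(
                    JunctionRecord(
                        chrom=cols[0],
                        start=first - 1,
                        end=last,
                        strand=_STRAND_FROM_CODE.get(strand_code, "."),
                        unique_reads=unique,
                        multi_reads=multi,
                    )
                )
    filtered = JunctionSet(
        [rec for rec in merged if rec.unique_reads >= min_unique]
    )
    return filtered


def write_junctions(records: list[JunctionRecord], path) -> None:
    """Emit records in the 9-column SJ.out.tab dialect."""
    code = {"+": 1, "-": 2, ".": 0}
    with open(path, "w") as fh:
        for r in records:
            motif = 1 if r.strand == "+" else (2 if r.strand == "-" else 0)
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.end}\t{code[r.strand]}\t{motif}\t0\t"
                f"{r.unique_reads}\t{r.multi_reads}\t20\n"
            )


# ---------------------------------------------------------------------------
# support

def flanking_introns(
    obj, me_interval: GenomicInterval | None = None
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """The introns immediately flanking a microexon.

    ``obj`` is a scanner Prediction (introns read off the chain around the
    microexon block) or a GeneModel (``me_interval`` names the microexon
    exon). Either side is None when no intron exists there.
    """
    if isinstance(obj, Prediction):
        left = right = None
        for iv in obj.intron_intervals:
            if iv.end == obj.microexon.start:
                left = iv
            if iv.start == obj.microexon.end:
                right = iv
        return left, right
    if me_interval is None:
        raise ValueError("me_interval required for GeneModel input")
    left = right = None
    for intron in obj.introns():
        if intron.end == me_interval.start:
            left = intron
        if intron.start == me_interval.end:
            right = intron
    return left, right


def is_supported(
    chrom: str,
    strand: str,
    left_intron: GenomicInterval | None,
    right_intron: GenomicInterval | None,
    junctions: JunctionSet,
) -> bool:
    """True iff both flanking introns are present with matching coordinates.

    Microexons without two defined flanking introns (e.g. intronless-mode
    predictions) are unsupported by definition.
    """
    if left_intron is None or right_intron is None:
        return False
    return junctions.contains(
        chrom, left_intron.start, left_intron.end, strand
    ) and junctions.contains(chrom, right_intron.start, right_intron.end, strand)


def prediction_supported(pred: Prediction, junctions: JunctionSet) -> bool:
    left, right = flanking_introns(pred)
    return is_supported(pred.seqid, pred.strand, left, right, junctions)


@dataclass
class CategorySupport:
    category: str
    n_total: int
    n_supported: int

    @property
    def proportion(self) -> float:
        """Support percentage; NaN for an empty category."""
        if self.n_total == 0:
            return math.nan
        return 100.0 * self.n_supported / self.n_total


def summarize(
    categorized: dict[str, list[tuple[str, str, GenomicInterval | None, GenomicInterval | None]]],
    junctions: JunctionSet,
) -> dict[str, CategorySupport]:
    """Per-category support summary.

    ``categorized`` maps a category name (e.g. predicted_only, annotated_only,
    both) to items of (chrom, strand, left_intron, right_intron).
    """
    out = {}
    for category, items in categorized.items():
        supported = sum(
            1
            for chrom, strand, left, right in items
            if is_supported(chrom, strand, left, right, junctions)
        )
        out[category] = CategorySupport(
            category=category, n_total=len(items), n_supported=supported
        )
    return out


def summary_to_table(summary: dict[str, CategorySupport]) -> pd.DataFrame:
    rows = [
        {
            "category": s.category,
            "n_total": s.n_total,
            "n_supported": s.n_supported,
            "proportion_pct": (
                "NA" if math.isnan(s.proportion) else round(s.proportion, 1)
            ),
        }
        for s in summary.values()
    ]
    return pd.DataFrame(rows, columns=["category", "n_total", "n_supported", "proportion_pct"])


__all__ = [
    "SJ_COLUMNS",
    "JunctionRecord",
    "JunctionSet",
    "JunctionFormatError",
    "read_junctions",
    "write_junctions",
    "flanking_introns",
    "is_supported",
    "prediction_supported",
    "CategorySupport",
    "summarize",
    "summary_to_table",
]
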