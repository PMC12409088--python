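"""Reconcile microexons with a reference annotation.

A microexon found by the scanner (or listed in a truth table) is classified
against its closest annotated transcript as

* ``annotated`` — it coincides exactly with an annotated exon's coding part,
* ``intronic_novel`` — it lies strictly inside an annotated intron (the
  microexon-skipping misannotation mode: the annotation joined the flanks
  with one long intron), or
* ``exon_overlapping`` — it overlaps or sits inside a larger annotated exon
  (alternative splicing or misannotation; no automatic surgery).

Intron-located novel microexons are repaired by transcript surgery: the
microexon is spliced into the exon chain of the closest transcript, the new
transcript gets the old id plus an ``x`` suffix, and the CDS and protein are
recomputed by translating from the original start codon through the corrected
chain to the first in-frame stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genomic_model import (
    CoordinateError,
    GeneModel,
    GenomicInterval,
    Microexon,
    genomic_to_transcript,
    spliced_sequence,
    transcript_to_genomic,
    translate_full,
)
from .tag_extraction import MicroexonTag

CATEGORY_ANNOTATED = "annotated"
CATEGORY_INTRONIC = "intronic_novel"
CATEGORY_EXONIC = "exon_overlapping"
CATEGORY_ORPHAN = "orphan"

DEFAULT_ORPHAN_WINDOW = 10_000


@dataclass
class MicroexonStatus:
    microexon: Microexon
    closest_transcript: str | None
    category: str
    pct_overlap: float
    new_transcript_id: str | None = None
    flags: list[str] | None = None


def _merged_intervals(ivs: list[GenomicInterval]) -> list[tuple[int, int]]:
    spans = sorted((iv.start, iv.end) for iv in ivs)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _exonic_intervals(obj) -> tuple[str, str, list[GenomicInterval]]:
    if isinstance(obj, GeneModel):
        return obj.chrom, obj.strand, obj.exons
    if isinstance(obj, MicroexonTag):
        return obj.chrom, obj.strand, [iv for iv, _ in obj.blocks]
    raise TypeError(f"expected GeneModel or MicroexonTag, got {type(obj).__name__}")


def pct_overlap(a, b) -> float:
    """Percent exonic overlap between two transcript structures: 100 x
    shared exonic bases / exonic union bases (Jaccard on exonic bases)."""
    chrom_a, _sa, ivs_a = _exonic_intervals(a)
    chrom_b, _sb, ivs_b = _exonic_intervals(b)
    if chrom_a != chrom_b:
        warnings.warn(
            f"pct_overlap across different sequences ({chrom_a} vs {chrom_b}) is 0",
            stacklevel=2,
        )
        return 0.0
    ma, mb = _merged_intervals(ivs_a), _merged_intervals(ivs_b)
    inter = 0
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s < e:
            inter += e - s
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    len_a = sum(e - s for s, e in ma)
    len_b = sum(e - s for s, e in mb)
    union = len_a + len_b - inter
    return 100.0 * inter / union if union else 0.0


def _tag_overlap_bases(tag_ivs: list[GenomicInterval], model: GeneModel) -> int:
    merged = _merged_intervals(model.exons)
    total = 0
    for iv in tag_ivs:
        for s, e in merged:
            total += max(0, min(iv.end, e) - max(iv.start, s))
    return total


def classify(
    me: Microexon,
    models: list[GeneModel],
    tag_intervals: list[GenomicInterval] | None = None,
    window: int = DEFAULT_ORPHAN_WINDOW,
) -> MicroexonStatus:
    """Classify a microexon against the closest annotated transcript.

    The closest transcript maximizes exonic-base overlap with the tag
    (``tag_intervals``; the bare microexon if no tag is given), ties broken
    by lexicographically smallest transcript id, falling back to the nearest
    transcript within ``window`` nt when nothing overlaps.
    """
    iv = me.interval
    tag_ivs = tag_intervals or [iv]
    same_strand = [
        m for m in models if m.chrom == iv.chrom and m.strand == iv.strand
    ]
    best = None
    best_key = None
    for m in same_strand:
        ov = _tag_overlap_bases(tag_ivs, m)
        if ov > 0:
            key = (-ov, m.transcript_id)
            if best_key is None or key < best_key:
                best, best_key = m, key
    if best is None:
        # nearest transcript span within the window
        near = []
        for m in same_strand:
            span = m.span
            dist = max(span.start - iv.end, iv.start - span.end, 0)
            if dist <= window:
                near.append((dist, m.transcript_id, m))
        if near:
            near.sort(key=lambda t: (t[0], t[1]))
            best = near[0][2]
    if best is None:
        return MicroexonStatus(
            microexon=me,
            closest_transcript=None,
            category=CATEGORY_ORPHAN,
            pct_overlap=0.0,
        )

    po = pct_overlap(_tag_shim(tag_ivs, iv), best)
    category = _categorize(iv, best)
    return MicroexonStatus(
        microexon=me,
        closest_transcript=best.transcript_id,
        category=category,
        pct_overlap=po,
    )


def _tag_shim(tag_ivs: list[GenomicInterval], iv: GenomicInterval) -> GeneModel:
    return GeneModel(
        gene_id=".",
        transcript_id=".",
        chrom=iv.chrom,
        strand=iv.strand,
        exons=list(tag_ivs),
        cds=[],
    )


def _categorize(iv: GenomicInterval, model: GeneModel) -> str:
    cds_merged = _merged_intervals(model.cds) if model.cds else []
    for exon in model.exons:
        if exon.start == iv.start and exon.end == iv.end:
            # exact exon match; "annotated" when it carries coding sequence
            if not cds_merged or any(
                min(iv.end, e) > max(iv.start, s) for s, e in cds_merged
            ):
                return CATEGORY_ANNOTATED
    for exon in model.exons:
        if exon.overlaps(iv):
            return CATEGORY_EXONIC
    for intron in model.introns():
        if intron.start <= iv.start and iv.end <= intron.end:
            return CATEGORY_INTRONIC
    return CATEGORY_ORPHAN


# ---------------------------------------------------------------------------
# transcript surgery

def insert_microexon(
    model: GeneModel,
    me: Microexon,
    genome: dict[str, str],
    existing_ids: set[str] | None = None,
) -> GeneModel:
    """Splice an intron-located microexon into a transcript and recompute CDS.

    The repaired transcript keeps the original exon flanks, gains the
    microexon as a new internal exon, and is renamed ``<old id>x`` (the
    suffix is extended past any id collision). The CDS is re-derived by
    translating from the original start codon through the corrected exon
    chain to the first in-frame stop; if the stop lands earlier than the old
    CDS end plus the insertion, the model is flagged
    ``nonsense_after_insertion`` but still returned.
    """
    iv = me.interval
    for intron in model.introns():
        if intron.start <= iv.start and iv.end <= intron.end:
            break
    else:
        raise CoordinateError(
            f"microexon {iv.chrom}:{iv.start}-{iv.end} is not inside an intron "
            f"of {model.transcript_id}"
        )
    for exon in model.exons:
        if exon.overlaps(iv):
            raise CoordinateError("insertion would create overlapping exons")

    new_exon = GenomicInterval(iv.chrom, iv.start, iv.end, model.strand)
    genomic = sorted(model.exons + [new_exon], key=lambda e: e.start)
    exons = genomic[::-1] if model.strand == "-" else genomic

    new_id = model.transcript_id + "x"
    while existing_ids and new_id in existing_ids:
        new_id += "x"

    repaired = GeneModel(
        gene_id=model.gene_id,
        transcript_id=new_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=exons,
        cds=[],
        flags=[],
    )

    # recompute CDS from the original start codon through the new chain
    first = model.cds[0]
    start_base = first.start if model.strand == "+" else first.end - 1
    start_off = genomic_to_transcript(exons, model.strand, start_base)
    tx = spliced_sequence(repaired, genome, "exon")
    coding_region = tx[start_off:]
    usable = len(coding_region) - len(coding_region) % 3
    result = translate_full(coding_region[:usable]) if usable >= 3 else None
    if result is None:
        raise CoordinateError(f"{new_id}: no coding sequence after insertion")
    cds_len = 3 * len(result.aa) + (3 if result.stopped else 0)
    partial = not result.stopped
    repaired.cds = transcript_to_genomic(exons, model.strand, start_off, cds_len)
    repaired.partial = partial

    old_cds_len = model.cds_length
    if result.stopped and cds_len < old_cds_len + me.size:
        repaired.flags.append("nonsense_after_insertion")
    return repaired


def update_annotation(
    microexons: list[tuple[Microexon, list[GenomicInterval] | None]],
    models: list[GeneModel],
    genome: dict[str, str],
    window: int = DEFAULT_ORPHAN_WINDOW,
) -> tuple[list[GeneModel], list[MicroexonStatus]]:
    """Classify each (microexon, optional tag intervals) pair and repair the
    intron-located novel ones. Returns (new transcripts, statuses)."""
    by_id = {m.transcript_id: m for m in models}
    existing = set(by_id)
    new_models: list[GeneModel] = []
    statuses: list[MicroexonStatus] = []
    for me, tag_ivs in microexons:
        status = classify(me, models, tag_intervals=tag_ivs, window=window)
        if status.category == CATEGORY_INTRONIC and status.closest_transcript:
            host = by_id[status.closest_transcript]
            repaired = insert_microexon(host, me, genome, existing_ids=existing)
            existing.add(repaired.transcript_id)
            new_models.append(repaired)
            status.new_transcript_id = repaired.transcript_id
            status.flags = list(repaired.flags)
        statuses.append(status)
    return new_models, statuses


def statuses_to_table(statuses: list[MicroexonStatus]):
    import pandas as pd

    rows = [
        {
            "chrom": s.microexon.interval.chrom,
            "start": s.microexon.interval.start + 1,
            "end": s.microexon.interval.end,
            "strand": s.microexon.interval.strand,
            "size": s.microexon.size,
            "phase": s.microexon.phase,
            "category": s.category,
            "closest_transcript": s.closest_transcript or ".",
            "pct_overlap": round(s.pct_overlap, 2),
            "new_transcript_id": s.new_transcript_id or ".",
            "flags": ",".join(s.flags) if s.flags else ".",
        }
        for s in statuses
    ]
    return pd.DataFrame(rows)


__all__ = [
    "CATEGORY_ANNOTATED",
    "CATEGORY_INTRONIC",
    "CATEGORY_EXONIC",
    "CATEGORY_ORPHAN",
    "MicroexonStatus",
    "classify",
    "insert_microexon",
    "pct_overlap",
    "update_annotation",
    "statuses_to_table",
]
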