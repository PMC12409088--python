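"""PWM scanning of genomic DNA for microexon-tags.

A cluster model's tag columns are partitioned into blocks (exonic segments).
Scanning places each block on the target sequence and chains the placements
across candidate introns: between consecutive blocks the genomic gap is
either 0 (no intron) or an intron of plausible length beginning with a donor
GT and ending with an acceptor AG on the prediction strand. The microexon's
location is read off its block in the winning chain.

Score model: each block placement is scored by summing the model's log2-odds
over its columns; N bases contribute 0 (background). A per-block threshold
(fraction of the block's maximum score) applies to blocks of at least
``min_scored_block`` nt — shorter blocks, in particular 1-9 nt microexons,
carry too little information to be score-filtered and are located purely by
the splice-site chaining geometry. The chain's raw score is the sum of its
block scores, reported alongside a min-max normalized score in [0, 1].

Both strands are scanned by running the forward algorithm on the reverse
complement and mapping coordinates back; results are always reported on the
forward strand of the input.

``brute_force_scan`` re-derives predictions by exhaustive enumeration of all
block placements and gap combinations (no anchoring, no early pruning) and
serves as the scanner's independent test oracle on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cluster_model import ClusterModel
from .genomic_model import GenomicInterval, MicrotagError, reverse_complement

ORACLE_MAX_LEN = 5000


class InputLengthError(MicrotagError):
    pass


class OracleSizeError(MicrotagError):
    pass


@dataclass(frozen=True)
class ScanOptions:
    """Scanner knobs. Defaults follow typical plant intron statistics and the
    prediction service's input-length bounds; library callers may override
    any of them (set min_len=0 / max_len=None to lift the bounds)."""

    per_block_threshold: float = 0.7
    global_threshold: float = 0.8
    intron_min: int = 35
    intron_max: int = 10_000
    allow_intronless: bool = False
    min_scored_block: int = 10
    allow_gc_donor: bool = False
    min_len: int = 200
    max_len: int | None = 1_000_000

    @property
    def donors(self) -> tuple[str, ...]:
        return ("GT", "GC") if self.allow_gc_donor else ("GT",)


@dataclass(frozen=True)
class BlockHit:
    model: str
    block_index: int
    interval: GenomicInterval
    strand: str
    score: float


@dataclass
class Prediction:
    """A chained placement of a cluster model on a target sequence.

    Coordinates are 0-based half-open on the forward strand of the scanned
    sequence; ``block_intervals`` ascend genomically and ``splice_flags``
    holds one of {"canonical", "absent"} per junction in that same order.
    """

    cluster_id: str
    seqid: str
    strand: str
    block_intervals: list[GenomicInterval]
    intron_intervals: list[GenomicInterval]
    microexon: GenomicInterval
    raw_score: float
    normalized_score: float
    splice_flags: list[str]

    @property
    def span(self) -> tuple[int, int]:
        return self.block_intervals[0].start, self.block_intervals[-1].end

    @property
    def n_absent(self) -> int:
        return sum(1 for f in self.splice_flags if f == "absent")


# ---------------------------------------------------------------------------
# block scoring

_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _pwm5(model: ClusterModel) -> np.ndarray:
    """PWM extended with an all-zero row for N (scores as background)."""
    return np.vstack([model.pwm, np.zeros(model.width)])


def block_max_score(model: ClusterModel, block_index: int) -> float:
    lo, hi = model.block_columns(block_index)
    return float(model.pwm[:, lo:hi].max(axis=0).sum())


def score_block(model: ClusterModel, block_index: int, window: str) -> float:
    """Log2-odds score of one block over a window of its exact length."""
    w = model.block_sizes[block_index]
    if len(window) != w:
        raise MicrotagError(
            f"window length {len(window)} != block length {w} "
            f"(block {block_index} of {model.cluster_id})"
        )
    lo, _ = model.block_columns(block_index)
    pwm5 = _pwm5(model)
    enc = encode(window.upper())
    return float(pwm5[enc, np.arange(lo, lo + w)].sum())


def block_score_array(model: ClusterModel, enc: np.ndarray, block_index: int) -> np.ndarray:
    """Score of the block at every start position of the encoded sequence."""
    lo, hi = model.block_columns(block_index)
    w = hi - lo
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0)
    pwm5 = _pwm5(model)
    out = np.zeros(n)
    for k in range(w):
        out += pwm5[:, lo + k][enc[k : k + n]]
    return out


def _is_scored(model: ClusterModel, block_index: int, options: ScanOptions) -> bool:
    return model.block_sizes[block_index] >= options.min_scored_block


def _block_threshold(model: ClusterModel, block_index: int, options: ScanOptions) -> float:
    return options.per_block_threshold * block_max_score(model, block_index)


def find_block_hits(
    model: ClusterModel,
    sequence: str,
    strand: str = "+",
    per_block_threshold: float = 0.7,
    block_indices: list[int] | None = None,
    seqid: str = ".",
) -> dict[int, list[BlockHit]]:
    """All positions where a block scores >= threshold x its max score."""
    enc = encode(sequence.upper())
    hits: dict[int, list[BlockHit]] = {}
    indices = (
        block_indices if block_indices is not None else range(len(model.block_sizes))
    )
    for b in indices:
        scores = block_score_array(model, enc, b)
        thr = per_block_threshold * block_max_score(model, b)
        w = model.block_sizes[b]
        hits[b] = [
            BlockHit(
                model=model.cluster_id,
                block_index=b,
                interval=GenomicInterval(seqid, int(p), int(p) + w, strand),
                strand=strand,
                score=float(scores[p]),
            )
            for p in np.nonzero(scores >= thr)[0]
        ]
    return hits


# ---------------------------------------------------------------------------
# chaining

def _junction_candidates_right(
    sequence: str,
    e: int,
    w_next: int,
    options: ScanOptions,
    allowed_positions: np.ndarray | None,
) -> list[tuple[int, str]]:
    """Candidate starts for the next block after a block ending at ``e``.

    ``allowed_positions`` restricts intronic candidates to a sorted position
    array (a scored block's hit positions); None means any AG-preceded
    position in the gap window.
    """
    n = len(sequence)
    out: list[tuple[int, str]] = []
    if options.allow_intronless and e + w_next <= n:
        out.append((e, "absent"))
    if e + 2 <= n and sequence[e : e + 2] in options.donors:
        g_hi = min(options.intron_max, n - e - w_next)
        if g_hi >= options.intron_min:
            lo_start = e + options.intron_min  # earliest next-block start
            hi_start = e + g_hi
            if allowed_positions is not None:
                i0 = np.searchsorted(allowed_positions, lo_start)
                i1 = np.searchsorted(allowed_positions, hi_start, side="right")
                for p in allowed_positions[i0:i1]:
                    p = int(p)
                    if sequence[p - 2 : p] == "AG":
                        out.append((p, "canonical"))
            else:
                idx = sequence.find("AG", max(lo_start - 2, 0))
                while 0 <= idx <= hi_start - 2:
                    out.append((idx + 2, "canonical"))
                    idx = sequence.find("AG", idx + 1)
    return out


def _junction_candidates_left(
    sequence: str,
    s: int,
    w_prev: int,
    options: ScanOptions,
    allowed_positions: np.ndarray | None,
) -> list[tuple[int, str]]:
    """Candidate starts for the previous block before a block starting at ``s``."""
    out: list[tuple[int, str]] = []
    if options.allow_intronless and s - w_prev >= 0:
        out.append((s - w_prev, "absent"))
    if s >= 2 and sequence[s - 2 : s] == "AG":
        g_hi = min(options.intron_max, s - w_prev)
        if g_hi >= options.intron_min:
            lo_end = s - g_hi  # earliest previous-block end (donor start)
            hi_end = s - options.intron_min
            if allowed_positions is not None:
                i0 = np.searchsorted(allowed_positions, lo_end - w_prev)
                i1 = np.searchsorted(allowed_positions, hi_end - w_prev, side="right")
                for p in allowed_positions[i0:i1]:
                    p = int(p)
                    if sequence[p + w_prev : p + w_prev + 2] in options.donors:
                        out.append((p, "canonical"))
            else:
                for d in options.donors:
                    idx = sequence.find(d, max(lo_end, 0))
                    while 0 <= idx <= hi_end:
                        if idx - w_prev >= 0:
                            out.append((idx - w_prev, "canonical"))
                        idx = sequence.find(d, idx + 1)
    return out


def chain_hits(
    model: ClusterModel,
    hits: dict[int, list[BlockHit]],
    sequence: str,
    options: ScanOptions = ScanOptions(),
    strand: str = "+",
    seqid: str = ".",
) -> list[Prediction]:
    """Chain block placements into complete tag predictions.

    ``hits`` carries pre-computed hits for the scored blocks (length >=
    ``min_scored_block``); the longest scored block anchors the chain and the
    remaining blocks are placed junction by junction, scored blocks through
    their hit lists, short blocks by splice-site geometry alone.
    """
    sequence = sequence.upper()
    nb = len(model.block_sizes)
    sizes = model.block_sizes
    enc = encode(sequence)
    arrays: dict[int, np.ndarray] = {}

    def scores_of(b: int) -> np.ndarray:
        if b not in arrays:
            arrays[b] = block_score_array(model, enc, b)
        return arrays[b]

    scored = [_is_scored(model, b, options) for b in range(nb)]
    anchor_choices = [b for b in hits if scored[b]] or list(hits)
    if not anchor_choices:
        raise MicrotagError("chain_hits needs hits for at least one block")
    anchor = max(anchor_choices, key=lambda b: (sizes[b], -b))
    hit_positions = {
        b: np.array(sorted(h.interval.start for h in hs), dtype=np.int64)
        for b, hs in hits.items()
    }

    def allowed(b: int) -> np.ndarray | None:
        return hit_positions.get(b) if scored[b] else None

    def passes(b: int, pos: int) -> bool:
        arr = scores_of(b)
        if pos >= arr.size:
            return False
        if scored[b] and arr[pos] < _block_threshold(model, b, options):
            return False
        return True

    chains: list[tuple[list[int], list[str]]] = []

    def run(p0: int) -> None:
        # rightward positions relative to anchor
        def right(pos_list: list[int], flag_list: list[str], b: int) -> None:
            if b == nb - 1:
                left(pos_list, flag_list, anchor)
                return
            e = pos_list[b - anchor] + sizes[b]
            for start_next, flag in _junction_candidates_right(
                sequence, e, sizes[b + 1], options, allowed(b + 1)
            ):
                if passes(b + 1, start_next):
                    right(pos_list + [start_next], flag_list + [flag], b + 1)

        def left(pos_list: list[int], flag_list: list[str], b: int) -> None:
            if b == 0:
                chains.append((pos_list, flag_list))
                return
            s = pos_list[0]
            for start_prev, flag in _junction_candidates_left(
                sequence, s, sizes[b - 1], options, allowed(b - 1)
            ):
                if passes(b - 1, start_prev):
                    left([start_prev] + pos_list, [flag] + flag_list, b - 1)

        right([p0], [], anchor)

    for p0 in sorted(set(int(p) for p in hit_positions.get(anchor, []))):
        if passes(anchor, p0):
            run(p0)

    return [
        _chain_to_prediction(model, positions, flags, scores_of, strand, seqid)
        for positions, flags in chains
    ]


def _chain_to_prediction(
    model: ClusterModel,
    positions: list[int],
    flags: list[str],
    scores_of,
    strand: str,
    seqid: str,
) -> Prediction:
    sizes = model.block_sizes
    raw = float(sum(scores_of(b)[p] for b, p in enumerate(positions)))
    span = model.max_score - model.min_score
    norm = (raw - model.min_score) / span if span > 0 else 0.0
    norm = min(max(norm, 0.0), 1.0)  # guard float epsilon at the extremes
    block_ivs = [
        GenomicInterval(seqid, p, p + sizes[b], strand)
        for b, p in enumerate(positions)
    ]
    introns = []
    for j, flag in enumerate(flags):
        if flag == "canonical":
            introns.append(
                GenomicInterval(
                    seqid, block_ivs[j].end, block_ivs[j + 1].start, strand
                )
            )
    me_iv = block_ivs[model.microexon_block_index]
    return Prediction(
        cluster_id=model.cluster_id,
        seqid=seqid,
        strand=strand,
        block_intervals=block_ivs,
        intron_intervals=introns,
        microexon=me_iv,
        raw_score=raw,
        normalized_score=float(norm),
        splice_flags=list(flags),
    )


# ---------------------------------------------------------------------------
# strand mapping, overlap resolution, top-level scan

def _map_to_forward(pred: Prediction, n: int) -> Prediction:
    """Map a prediction made on the reverse complement back to forward coords."""

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, n - iv.end, n - iv.start, "-")

    return Prediction(
        cluster_id=pred.cluster_id,
        seqid=pred.seqid,
        strand="-",
        block_intervals=[flip(iv) for iv in reversed(pred.block_intervals)],
        intron_intervals=[flip(iv) for iv in reversed(pred.intron_intervals)],
        microexon=flip(pred.microexon),
        raw_score=pred.raw_score,
        normalized_score=pred.normalized_score,
        splice_flags=list(reversed(pred.splice_flags)),
    )


def _resolve_overlaps(preds: list[Prediction]) -> list[Prediction]:
    """Greedy per-(model, strand) resolution of overlapping predictions:
    highest raw score wins, then leftmost, then fewest absent introns."""
    out: list[Prediction] = []
    groups: dict[tuple[str, str], list[Prediction]] = {}
    for p in preds:
        groups.setdefault((p.cluster_id, p.strand), []).append(p)
    for group in groups.values():
        group.sort(key=lambda p: (-p.raw_score, p.span[0], p.n_absent, p.microexon.start))
        kept: list[Prediction] = []
        for p in group:
            s, e = p.span
            if all(e <= k.span[0] or k.span[1] <= s for k in kept):
                kept.append(p)
        out.extend(kept)
    return out


def _scan_one_strand(
    model: ClusterModel,
    sequence: str,
    strand: str,
    seqid: str,
    options: ScanOptions,
) -> list[Prediction]:
    if len(sequence) < model.width:
        return []
    scored_blocks = [
        b
        for b in range(len(model.block_sizes))
        if _is_scored(model, b, options)
    ] or list(range(len(model.block_sizes)))
    hits = find_block_hits(
        model,
        sequence,
        strand=strand,
        per_block_threshold=options.per_block_threshold,
        block_indices=scored_blocks,
        seqid=seqid,
    )
    return chain_hits(model, hits, sequence, options, strand=strand, seqid=seqid)


def scan(
    models: list[ClusterModel],
    sequences: dict[str, str] | str,
    options: ScanOptions = ScanOptions(),
) -> list[Prediction]:
    """Scan sequence(s) with cluster models on both strands.

    Returns predictions with normalized score >= ``options.global_threshold``
    in deterministic order (sequence, microexon position, score descending,
    cluster id). Input length bounds are enforced when configured (defaults
    mirror the prediction service: 200 nt to 1 Mnt).
    """
    if isinstance(sequences, str):
        sequences = {"query": sequences}
    results: list[Prediction] = []
    for seqid, seq in sequences.items():
        n = len(seq)
        if options.min_len and n < options.min_len:
            raise InputLengthError(
                f"sequence {seqid!r} is {n} nt; accepted length is between "
                f"{options.min_len} nt and {options.max_len or 'unbounded'} nt"
            )
        if options.max_len is not None and n > options.max_len:
            raise InputLengthError(
                f"sequence {seqid!r} is {n} nt; accepted length is between "
                f"{options.min_len} nt and {options.max_len} nt"
            )
        seq = seq.upper()
        rc = reverse_complement(seq)
        per_seq: list[Prediction] = []
        for model in models:
            cands = _scan_one_strand(model, seq, "+", seqid, options)
            cands += [
                _map_to_forward(p, n)
                for p in _scan_one_strand(model, rc, "+", seqid, options)
            ]
            cands = [
                p for p in cands if p.normalized_score >= options.global_threshold
            ]
            per_seq.extend(_resolve_overlaps(cands))
        per_seq.sort(
            key=lambda p: (
                p.microexon.start,
                -p.normalized_score,
                p.cluster_id,
                p.strand,
            )
        )
        results.extend(per_seq)
    return results


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_scan(
    model: ClusterModel,
    sequence: str,
    options: ScanOptions = ScanOptions(),
    seqid: str = ".",
) -> list[Prediction]:
    """Exhaustive enumeration of all block placements and gap combinations.

    Independent oracle for ``scan``: no anchoring and no hit lists — every
    start position of block 0 and every admissible gap assignment is tried,
    then the same prediction-semantics filters (per-block threshold on scored
    blocks, global normalized threshold, overlap resolution) are applied.
    Refuses sequences longer than ORACLE_MAX_LEN.
    """
    n = len(sequence)
    if n > ORACLE_MAX_LEN:
        raise OracleSizeError(
            f"oracle is limited to {ORACLE_MAX_LEN} nt (got {n})"
        )
    results: list[Prediction] = []
    for strand, seq in (("+", sequence.upper()), ("-", reverse_complement(sequence.upper()))):
        cands = _enumerate_chains(model, seq, options, seqid)
        if strand == "-":
            cands = [_map_to_forward(p, n) for p in cands]
        cands = [p for p in cands if p.normalized_score >= options.global_threshold]
        results.extend(_resolve_overlaps(cands))
    results.sort(
        key=lambda p: (p.microexon.start, -p.normalized_score, p.cluster_id, p.strand)
    )
    return results


def _enumerate_chains(
    model: ClusterModel, seq: str, options: ScanOptions, seqid: str
) -> list[Prediction]:
    nb = len(model.block_sizes)
    sizes = model.block_sizes
    enc = encode(seq)
    arrays = [block_score_array(model, enc, b) for b in range(nb)]

    def scores_of(b: int) -> np.ndarray:
        return arrays[b]

    out: list[Prediction] = []
    min_span = sum(sizes)

    def complete(positions: list[int], flags: list[str]) -> None:
        for b, p in enumerate(positions):
            if p >= arrays[b].size:
                return
            if _is_scored(model, b, options) and arrays[b][p] < _block_threshold(
                model, b, options
            ):
                return
        out.append(
            _chain_to_prediction(model, positions, flags, scores_of, "+", seqid)
        )

    def walk(positions: list[int], flags: list[str], b: int) -> None:
        if b == nb - 1:
            complete(positions, flags)
            return
        e = positions[-1] + sizes[b]
        w_next = sizes[b + 1]
        # gap 0
        if options.allow_intronless and e + w_next <= len(seq):
            walk(positions + [e], flags + ["absent"], b + 1)
        # intronic gaps
        if e + 2 <= len(seq) and seq[e : e + 2] in options.donors:
            g_hi = min(options.intron_max, len(seq) - e - w_next)
            for g in range(options.intron_min, g_hi + 1):
                if seq[e + g - 2 : e + g] == "AG":
                    walk(positions + [e + g], flags + ["canonical"], b + 1)

    for p0 in range(0, len(seq) - min_span + 1):
        walk([p0], [], 0)
    return out


# ---------------------------------------------------------------------------
# prediction output

def predictions_to_table(preds: list[Prediction]):
    import pandas as pd

    rows = [
        {
            "seqid": p.seqid,
            "cluster_id": p.cluster_id,
            "strand": p.strand,
            "microexon_start": p.microexon.start + 1,
            "microexon_end": p.microexon.end,
            "block_starts": ",".join(str(iv.start + 1) for iv in p.block_intervals),
            "block_ends": ",".join(str(iv.end) for iv in p.block_intervals),
            "intron_starts": ",".join(str(iv.start + 1) for iv in p.intron_intervals)
            or ".",
            "intron_ends": ",".join(str(iv.end) for iv in p.intron_intervals) or ".",
            "raw_score": round(p.raw_score, 4),
            "normalized_score": round(p.normalized_score, 4),
            "splice_flags": ",".join(p.splice_flags),
        }
        for p in preds
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seqid",
            "cluster_id",
            "strand",
            "microexon_start",
            "microexon_end",
            "block_starts",
            "block_ends",
            "intron_starts",
            "intron_ends",
            "raw_score",
            "normalized_score",
            "splice_flags",
        ],
    )


def predictions_to_bed(preds: list[Prediction], path) -> None:
    """BED6 of microexon intervals (score column = normalized score x 1000)."""
    with open(path, "w") as fh:
        for p in preds:
            fh.write(
                f"{p.seqid}\t{p.microexon.start}\t{p.microexon.end}\t"
                f"{p.cluster_id}\t{int(round(p.normalized_score * 1000))}\t{p.strand}\n"
            )


def predictions_to_gff3(preds: list[Prediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(preds, start=1):
            pid = f"prediction{i:05d}"
            s, e = p.span
            fh.write(
                f"{p.seqid}\tmicrotag\tmatch\t{s + 1}\t{e}\t"
                f"{p.normalized_score:.4f}\t{p.strand}\t.\t"
                f"ID={pid};cluster={p.cluster_id}\n"
            )
            for iv in p.block_intervals:
                kind = "microexon" if iv == p.microexon else "match_part"
                fh.write(
                    f"{p.seqid}\tmicrotag\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{p.strand}\t.\tParent={pid}\n"
                )


__all__ = [
    "ScanOptions",
    "BlockHit",
    "Prediction",
    "InputLengthError",
    "OracleSizeError",
    "encode",
    "score_block",
    "block_max_score",
    "block_score_array",
    "find_block_hits",
    "chain_hits",
    "scan",
    "brute_force_scan",
    "predictions_to_table",
    "predictions_to_bed",
    "predictions_to_gff3",
]
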