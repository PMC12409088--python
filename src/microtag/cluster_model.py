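"""Compile microexon-tags into PWM cluster models.

Tags are first partitioned by (microexon size, phase) — members of a cluster
must code for the same insertion at the same codon position — then clustered
within each group by single-linkage over pairwise global alignment of their
36-aa translations, and finally compiled into a position frequency/weight
matrix over the tag's nucleotide columns.

Column frame: all tags of a (size, phase) group share the canonical left
flank length L = canonical_left_flank(size, phase), so column j of the model
is CDS offset j of an untruncated tag. Truncated tags are right/left aligned
into that frame via the microexon anchor and contribute counts only to the
columns they cover.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genomic_model import MicrotagError
from .tag_extraction import DEFAULT_TAG_LEN, MicroexonTag, canonical_left_flank

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MODEL_FORMAT_VERSION = 1
DEFAULT_CLUSTER_PREFIX = "MEC"


class ModelBuildError(MicrotagError):
    pass


class SchemaError(MicrotagError):
    pass


@dataclass
class ClusterModel:
    """A PWM model of one conserved microexon-tag cluster.

    ``pfm`` holds raw base counts (4 x W), ``coverage`` the number of member
    tags covering each column (truncated members cover a suffix/prefix only),
    and ``pwm`` the log2-odds scores
    pwm[b][j] = log2(((pfm[b][j] + a*bg[b]) / (coverage[j] + a)) / bg[b])
    with pseudocount weight ``pseudocount`` distributed by the background.
    """

    cluster_id: str
    microexon_size: int
    phase: int
    block_sizes: list[int]
    microexon_block_index: int
    pfm: np.ndarray  # (4, W) counts
    coverage: np.ndarray  # (W,) per-column member coverage
    pwm: np.ndarray  # (4, W) log2-odds, bits
    background: np.ndarray  # (4,) base probabilities
    consensus_nt: str
    member_count: int
    pseudocount: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.shape != (4, self.width) or self.pwm.shape != (4, self.width):
            raise SchemaError(
                f"{self.cluster_id}: matrix shape does not match block sizes"
            )

    @property
    def width(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def max_score(self) -> float:
        """Score of the per-column best base (the consensus), in bits."""
        return float(self.pwm.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.pwm.min(axis=0).sum())

    @property
    def left_flank_len(self) -> int:
        return int(sum(self.block_sizes[: self.microexon_block_index]))

    def block_columns(self, block_index: int) -> tuple[int, int]:
        """Column range [lo, hi) of one block within the tag."""
        lo = int(sum(self.block_sizes[:block_index]))
        return lo, lo + self.block_sizes[block_index]

    def anti_consensus_nt(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmin(axis=0))


# ---------------------------------------------------------------------------
# grouping and clustering

def group_tags(
    tags: list[MicroexonTag],
) -> dict[tuple[int, int], list[MicroexonTag]]:
    """Partition tags by (microexon size, phase)."""
    groups: dict[tuple[int, int], list[MicroexonTag]] = {}
    for t in tags:
        groups.setdefault((t.microexon.size, t.phase), []).append(t)
    return groups


def _aligner(score_matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(score_matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def cluster_group(
    tags: list[MicroexonTag],
    score_matrix: str = "BLOSUM62",
    threshold: float = 0.6,
) -> list[list[MicroexonTag]]:
    """Single-linkage clusters of tags at normalized aa similarity >= threshold.

    Normalized similarity of a pair is its global alignment score divided by
    the self-alignment score of the shorter translation, so identical
    sequences score 1. Tags with an empty translation are excluded with a
    warning. Single linkage over a pairwise graph is independent of input
    order; clusters are returned largest first.
    """
    keys = {(t.microexon.size, t.phase) for t in tags}
    if len(keys) > 1:
        raise ModelBuildError(f"tags span multiple (size, phase) groups: {keys}")
    usable = []
    for t in tags:
        if not t.aa_sequence:
            warnings.warn(
                f"tag {t.tag_id or t.transcript_id} has empty translation; excluded",
                stacklevel=2,
            )
        else:
            usable.append(t)
    if not usable:
        return []
    aligner = _aligner(score_matrix)
    self_scores = [aligner.score(t.aa_sequence, t.aa_sequence) for t in usable]

    parent = list(range(len(usable)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            shorter = i if len(usable[i].aa_sequence) <= len(usable[j].aa_sequence) else j
            denom = self_scores[shorter]
            if denom <= 0:
                continue
            sim = aligner.score(usable[i].aa_sequence, usable[j].aa_sequence) / denom
            if sim >= threshold:
                parent[find(i)] = find(j)

    comps: dict[int, list[MicroexonTag]] = {}
    for i, t in enumerate(usable):
        comps.setdefault(find(i), []).append(t)
    clusters = list(comps.values())
    # deterministic: largest first, ties by first member's identity
    clusters.sort(key=lambda c: (-len(c), c[0].transcript_id, c[0].tag_id))
    return clusters


# ---------------------------------------------------------------------------
# model compilation

def _majority_block_structure(
    members: list[MicroexonTag],
) -> tuple[tuple[int, ...], int]:
    """Majority (block_sizes, microexon_block_index) among untruncated members."""
    untrunc = [m for m in members if m.untruncated]
    if not untrunc:
        raise ModelBuildError(
            "cluster has no untruncated member to define the column frame: "
            + ", ".join(m.tag_id or m.transcript_id for m in members)
        )
    counts = Counter((m.block_sizes, m.microexon_block_index) for m in untrunc)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        raise ModelBuildError(
            "no majority block structure among members: "
            + "; ".join(
                f"{list(k[0])}(x{v})" for k, v in ranked
            )
            + " members: "
            + ", ".join(m.tag_id or m.transcript_id for m in untrunc)
        )
    (block_sizes, me_idx), _ = ranked[0]
    return block_sizes, me_idx


def build_model(
    cluster: list[MicroexonTag],
    background: np.ndarray | list[float] | None = None,
    pseudocount: float = 1.0,
    cluster_id: str = "MEC01",
    tag_len: int = DEFAULT_TAG_LEN,
    extra_sequences: list[str] | None = None,
    provenance: str = "",
) -> ClusterModel:
    """Compile one tag cluster into a ClusterModel.

    ``extra_sequences`` are additional full-width nucleotide sequences (e.g.
    expressed-sequence evidence) counted into the PFM alongside the members.
    """
    if not cluster:
        raise ModelBuildError("empty cluster")
    sizes = {t.microexon.size for t in cluster}
    phases = {t.phase for t in cluster}
    if len(sizes) > 1 or len(phases) > 1:
        raise ModelBuildError(
            f"cluster members disagree on size/phase: sizes={sizes} phases={phases}"
        )
    size, phase = sizes.pop(), phases.pop()
    block_sizes, me_idx = _majority_block_structure(cluster)
    width = tag_len
    if sum(block_sizes) != width:
        raise ModelBuildError(
            f"majority block structure sums to {sum(block_sizes)}, expected {width}"
        )
    canon_left = canonical_left_flank(size, phase, tag_len)

    pfm = np.zeros((4, width))
    coverage = np.zeros(width)
    n_members = 0
    for t in cluster:
        start_col = canon_left - t.left_flank_len
        if start_col < 0 or start_col + len(t.nt_sequence) > width:
            raise ModelBuildError(
                f"tag {t.tag_id or t.transcript_id} does not fit the canonical "
                f"column frame (left flank {t.left_flank_len} vs {canon_left})"
            )
        _count_sequence(pfm, coverage, t.nt_sequence, start_col)
        n_members += 1
    for seq in extra_sequences or []:
        if len(seq) != width:
            raise ModelBuildError(
                f"extra sequence of length {len(seq)} != model width {width}"
            )
        _count_sequence(pfm, coverage, seq.upper(), 0)

    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
        raise ModelBuildError("background must be a 4-vector summing to 1")

    a = float(pseudocount)
    with np.errstate(divide="ignore"):
        probs = (pfm + a * background[:, None]) / (coverage[None, :] + a)
        pwm = np.log2(probs / background[:, None])
    consensus = "".join(BASES[i] for i in pfm.argmax(axis=0))

    return ClusterModel(
        cluster_id=cluster_id,
        microexon_size=size,
        phase=phase,
        block_sizes=list(block_sizes),
        microexon_block_index=me_idx,
        pfm=pfm,
        coverage=coverage,
        pwm=pwm,
        background=background,
        consensus_nt=consensus,
        member_count=n_members,
        pseudocount=a,
        provenance=provenance,
    )


def _count_sequence(pfm: np.ndarray, coverage: np.ndarray, seq: str, start_col: int) -> None:
    for k, base in enumerate(seq):
        idx = BASE_INDEX.get(base)
        if idx is None:  # N: covered but uninformative -> skip count entirely
            continue
        pfm[idx, start_col + k] += 1
        coverage[start_col + k] += 1


def build_models(
    tags: list[MicroexonTag],
    score_matrix: str = "BLOSUM62",
    threshold: float = 0.6,
    background=None,
    pseudocount: float = 1.0,
    prefix: str = DEFAULT_CLUSTER_PREFIX,
    min_members: int = 1,
    tag_len: int = DEFAULT_TAG_LEN,
    provenance: str = "",
) -> list[ClusterModel]:
    """Full pipeline: group by (size, phase), cluster, compile, assign ids.

    Cluster ids are ``<prefix><index>`` with a zero-padded index, ordered by
    member count descending then (size, phase).
    """
    all_clusters: list[tuple[tuple[int, int], list[MicroexonTag]]] = []
    for key in sorted(group_tags(tags)):
        for cl in cluster_group(group_tags(tags)[key], score_matrix, threshold):
            if len(cl) >= min_members:
                all_clusters.append((key, cl))
    all_clusters.sort(key=lambda kc: (-len(kc[1]), kc[0]))
    pad = max(2, len(str(len(all_clusters))))
    models = []
    for i, (_key, cl) in enumerate(all_clusters, start=1):
        models.append(
            build_model(
                cl,
                background=background,
                pseudocount=pseudocount,
                cluster_id=f"{prefix}{i:0{pad}d}",
                tag_len=tag_len,
                provenance=provenance,
            )
        )
    return models


# ---------------------------------------------------------------------------
# model serialization (versioned JSON)

_REQUIRED_KEYS = {
    "cluster_id",
    "microexon_size",
    "phase",
    "block_sizes",
    "microexon_block_index",
    "pfm",
    "coverage",
    "pwm",
    "background",
    "consensus_nt",
    "member_count",
    "pseudocount",
}


def write_models(models: list[ClusterModel], path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "models": [
            {
                "cluster_id": m.cluster_id,
                "microexon_size": m.microexon_size,
                "phase": m.phase,
                "block_sizes": list(m.block_sizes),
                "microexon_block_index": m.microexon_block_index,
                "pfm": m.pfm.tolist(),
                "coverage": m.coverage.tolist(),
                "pwm": m.pwm.tolist(),
                "background": m.background.tolist(),
                "consensus_nt": m.consensus_nt,
                "member_count": m.member_count,
                "pseudocount": m.pseudocount,
                "provenance": m.provenance,
            }
            for m in models
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_models(path) -> list[ClusterModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise SchemaError(f"{path}: not a model file (missing format_version)")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: unsupported model format version {version} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    models = []
    for entry in payload.get("models", []):
        missing = _REQUIRED_KEYS - set(entry)
        if missing:
            raise SchemaError(
                f"{path}: model entry missing keys {sorted(missing)}"
            )
        models.append(
            ClusterModel(
                cluster_id=entry["cluster_id"],
                microexon_size=entry["microexon_size"],
                phase=entry["phase"],
                block_sizes=list(entry["block_sizes"]),
                microexon_block_index=entry["microexon_block_index"],
                pfm=np.array(entry["pfm"]),
                coverage=np.array(entry["coverage"]),
                pwm=np.array(entry["pwm"]),
                background=np.array(entry["background"]),
                consensus_nt=entry["consensus_nt"],
                member_count=entry["member_count"],
                pseudocount=entry["pseudocount"],
                provenance=entry.get("provenance", ""),
            )
        )
    return models


def write_cluster_report(models: list[ClusterModel], path) -> None:
    import pandas as pd

    rows = [
        {
            "cluster_id": m.cluster_id,
            "microexon_size": m.microexon_size,
            "phase": m.phase,
            "block_sizes": ",".join(map(str, m.block_sizes)),
            "microexon_block_index": m.microexon_block_index,
            "member_count": m.member_count,
            "consensus_nt": m.consensus_nt,
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_jaspar(models: list[ClusterModel], path) -> None:
    """Per-cluster count matrices in JASPAR-style 4-row format (for logo tools)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.cluster_id} {m.consensus_nt}\n")
            for bi, base in enumerate(BASES):
                counts = " ".join(f"{c:g}" for c in m.pfm[bi])
                fh.write(f"{base}  [ {counts} ]\n")


__all__ = [
    "BASES",
    "BASE_INDEX",
    "ClusterModel",
    "ModelBuildError",
    "SchemaError",
    "group_tags",
    "cluster_group",
    "build_model",
    "build_models",
    "write_models",
    "read_models",
    "write_cluster_report",
    "write_jaspar",
]
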