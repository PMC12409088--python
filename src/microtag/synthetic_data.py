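"""Synthetic genomes with planted microexon-tags.

The generator emulates the discovery substrate of the method: coding
microexons of 1-15 nt sitting inside multi-exon genes, flanked by canonical
GT-AG introns, surrounded by intergenic background. For each locus it plants
one tag — the cluster consensus (optionally mutated at a per-base rate) split
by introns of sampled length, or left contiguous with some probability — and
emits everything the other modules consume: genome FASTA, truth GFF3, a
mis-annotated GFF3 in which the microexon is skipped and its flanks joined by
one long intron, a truth table, splice-junction files, and the model file.

All randomness flows through one numpy Generator seeded from the config, so
identical configs produce byte-identical outputs. The background is i.i.d.
from the configured base composition: no repeats, paralogy or read-level
noise, which is sufficient for desk-scale sensitivity/specificity testing
but does not emulate the repeat structure of real plant genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_model import BASES, ClusterModel, write_models
from .genomic_model import (
    GeneModel,
    GenomicInterval,
    Microexon,
    MicrotagError,
    reverse_complement,
    write_genome,
    write_gff3,
)
from .junction_validation import JunctionRecord, write_junctions
from .tag_extraction import DEFAULT_TAG_LEN, canonical_left_flank

_STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(MicrotagError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 50
    models: list[ClusterModel] | str = "random"
    n_random_models: int = 5
    per_base_mutation_rate: float = 0.0
    intron_length_range: tuple[int, int] = (60, 200)
    intergenic_length_range: tuple[int, int] = (200, 500)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fraction_intronless: float = 0.0
    junction_support_rate: float = 1.0
    n_junction_files: int = 1
    n_decoy_loci: int = 0
    extra_flank_splits: int = 0  # 0-2 additional exon splits in random models
    tag_len: int = DEFAULT_TAG_LEN

    def validate(self) -> "SimulationConfig":
        for name in (
            "per_base_mutation_rate",
            "fraction_intronless",
            "junction_support_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for name in ("intron_length_range", "intergenic_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name} = ({lo}, {hi}) is not an ordered range")
        if self.intron_length_range[0] < 4:
            raise ConfigError("introns need at least 4 nt for the GT..AG motif")
        if not np.isclose(sum(self.base_composition), 1.0):
            raise ConfigError("base_composition must sum to 1")
        if self.n_loci < 0 or self.n_decoy_loci < 0:
            raise ConfigError("negative locus counts")
        return self


@dataclass
class PlantedLocus:
    locus_id: str
    chrom: str
    strand: str
    cluster_id: str
    microexon: GenomicInterval
    size: int
    phase: int
    intronless: bool
    supported: bool
    tag_start: int
    tag_end: int
    blocks: list[GenomicInterval]
    introns: list[GenomicInterval]
    tag_nt: str
    n_mutations: int


@dataclass
class SimulatedData:
    config: SimulationConfig
    models: list[ClusterModel]
    genome: dict[str, str]
    truth_models: list[GeneModel]
    skipped_models: list[GeneModel]
    loci: list[PlantedLocus]
    junction_replicates: list[list[JunctionRecord]]

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "strand": l.strand,
                "cluster_id": l.cluster_id,
                "microexon_start": l.microexon.start + 1,
                "microexon_end": l.microexon.end,
                "size": l.size,
                "phase": l.phase,
                "intronless": l.intronless,
                "supported": l.supported,
                "tag_start": l.tag_start + 1,
                "tag_end": l.tag_end,
                "n_mutations": l.n_mutations,
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "truth_gff3": outdir / "truth.gff3",
            "skipped_gff3": outdir / "skipped.gff3",
            "truth_table": outdir / "truth.tsv",
            "models": outdir / "models.json",
        }
        write_genome(self.genome, paths["genome"])
        write_gff3(self.truth_models, paths["truth_gff3"])
        write_gff3(self.skipped_models, paths["skipped_gff3"])
        self.truth_table.to_csv(paths["truth_table"], sep="\t", index=False)
        write_models(self.models, paths["models"])
        paths["junctions"] = []
        for i, records in enumerate(self.junction_replicates, start=1):
            p = outdir / f"SJ_rep{i}.out.tab"
            write_junctions(records, p)
            paths["junctions"].append(p)
        return paths


# ---------------------------------------------------------------------------
# random cluster models

def _random_coding_nt(rng: np.random.Generator, length: int) -> str:
    """Random in-frame coding sequence (no stop codon at codon positions)."""
    codons = []
    for _ in range(length // 3):
        codon = "".join(rng.choice(list(BASES), size=3))
        while codon in _STOPS:
            codon = "".join(rng.choice(list(BASES), size=3))
        codons.append(codon)
    seq = "".join(codons)
    if len(seq) < length:
        seq += "".join(rng.choice(list(BASES), size=length - len(seq)))
    return seq


def model_from_consensus(
    consensus: str,
    block_sizes: list[int],
    microexon_block_index: int,
    size: int,
    phase: int,
    cluster_id: str,
    weight: float = 5.0,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    provenance: str = "synthetic",
) -> ClusterModel:
    """Sharp single-consensus model: each column counts ``weight`` for the
    consensus base; the PWM follows the standard pseudocount formula."""
    width = len(consensus)
    if sum(block_sizes) != width:
        raise ConfigError("block sizes do not sum to consensus length")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    pfm = np.zeros((4, width))
    for j, base in enumerate(consensus):
        pfm[BASES.index(base), j] = weight
    coverage = np.full(width, weight)
    a = float(pseudocount)
    probs = (pfm + a * background[:, None]) / (coverage[None, :] + a)
    pwm = np.log2(probs / background[:, None])
    return ClusterModel(
        cluster_id=cluster_id,
        microexon_size=size,
        phase=phase,
        block_sizes=list(block_sizes),
        microexon_block_index=microexon_block_index,
        pfm=pfm,
        coverage=coverage,
        pwm=pwm,
        background=background,
        consensus_nt=consensus,
        member_count=1,
        pseudocount=a,
        provenance=provenance,
    )


def random_cluster_models(
    rng: np.random.Generator,
    n: int,
    sizes: list[int] | None = None,
    phases: list[int] | None = None,
    tag_len: int = DEFAULT_TAG_LEN,
    extra_flank_splits: int = 0,
    prefix: str = "SYN",
) -> list[ClusterModel]:
    """Random sharp cluster models over the ultra-short size range.

    Flanks may be split into additional blocks (each piece >= 12 nt) to
    exercise 4- and 5-block tag structures.
    """
    models = []
    for i in range(n):
        size = int(sizes[i % len(sizes)]) if sizes else int(rng.integers(1, 16))
        phase = int(phases[i % len(phases)]) if phases else int(rng.integers(0, 3))
        left = canonical_left_flank(size, phase, tag_len)
        right = tag_len - size - left
        left_parts, right_parts = [left], [right]
        for _ in range(extra_flank_splits):
            side = left_parts if rng.random() < 0.5 else right_parts
            k = int(np.argmax([p for p in side]))
            piece = side[k]
            if piece >= 24:
                cut = int(rng.integers(12, piece - 11))
                side[k : k + 1] = [cut, piece - cut]
        block_sizes = left_parts + [size] + right_parts
        me_idx = len(left_parts)
        consensus = _random_coding_nt(rng, tag_len)
        models.append(
            model_from_consensus(
                consensus,
                block_sizes,
                me_idx,
                size,
                phase,
                cluster_id=f"{prefix}{i + 1:02d}",
                provenance=f"synthetic random model seed-derived #{i + 1}",
            )
        )
    return models


# ---------------------------------------------------------------------------
# simulation

def _random_background(rng: np.random.Generator, length: int, comp) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(comp)))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    out = list(seq)
    n_mut = 0
    hits = rng.random(len(seq)) < rate
    for j in np.nonzero(hits)[0]:
        alternatives = [b for b in BASES if b != out[j]]
        out[j] = alternatives[int(rng.integers(0, 3))]
        n_mut += 1
    return "".join(out), n_mut


def _flip(iv: GenomicInterval, n: int) -> GenomicInterval:
    return GenomicInterval(iv.chrom, n - iv.end, n - iv.start, "-")


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate a synthetic dataset per the config (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.models == "random":
        models = random_cluster_models(
            rng,
            config.n_random_models,
            tag_len=config.tag_len,
            extra_flank_splits=config.extra_flank_splits,
        )
    elif isinstance(config.models, str):
        raise ConfigError(f"unknown models setting {config.models!r}")
    else:
        models = list(config.models)
        if not models:
            raise ConfigError("empty model list")

    genome: dict[str, str] = {}
    truth_models: list[GeneModel] = []
    skipped_models: list[GeneModel] = []
    loci: list[PlantedLocus] = []
    junction_reps: list[list[JunctionRecord]] = [
        [] for _ in range(config.n_junction_files)
    ]

    ilo, ihi = config.intron_length_range
    glo, ghi = config.intergenic_length_range

    for i in range(config.n_loci):
        model = models[i % len(models)]
        chrom = f"locus{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        intronless = rng.random() < config.fraction_intronless
        tag_nt, n_mut = _mutate(
            rng, model.consensus_nt, config.per_base_mutation_rate
        )

        pieces = []
        offsets = []
        pos = 0
        for b, w in enumerate(model.block_sizes):
            lo, hi = model.block_columns(b)
            pieces.append(tag_nt[lo:hi])
            offsets.append(pos)
            pos += w
            if b < len(model.block_sizes) - 1 and not intronless:
                ilen = int(rng.integers(ilo, ihi + 1))
                intron = (
                    "GT"
                    + _random_background(rng, ilen - 4, config.base_composition)
                    + "AG"
                )
                pieces.append(intron)
                pos += ilen

        left_pad = int(rng.integers(glo, ghi + 1))
        right_pad = int(rng.integers(glo, ghi + 1))
        body = "".join(pieces)
        seq = (
            _random_background(rng, left_pad, config.base_composition)
            + body
            + _random_background(rng, right_pad, config.base_composition)
        )
        n = len(seq)

        # forward-construct coordinates
        block_ivs = []
        pos = left_pad
        intron_ivs = []
        for b, w in enumerate(model.block_sizes):
            block_ivs.append(GenomicInterval(chrom, pos, pos + w, "+"))
            pos += w
            if b < len(model.block_sizes) - 1 and not intronless:
                ilen = block_end = None
                # recover intron length from layout
                ilen = len(pieces[2 * b + 1])
                intron_ivs.append(GenomicInterval(chrom, pos, pos + ilen, "+"))
                pos += ilen
        me_iv = block_ivs[model.microexon_block_index]
        tag_start, tag_end = block_ivs[0].start, block_ivs[-1].end

        if strand == "-":
            seq = reverse_complement(seq)
            block_ivs = [_flip(iv, n) for iv in block_ivs]
            intron_ivs = [_flip(iv, n) for iv in intron_ivs]
            me_iv = _flip(me_iv, n)
            tag_start, tag_end = n - tag_end, n - tag_start
        genome[chrom] = seq

        # gene models: exon/CDS lists in transcript orientation
        tx_blocks = sorted(
            block_ivs, key=lambda iv: iv.start, reverse=(strand == "-")
        )
        gene_id = f"g{i + 1:04d}"
        tid = f"{gene_id}.1"
        truth_models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=list(tx_blocks),
                cds=list(tx_blocks),
            ).validate()
        )
        if intronless:
            skipped_models.append(truth_models[-1])
        else:
            skip_blocks = [
                iv
                for iv in tx_blocks
                if not (iv.start == me_iv.start and iv.end == me_iv.end)
            ]
            skipped_models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tid,
                    chrom=chrom,
                    strand=strand,
                    exons=list(skip_blocks),
                    cds=list(skip_blocks),
                ).validate()
            )

        # junction evidence
        supported = False
        if not intronless:
            flank_left = next(
                (iv for iv in intron_ivs if iv.end == me_iv.start), None
            )
            flank_right = next(
                (iv for iv in intron_ivs if iv.start == me_iv.end), None
            )
            other = [
                iv for iv in intron_ivs if iv not in (flank_left, flank_right)
            ]
            supported = rng.random() < config.junction_support_rate
            emit: list[GenomicInterval] = list(other)
            if supported:
                emit += [flank_left, flank_right]
            elif rng.random() < 0.5:
                emit.append(flank_left)  # partial evidence: one side only
            for iv in emit:
                for rep in junction_reps:
                    rep.append(
                        JunctionRecord(
                            chrom=chrom,
                            start=iv.start,
                            end=iv.end,
                            strand=strand,
                            unique_reads=int(rng.integers(3, 31)),
                            multi_reads=int(rng.integers(0, 5)),
                        )
                    )

        loci.append(
            PlantedLocus(
                locus_id=f"L{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                cluster_id=model.cluster_id,
                microexon=me_iv,
                size=model.microexon_size,
                phase=model.phase,
                intronless=intronless,
                supported=supported,
                tag_start=tag_start,
                tag_end=tag_end,
                blocks=tx_blocks,
                introns=intron_ivs,
                tag_nt=tag_nt,
                n_mutations=n_mut,
            )
        )

    for d in range(config.n_decoy_loci):
        chrom = f"decoy{d + 1:04d}"
        length = int(rng.integers(800, 2001))
        genome[chrom] = _random_background(rng, length, config.base_composition)

    return SimulatedData(
        config=config,
        models=models,
        genome=genome,
        truth_models=truth_models,
        skipped_models=skipped_models,
        loci=loci,
        junction_replicates=junction_reps,
    )


__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "PlantedLocus",
    "ConfigError",
    "simulate",
    "random_cluster_models",
    "model_from_consensus",
]
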