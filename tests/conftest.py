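"""Shared fixtures: hand-buildable toy genes and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from microtag.genomic_model import GeneModel, GenomicInterval, reverse_complement

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def random_coding(rng: np.random.Generator, length: int, lead: str = "") -> str:
    """Random sequence of ``length`` nt with no stop codon in frame 0 after
    the fixed ``lead`` prefix."""
    out = lead
    while len(out) < len(lead) + length:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon in STOPS:
            continue
        out += codon
    return out[len(lead) : len(lead) + length]


def make_gene(
    rng: np.random.Generator,
    cds_lens: list[int],
    strand: str = "+",
    chrom: str = "chr1",
    utr5: int = 0,
    utr3: int = 0,
    intron_len: int = 60,
    pad: int = 50,
    cds_seq: str | None = None,
) -> tuple[dict[str, str], GeneModel]:
    """Build a toy gene on a synthetic chromosome.

    ``cds_lens`` are the coding lengths of consecutive exons (transcript
    order). The first/last exon may carry ``utr5``/``utr3`` extra non-coding
    nt. Introns are GT..AG of ``intron_len`` nt. ``cds_seq``, if given, is
    laid into the coding positions (transcript orientation); otherwise the
    coding sequence is random and stop-free in frame 0.
    """
    total_cds = sum(cds_lens)
    if cds_seq is None:
        cds_seq = random_coding(rng, total_cds)
    assert len(cds_seq) == total_cds

    # assemble the forward (transcript-orientation) construct
    parts = []
    exon_spans = []  # (start, end, cds_start, cds_end) in construct coords
    pos = pad
    parts.append("".join(rng.choice(list(BASES), size=pad)))
    off = 0
    for i, clen in enumerate(cds_lens):
        lead = utr5 if i == 0 else 0
        tail = utr3 if i == len(cds_lens) - 1 else 0
        exon_seq = (
            "".join(rng.choice(list(BASES), size=lead))
            + cds_seq[off : off + clen]
            + "".join(rng.choice(list(BASES), size=tail))
        )
        exon_spans.append((pos, pos + len(exon_seq), pos + lead, pos + lead + clen))
        parts.append(exon_seq)
        pos += len(exon_seq)
        off += clen
        if i < len(cds_lens) - 1:
            intron = (
                "GT"
                + "".join(rng.choice(list(BASES), size=intron_len - 4))
                + "AG"
            )
            parts.append(intron)
            pos += intron_len
    parts.append("".join(rng.choice(list(BASES), size=pad)))
    seq = "".join(parts)
    n = len(seq)

    exons = [GenomicInterval(chrom, s, e, strand) for s, e, _, _ in exon_spans]
    cds = [GenomicInterval(chrom, cs, ce, strand) for _, _, cs, ce in exon_spans]
    if strand == "-":
        seq = reverse_complement(seq)
        exons = [GenomicInterval(chrom, n - iv.end, n - iv.start, "-") for iv in exons]
        cds = [GenomicInterval(chrom, n - iv.end, n - iv.start, "-") for iv in cds]
        # lists stay in transcript order: first constructed exon is 5'-most
    model = GeneModel(
        gene_id="gene1",
        transcript_id="gene1.1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
    ).validate()
    return {chrom: seq}, model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_small():
    """Small mixed-strand simulated dataset with exact (unmutated) tags."""
    from microtag.synthetic_data import SimulationConfig, simulate

    return simulate(
        SimulationConfig(seed=3, n_loci=10, n_random_models=4)
    )
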