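"""Grouping, amino-acid clustering and PWM model compilation."""

import math

import numpy as np
import pytest

from microtag.cluster_model import (
    ModelBuildError,
    SchemaError,
    build_model,
    build_models,
    cluster_group,
    group_tags,
    read_models,
    write_models,
)
from microtag.genomic_model import GenomicInterval, Microexon, translate
from microtag.scanner import score_block
from microtag.tag_extraction import MicroexonTag, canonical_left_flank

from conftest import random_coding


def make_tag(
    nt: str,
    size: int = 9,
    phase: int = 0,
    tag_id: str = "t1",
    truncate_left: int = 0,
) -> MicroexonTag:
    """Tag with the canonical 3-block structure laid on a dummy chromosome.

    ``truncate_left`` removes that many nt from the start (start-codon
    truncation); the canonical frame shrinks accordingly.
    """
    left = canonical_left_flank(size, phase) - truncate_left
    right = len(nt) - left - size
    start = 1000
    ivs = [
        GenomicInterval("c", start, start + left, "+"),
        GenomicInterval("c", start + left + 100, start + left + 100 + size, "+"),
        GenomicInterval(
            "c", start + left + 200 + size, start + left + 200 + size + right, "+"
        ),
    ]
    return MicroexonTag(
        microexon=Microexon(ivs[1], phase=phase, parent_transcript=tag_id),
        blocks=[(iv, iv.length) for iv in ivs],
        microexon_block_index=1,
        nt_sequence=nt,
        aa_sequence=translate(nt) if len(nt) >= 3 and truncate_left % 3 == 0 else "",
        phase=phase,
        truncated_left=truncate_left > 0,
        truncated_right=False,
        transcript_id=tag_id,
        chrom="c",
        strand="+",
        tag_id=tag_id,
    )


class TestGroupTags:
    def test_partition_by_size_and_phase(self, rng):
        tags = [
            make_tag(random_coding(rng, 108), size=9, phase=0, tag_id="a"),
            make_tag(random_coding(rng, 108), size=9, phase=0, tag_id="b"),
            make_tag(random_coding(rng, 108), size=1, phase=2, tag_id="c"),
        ]
        groups = group_tags(tags)
        assert set(groups) == {(9, 0), (1, 2)}
        assert len(groups[(9, 0)]) == 2
        assert sum(len(v) for v in groups.values()) == len(tags)

    def test_empty_input(self):
        assert group_tags([]) == {}

    def test_full_sweep_has_45_groups(self, rng):
        tags = [
            make_tag(random_coding(rng, 108), size=s, phase=p, tag_id=f"t{s}_{p}")
            for s in range(1, 16)
            for p in range(3)
        ]
        assert len(group_tags(tags)) == 45


class TestClusterGroup:
    def test_identical_translations_one_cluster(self, rng):
        nt = random_coding(rng, 108)
        clusters = cluster_group([make_tag(nt, tag_id="a"), make_tag(nt, tag_id="b")])
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_unrelated_sequences_split(self, rng):
        """Two random translations: verify against the explicit pairwise
        normalized-similarity table that they fall below 0.6."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        a = make_tag(random_coding(rng, 108), tag_id="a")
        b = make_tag(random_coding(rng, 108), tag_id="b")
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score, aligner.extend_gap_score = -11.0, -1.0
        cross = aligner.score(a.aa_sequence, b.aa_sequence)
        self_min = min(
            aligner.score(a.aa_sequence, a.aa_sequence),
            aligner.score(b.aa_sequence, b.aa_sequence),
        )
        assert cross / self_min < 0.6  # precondition for this fixture
        clusters = cluster_group([a, b], threshold=0.6)
        assert len(clusters) == 2

    def test_order_invariance(self, rng):
        nts = [random_coding(rng, 108) for _ in range(4)]
        # two identical pairs -> two clusters regardless of input order
        tags = [
            make_tag(nts[0], tag_id="a1"),
            make_tag(nts[0], tag_id="a2"),
            make_tag(nts[1], tag_id="b1"),
            make_tag(nts[1], tag_id="b2"),
        ]
        ref = {
            frozenset(t.tag_id for t in c) for c in cluster_group(tags)
        }
        for seed in range(3):
            shuffled = list(tags)
            np.random.default_rng(seed).shuffle(shuffled)
            got = {
                frozenset(t.tag_id for t in c) for c in cluster_group(shuffled)
            }
            assert got == ref

    def test_empty_translation_excluded_with_warning(self, rng):
        good = make_tag(random_coding(rng, 108), tag_id="g")
        bad = make_tag(random_coding(rng, 108), tag_id="x", truncate_left=1)
        assert bad.aa_sequence == ""
        with pytest.warns(UserWarning, match="empty translation"):
            clusters = cluster_group([good, bad])
        assert sum(len(c) for c in clusters) == 1


class TestBuildModel:
    def test_single_member_tiny_pseudocount_is_two_bit_consensus(self, rng):
        nt = random_coding(rng, 108)
        m = build_model([make_tag(nt)], pseudocount=1e-9)
        # uniform background: consensus column ~ log2(1/0.25) = 2 bits
        assert m.consensus_nt == nt
        assert m.max_score == pytest.approx(2 * 108, abs=1e-5)

    def test_hand_arithmetic_on_pseudocount_formula(self, rng):
        # 4 members, first column counts A:2, C:2; alpha=1, uniform background
        base = random_coding(rng, 108)
        members = [
            make_tag(b + base[1:], tag_id=f"t{i}")
            for i, b in enumerate("AACC")
        ]
        m = build_model(members, pseudocount=1.0)
        pA = (2 + 0.25) / 5
        assert m.pwm[0, 0] == pytest.approx(math.log2(pA / 0.25))
        assert m.pfm[:, 0].sum() == m.coverage[0] == 4

    def test_uniform_column_scores_zero(self, rng):
        base = random_coding(rng, 108)
        members = [
            make_tag(b + base[1:], tag_id=f"t{i}")
            for i, b in enumerate("ACGT")
        ]
        m = build_model(members)
        assert np.allclose(m.pwm[:, 0], 0.0)

    def test_truncated_member_covers_suffix_only(self, rng):
        nt = random_coding(rng, 108)
        cut = 12
        full = make_tag(nt, tag_id="full")
        part = make_tag(nt[cut:], tag_id="part", truncate_left=cut)
        m = build_model([full, part])
        assert m.member_count == 2
        assert np.all(m.coverage[:cut] == 1) and np.all(m.coverage[cut:] == 2)

    def test_all_truncated_rejected(self, rng):
        nt = random_coding(rng, 108)
        with pytest.raises(ModelBuildError, match="untruncated"):
            build_model([make_tag(nt[3:], truncate_left=3)])

    def test_conflicting_structures_without_majority_listed(self, rng):
        nt = random_coding(rng, 108)
        a = make_tag(nt, tag_id="a")
        b = make_tag(nt, tag_id="b")
        # give b a different (split) block structure with the same sequence
        iv0, n0 = b.blocks[0]
        b.blocks = [
            (GenomicInterval("c", iv0.start, iv0.start + 12, "+"), 12),
            (GenomicInterval("c", iv0.start + 50, iv0.end + 38, "+"), n0 - 12),
        ] + b.blocks[1:]
        b.microexon_block_index = 2
        with pytest.raises(ModelBuildError, match="no majority"):
            build_model([a, b])

    def test_consensus_and_anticonsensus_hit_score_bounds(self, rng):
        m = build_model([make_tag(random_coding(rng, 108))])
        total = sum(
            score_block(m, b, _window(m.consensus_nt, m, b))
            for b in range(len(m.block_sizes))
        )
        assert total == pytest.approx(m.max_score)
        anti = m.anti_consensus_nt()
        total_min = sum(
            score_block(m, b, _window(anti, m, b)) for b in range(len(m.block_sizes))
        )
        assert total_min == pytest.approx(m.min_score)


def _window(seq: str, model, block_index: int) -> str:
    lo, hi = model.block_columns(block_index)
    return seq[lo:hi]


class TestModelIO:
    def test_round_trip_within_tolerance(self, tmp_path, rng):
        models = build_models(
            [
                make_tag(random_coding(rng, 108), size=9, phase=0, tag_id=f"a{i}")
                for i in range(2)
            ]
            + [make_tag(random_coding(rng, 108), size=6, phase=0, tag_id="b")],
        )
        assert len(models) >= 2 and models[0].cluster_id.startswith("MEC")
        p = tmp_path / "models.json"
        write_models(models, p)
        back = read_models(p)
        assert [m.cluster_id for m in back] == [m.cluster_id for m in models]
        for a, b in zip(models, back):
            assert np.allclose(a.pwm, b.pwm, atol=1e-9)
            assert np.array_equal(a.pfm, b.pfm)
            assert np.array_equal(a.coverage, b.coverage)
            assert a.member_count == b.member_count
            assert a.block_sizes == b.block_sizes

    def test_missing_block_sizes_rejected(self, tmp_path, rng):
        p = tmp_path / "models.json"
        write_models([build_model([make_tag(random_coding(rng, 108))])], p)
        import json

        payload = json.loads(p.read_text())
        del payload["models"][0]["block_sizes"]
        p.write_text(json.dumps(payload))
        with pytest.raises(SchemaError, match="block_sizes"):
            read_models(p)

    def test_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "models.json"
        p.write_text('{"format_version": 99, "models": []}')
        with pytest.raises(SchemaError, match="version 99"):
            read_models(p)

    def test_minimal_handwritten_model_scores_consensus_at_max(self, tmp_path):
        """A hand-written model file scores its consensus window at max_score."""
        import json

        consensus = "ACGTAC"
        pfm = [[0.0] * 6 for _ in range(4)]
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, b in enumerate(consensus):
            pfm[idx[b]][j] = 3.0
        cov = [3.0] * 6
        a, bg = 1.0, 0.25
        pwm = [
            [math.log2((pfm[i][j] + a * bg) / (cov[j] + a) / bg) for j in range(6)]
            for i in range(4)
        ]
        payload = {
            "format_version": 1,
            "models": [
                {
                    "cluster_id": "HAND01",
                    "microexon_size": 2,
                    "phase": 0,
                    "block_sizes": [2, 2, 2],
                    "microexon_block_index": 1,
                    "pfm": pfm,
                    "coverage": cov,
                    "pwm": pwm,
                    "background": [0.25] * 4,
                    "consensus_nt": consensus,
                    "member_count": 3,
                    "pseudocount": 1.0,
                }
            ],
        }
        p = tmp_path / "hand.json"
        p.write_text(json.dumps(payload))
        (m,) = read_models(p)
        total = sum(score_block(m, b, consensus[2 * b : 2 * b + 2]) for b in range(3))
        assert total == pytest.approx(m.max_score)
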