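"""PWM scanning, splice-constrained chaining and the brute-force oracle."""

import numpy as np
import pytest

from microtag.genomic_model import reverse_complement
from microtag.scanner import (
    InputLengthError,
    OracleSizeError,
    ScanOptions,
    brute_force_scan,
    chain_hits,
    find_block_hits,
    scan,
    score_block,
)
from microtag.synthetic_data import (
    SimulationConfig,
    model_from_consensus,
    simulate,
)

OPEN = ScanOptions(min_len=0, max_len=None)  # library-mode bounds


def tiny_model():
    """6-column model, blocks 3+1+2, for hand arithmetic (weight 5, alpha 1):
    consensus column = log2(((5+.25)/6)/.25), off column = log2((.25/6)/.25)."""
    return model_from_consensus("ACGTAC", [3, 1, 2], 1, size=1, phase=0, cluster_id="T01")


CONS_BIT = np.log2(((5 + 0.25) / 6) / 0.25)  # ~ 1.8074
OFF_BIT = np.log2((0.25 / 6) / 0.25)  # ~ -2.5850


class TestScoreBlock:
    def test_consensus_window_is_block_max(self):
        m = tiny_model()
        assert score_block(m, 0, "ACG") == pytest.approx(3 * CONS_BIT)

    def test_hand_summed_mixed_window(self):
        m = tiny_model()
        # first base wrong, rest consensus
        assert score_block(m, 0, "CCG") == pytest.approx(OFF_BIT + 2 * CONS_BIT)

    def test_all_n_window_scores_zero(self):
        assert score_block(tiny_model(), 0, "NNN") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="length"):
            score_block(tiny_model(), 0, "ACGT")


class TestFindBlockHits:
    def test_planted_consensus_found_at_offset(self, rng):
        m = tiny_model()
        seq = "".join(rng.choice(list("AT"), size=40)) + "ACG" + "T" * 20
        hits = find_block_hits(m, seq, per_block_threshold=1.0, block_indices=[0])
        assert any(
            h.interval.start == 40 and h.score == pytest.approx(3 * CONS_BIT)
            for h in hits[0]
        )

    def test_threshold_zero_is_exhaustive(self):
        m = tiny_model()
        seq = "ACGTACGTAC"
        hits = find_block_hits(m, seq, per_block_threshold=-10.0, block_indices=[0])
        assert len(hits[0]) == len(seq) - 3 + 1

    def test_full_threshold_rare_on_random_sequence(self, sim_small):
        # a 40+ nt consensus block at threshold 1.0 on 10 kb of random DNA
        model = sim_small.models[0]
        local = np.random.default_rng(77)
        seq = "".join(local.choice(list("ACGT"), size=10_000))
        b = int(np.argmax(model.block_sizes))
        hits = find_block_hits(m := model, seq, per_block_threshold=1.0, block_indices=[b])
        assert hits[b] == []


def _truth_key(locus):
    return (locus.chrom, locus.strand, locus.microexon.start, locus.microexon.end)


def _pred_keys(preds):
    return {(p.seqid, p.strand, p.microexon.start, p.microexon.end) for p in preds}


class TestChaining:
    def test_planted_tag_with_introns_recovered(self, sim_small):
        preds = scan(sim_small.models, sim_small.genome, OPEN)
        found = _pred_keys(preds)
        for locus in sim_small.loci:
            assert _truth_key(locus) in found, locus.locus_id

    def test_prediction_reports_introns_and_flags(self, sim_small):
        preds = scan(sim_small.models, sim_small.genome, OPEN)
        by_key = {(p.seqid, p.strand, p.microexon.start): p for p in preds}
        for locus in sim_small.loci:
            p = by_key[(locus.chrom, locus.strand, locus.microexon.start)]
            assert all(f == "canonical" for f in p.splice_flags)
            assert sorted(iv.start for iv in p.intron_intervals) == sorted(
                iv.start for iv in locus.introns
            )

    def test_non_canonical_donor_rejected(self):
        cfg = SimulationConfig(seed=21, n_loci=1, n_random_models=1)
        d = simulate(cfg)
        locus = d.loci[0]
        chrom, seq = next(iter(d.genome.items()))
        left = next(iv for iv in locus.introns if iv.end == locus.microexon.start)
        donor = left.start if locus.strand == "+" else left.end - 2
        # mutate the donor GT (forward-strand CT..AC for a minus-strand gene)
        s = list(seq)
        if locus.strand == "+":
            assert seq[left.start : left.start + 2] == "GT"
            s[left.start] = "C"
        else:
            assert seq[left.end - 2 : left.end] == "AC"
            s[left.end - 1] = "G"
        mutated = "".join(s)
        preds = scan(d.models, {chrom: mutated}, OPEN)
        assert _truth_key(locus) not in _pred_keys(preds)

    def test_intronless_tag_needs_flag(self):
        cfg = SimulationConfig(seed=22, n_loci=4, n_random_models=2, fraction_intronless=1.0)
        d = simulate(cfg)
        strict = scan(d.models, d.genome, OPEN)
        assert strict == []
        relaxed = scan(d.models, d.genome, ScanOptions(min_len=0, max_len=None, allow_intronless=True))
        found = _pred_keys(relaxed)
        for locus in d.loci:
            assert _truth_key(locus) in found
        for p in relaxed:
            assert all(f == "absent" for f in p.splice_flags)
            assert p.intron_intervals == []


class TestScan:
    def test_short_input_rejected_quoting_bounds(self, sim_small):
        with pytest.raises(InputLengthError, match="between 200 nt and 1000000 nt"):
            scan(sim_small.models, {"s": "A" * 150})

    def test_long_input_rejected(self, sim_small):
        with pytest.raises(InputLengthError, match="1000000"):
            scan(sim_small.models, {"s": "A" * 1_000_001})

    def test_empty_model_list(self, sim_small):
        chrom, seq = next(iter(sim_small.genome.items()))
        assert scan([], {chrom: seq}, OPEN) == []

    def test_normalized_score_bounds_and_consensus_unity(self, sim_small):
        preds = scan(sim_small.models, sim_small.genome, OPEN)
        assert preds
        for p in preds:
            assert 0.0 <= p.normalized_score <= 1.0
        # unmutated planted tags with canonical introns score exactly 1
        best = max(p.normalized_score for p in preds)
        assert best == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_ordering(self, sim_small):
        a = scan(sim_small.models, sim_small.genome, OPEN)
        b = scan(sim_small.models, sim_small.genome, OPEN)
        assert [(p.seqid, p.microexon.start, p.cluster_id) for p in a] == [
            (p.seqid, p.microexon.start, p.cluster_id) for p in b
        ]


class TestStrandSymmetry:
    def test_reverse_complement_mirrors_predictions(self):
        cfg = SimulationConfig(seed=31, n_loci=3, n_random_models=2,
                               per_base_mutation_rate=0.02)
        d = simulate(cfg)
        for chrom, seq in d.genome.items():
            fwd = scan(d.models, {chrom: seq}, OPEN)
            rev = scan(d.models, {chrom: reverse_complement(seq)}, OPEN)
            n = len(seq)
            mirrored = {
                (
                    p.cluster_id,
                    "-" if p.strand == "+" else "+",
                    n - p.microexon.end,
                    n - p.microexon.start,
                    round(p.raw_score, 6),
                )
                for p in rev
            }
            original = {
                (
                    p.cluster_id,
                    p.strand,
                    p.microexon.start,
                    p.microexon.end,
                    round(p.raw_score, 6),
                )
                for p in fwd
            }
            assert mirrored == original


class TestScoreMonotonicity:
    def test_mutation_away_from_consensus_never_raises_score(self):
        cfg = SimulationConfig(seed=41, n_loci=1, n_random_models=1)
        d = simulate(cfg)
        locus = d.loci[0]
        chrom, seq = next(iter(d.genome.items()))
        base_pred = scan(d.models, {chrom: seq}, OPEN)
        base_raw = max(p.raw_score for p in base_pred)
        local = np.random.default_rng(0)
        exonic = [
            pos
            for iv in locus.blocks
            for pos in range(iv.start, iv.end)
        ]
        for pos in local.choice(exonic, size=8, replace=False):
            s = list(seq)
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            preds = scan(
                d.models, {chrom: "".join(s)},
                ScanOptions(min_len=0, max_len=None, global_threshold=0.0),
            )
            match = [
                p for p in preds
                if (p.seqid, p.strand, p.microexon.start, p.microexon.end)
                == _truth_key(locus)
            ]
            if match:  # chain may vanish entirely, never improve
                assert max(p.raw_score for p in match) <= base_raw + 1e-9


class TestOracle:
    def test_scan_matches_brute_force_on_seeded_instances(self):
        """Dual-route check: anchored chaining vs exhaustive enumeration."""
        agreements = 0
        for seed in range(15):
            cfg = SimulationConfig(
                seed=seed,
                n_loci=1,
                n_random_models=1,
                per_base_mutation_rate=0.03,
                intron_length_range=(35, 120),
                intergenic_length_range=(150, 400),
            )
            d = simulate(cfg)
            opts = ScanOptions(min_len=0, max_len=None, intron_min=35, intron_max=120)
            chrom, seq = next(iter(d.genome.items()))
            assert len(seq) <= 2000
            a = scan(d.models, {chrom: seq}, opts)
            b = brute_force_scan(d.models[0], seq, opts, seqid=chrom)
            key = lambda p: (p.strand, p.microexon.start, p.microexon.end, round(p.raw_score, 6))
            assert {key(p) for p in a} == {key(p) for p in b}, f"seed {seed}"
            agreements += 1
        assert agreements == 15

    def test_oracle_refuses_large_input(self, sim_small):
        with pytest.raises(OracleSizeError):
            brute_force_scan(sim_small.models[0], "A" * 6000)

    def test_sequence_shorter_than_tag_empty(self, sim_small):
        assert brute_force_scan(sim_small.models[0], "ACGT" * 20, OPEN) == []

    def test_two_non_overlapping_tags_both_found_by_both(self):
        cfg = SimulationConfig(seed=55, n_loci=2, n_random_models=1,
                               intron_length_range=(35, 100),
                               intergenic_length_range=(100, 200))
        d = simulate(cfg)
        # concatenate the two loci into one sequence
        seqs = list(d.genome.values())
        joined = seqs[0] + seqs[1]
        assert len(joined) <= 5000
        opts = ScanOptions(min_len=0, max_len=None, intron_min=35, intron_max=100)
        a = scan(d.models, {"j": joined}, opts)
        b = brute_force_scan(d.models[0], joined, opts, seqid="j")
        assert len(a) == len(b) == 2
        key = lambda p: (p.strand, p.microexon.start, p.raw_score)
        assert sorted(map(key, a)) == sorted(map(key, b))
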