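"""Match-block merging, chaining DP vs exhaustive enumeration, skeletons."""

import numpy as np
import pytest

from ovgraph.io_paf import Read, RunConfig, revcomp
from ovgraph.seed_index import build_index, extract_minimizer_arrays, query_index
from ovgraph.skeleton import (
    MatchBlock,
    chain_sdp,
    collect_match_blocks,
    edge_valid,
    extract_skeletons,
    rescue_repetitive,
    _edge_penalty,
)

CFG = RunConfig()


def mb(q0, q1, s0, s1, covered=None, seed=0, strand=1):
    cov = covered if covered is not None else min(q1 - q0, s1 - s0)
    return MatchBlock(seed, strand, q0, q1, s0, s1, cov)


class TestCollectMatchBlocks:
    def test_single_match_one_block(self):
        (b,) = collect_match_blocks(np.array([10]), np.array([40]), 0, 1, k=15)
        assert (b.q_start, b.q_end, b.s_start, b.s_end, b.covered) == (10, 25, 40, 55, 15)

    def test_two_colinear_matches_merge_with_union_coverage(self):
        # k-mers at offsets 0 and 20 leave a 5-base hole: 15 + 15 = 30 bases
        (b,) = collect_match_blocks(np.array([0, 20]), np.array([0, 20]), 0, 1, k=15)
        assert (b.q_start, b.q_end) == (0, 35)
        assert b.covered == 30

    def test_overlapping_kmers_counted_once(self):
        (b,) = collect_match_blocks(np.array([0, 5]), np.array([0, 5]), 0, 1, k=15)
        assert b.covered == 20  # union of [0,15) and [5,20)

    def test_diagonal_jump_beyond_max_gap_splits(self):
        blocks = collect_match_blocks(
            np.array([0, 30]), np.array([0, 330]), 0, 1, k=15, max_gap=100
        )
        assert len(blocks) == 2

    def test_nonmonotone_seed_position_splits(self):
        blocks = collect_match_blocks(
            np.array([0, 30]), np.array([300, 100]), 0, 1, k=15, max_gap=1000
        )
        assert len(blocks) == 2


class TestEdgeValidity:
    def make(self, d_q, d_s):
        a = mb(0, 100, 0, 100)
        b = mb(100 + d_q, 200 + d_q, 100 + d_s, 200 + d_s)
        return a, b

    def test_large_block_overlap_rejected(self):
        a, b = self.make(-20, 10)
        assert not edge_valid(a, b, k=15, delta=0.25)

    def test_small_relative_gap_difference_accepted(self):
        a, b = self.make(100, 102)
        assert edge_valid(a, b, k=15, delta=0.25)  # |2| < 0.25*100

    def test_large_relative_gap_difference_rejected(self):
        a, b = self.make(100, 300)
        assert not edge_valid(a, b, k=15, delta=0.25)  # 200 >= 25

    def test_degenerate_gap_clamp(self):
        # min gap <= 0: the bound becomes delta*k
        a, b = self.make(-5, -7)
        assert edge_valid(a, b, k=15, delta=0.25)  # |2| < 3.75
        a, b = self.make(-5, 10)
        assert not edge_valid(a, b, k=15, delta=0.25)  # |15| >= 3.75


def brute_force_best_chain(blocks, cfg):
    """Exhaustive DFS over all valid chains (paths in the DAG)."""
    n = len(blocks)
    best = -np.inf

    def extend(i, score):
        nonlocal best
        best = max(best, score)
        for j in range(n):
            if blocks[j].q_start > blocks[i].q_start and edge_valid(
                blocks[i], blocks[j], cfg.k, cfg.delta
            ):
                extend(j, score + blocks[j].covered - _edge_penalty(blocks[i], blocks[j], cfg))

    for i in range(n):
        extend(i, float(blocks[i].covered))
    return best


class TestChainSdp:
    def test_single_block_base_case(self):
        path, score = chain_sdp([mb(0, 30, 0, 30, covered=30)], CFG)
        assert path == [0] and score == 30

    def test_unreachable_blocks_pick_heavier(self):
        blocks = [mb(0, 50, 0, 50, covered=40), mb(10, 60, 5000, 5050, covered=48)]
        blocks.sort(key=lambda b: (b.q_start, b.s_start))
        path, score = chain_sdp(blocks, CFG)
        assert score == 48 and len(path) == 1

    def test_three_colinear_blocks_match_enumeration(self):
        blocks = [
            mb(0, 100, 0, 100),
            mb(120, 220, 121, 221),
            mb(240, 340, 243, 343),
        ]
        path, score = chain_sdp(blocks, CFG)
        assert len(path) == 3
        assert score == pytest.approx(brute_force_best_chain(blocks, CFG))

    @pytest.mark.parametrize("trial", range(20))
    def test_random_instances_match_enumeration(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(1, 13))
        blocks = []
        q = 0
        for _ in range(n):
            q += int(rng.integers(-30, 250))
            length = int(rng.integers(15, 120))
            s = q + int(rng.integers(-80, 80))
            blocks.append(mb(max(q, 0), max(q, 0) + length, max(s, 0),
                             max(s, 0) + length,
                             covered=int(rng.integers(15, length + 1))))
        blocks.sort(key=lambda b: (b.q_start, b.s_start))
        _, score = chain_sdp(blocks, CFG)
        assert score == pytest.approx(brute_force_best_chain(blocks, CFG))


def _skeletons_for(query_seq, seed_seqs, cfg=CFG, qid=100):
    seeds = [Read(i, f"s{i}", s) for i, s in enumerate(seed_seqs)]
    idx = build_index(seeds, cfg.w_sr, cfg.k, cfg.l, cfg.repeat_occ_cap)
    query = Read(qid, "q", query_seq)
    minis = extract_minimizer_arrays(query, cfg.w_sr, cfg.k)
    matches = query_index(idx, minis)
    lens = {r.id: r.length for r in seeds}
    return extract_skeletons(query, matches, cfg, lens), idx, minis, lens, query


class TestExtractSkeletons:
    def test_no_matches_empty(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 400))]
        sks, *_ = _skeletons_for("A" * 400, seqs)
        assert sks == []

    def test_identical_read_end_to_end_zero_overhangs(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        (sk,), *_ = _skeletons_for(seq, [seq])
        assert (sk.q_start, sk.q_end) == (0, 1500)
        assert (sk.s_start, sk.s_end) == (0, 1500)
        # the chain starts at the first shared minimizer, so hangs are
        # bounded by the minimizer sampling granularity, not exactly zero
        assert sk.overhang_left < 25 and sk.overhang_right < 25
        assert sk.strand == 1

    def test_containment_interval_exact(self, rng):
        seed = "".join(rng.choice(list("ACGT"), 3000))
        query = seed[700:1900]
        sks, *_ = _skeletons_for(query, [seed])
        sk = sks[0]
        assert (sk.q_start, sk.q_end) == (0, 1200)
        assert (sk.s_start, sk.s_end) == (700, 1900)
        assert sk.overhang_left < 25 and sk.overhang_right < 25

    def test_reverse_complement_containment(self, rng):
        seed = "".join(rng.choice(list("ACGT"), 3000))
        query = revcomp(seed[700:1900])
        sks, *_ = _skeletons_for(query, [seed])
        sk = sks[0]
        assert sk.strand == -1
        assert (sk.s_start, sk.s_end) == (700, 1900)

    def test_two_disjoint_seeds_two_skeletons(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), 2000))
        s2 = "".join(rng.choice(list("ACGT"), 2000))
        query = s1[1000:] + s2[:1000]
        sks, *_ = _skeletons_for(query, [s1, s2])
        assert {sk.seed for sk in sks} >= {0, 1}
        # each per-seed skeleton matches chaining that seed independently
        solo1, *_ = _skeletons_for(query, [s1])
        solo2, *_ = _skeletons_for(query, [s2])
        by_seed = {sk.seed: sk for sk in sks}
        assert by_seed[0].score == solo1[0].score
        assert by_seed[1].score == solo2[0].score

    def test_scores_non_increasing_across_extraction(self, rng):
        seed = "".join(rng.choice(list("ACGT"), 4000))
        query = seed[:1500] + seed[2000:3500]
        sks, *_ = _skeletons_for(query, [seed])
        scores = [sk.score for sk in sks]
        assert scores == sorted(scores, reverse=True)


class TestRescue:
    def test_no_repetitive_minimizers_unchanged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        sks, idx, minis, lens, query = _skeletons_for(seq, [seq])
        out = rescue_repetitive(query, minis, sks[0], idx, CFG, lens)
        assert out is sks[0]

    def test_rescue_never_decreases_score(self, rng):
        unit = "".join(rng.choice(list("ACGT"), 120))
        unique = "".join(rng.choice(list("ACGT"), 800))
        seed_seq = unique + unit * 12 + unique[::-1]
        cfg = CFG.updated(repeat_occ_cap=3)
        seeds = [Read(0, "s", seed_seq)]
        idx = build_index(seeds, cfg.w_sr, cfg.k, cfg.l, cfg.repeat_occ_cap)
        assert idx.repetitive.any()
        query = Read(5, "q", seed_seq[400:2400])
        minis = extract_minimizer_arrays(query, cfg.w_sr, cfg.k)
        matches = query_index(idx, minis)
        lens = {0: len(seed_seq)}
        sks = extract_skeletons(query, matches, cfg, lens)
        for sk in sks:
            out = rescue_repetitive(query, minis, sk, idx, cfg, lens)
            assert out.score >= sk.score

    def test_rescue_recovers_truth_placement_in_tandem_repeat(self, rng):
        unit = "".join(rng.choice(list("ACGT"), 200))
        left = "".join(rng.choice(list("ACGT"), 1500))
        right = "".join(rng.choice(list("ACGT"), 1500))
        seed_seq = left + unit * 10 + right
        cfg = CFG.updated(repeat_occ_cap=4, rescue_band=300)
        seeds = [Read(0, "s", seed_seq)]
        idx = build_index(seeds, cfg.w_sr, cfg.k, cfg.l, cfg.repeat_occ_cap)
        # query spans unique left flank plus the repeat: anchors fix the diagonal
        q0, q1 = 800, 800 + 2000
        query = Read(5, "q", seed_seq[q0:q1])
        minis = extract_minimizer_arrays(query, cfg.w_sr, cfg.k)
        matches = query_index(idx, minis)
        lens = {0: len(seed_seq)}
        sks = extract_skeletons(query, matches, cfg, lens)
        best = max(sks, key=lambda s: s.score)
        rescued = rescue_repetitive(query, minis, best, idx, cfg, lens)
        assert rescued.score >= best.score
        assert abs(rescued.s_start - q0) < 100 and abs(rescued.s_end - q1) < 100
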