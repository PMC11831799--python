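"""Alignment skeletons: colinear match blocks chained by sparse DP.

Minimizer matches between a query read and one seed read are merged into
match blocks (MBs): maximal runs of matches monotone on both reads whose
per-step diagonal drift stays within ``max_gap``.  Blocks are vertices of
a DAG; an edge i -> j (blocks ordered by query start) exists when

    D_q > -k,   D_s > -k,   |D_q - D_s| < delta * min(D_q, D_s)

where D_q and D_s are the gaps between block i's end and block j's start
on the query and seed, k is the maximum allowed block overlap (set to the
k-mer length) and delta bounds the relative gap-length difference.  When
min(D_q, D_s) <= 0 the third condition degenerates and is clamped to
|D_q - D_s| < delta * k.  Each vertex is scored by the recursion

    S(MB_j) = max_i { S(MB_i) + w(i->j) - p(i->j) }

with base case S = the block's own matched bases, edge weight w = matched
bases of the successor, and penalty p = gap_open * |D_q - D_s|
+ gap_extend * max(min(D_q, D_s), 0), so that cost is dominated by
diagonal drift.  The best path is an alignment skeleton; its blocks are
removed and chaining repeats until no high-scoring skeleton remains.

Seed coordinates are handled in an *oriented* frame: for a relative
strand of -1 every seed position p becomes seed_len - k - p (the k-mer's
position on the reverse complement), so chains ascend on both axes
regardless of strand.  Conversion back to forward seed coordinates
happens only when overlap geometry is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_paf import Read, RunConfig
from .seed_index import MatchArrays, MinimizerIndex, _MiniArrays, query_index

__all__ = [
    "MatchBlock",
    "AlignmentSkeleton",
    "group_matches",
    "collect_match_blocks",
    "edge_valid",
    "chain_sdp",
    "extract_skeletons",
    "rescue_repetitive",
]


@dataclass(frozen=True)
class MatchBlock:
    """A maximal colinear run of minimizer matches, oriented frame."""

    seed: int
    strand: int          # +1 same strand, -1 opposite
    q_start: int
    q_end: int
    s_start: int         # oriented seed coordinates
    s_end: int
    covered: int         # distinct query bases under the merged k-mer matches

    def __post_init__(self):
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("empty match block span")
        if self.covered > min(self.q_end - self.q_start, self.s_end - self.s_start):
            raise ValueError("covered exceeds block span")


@dataclass
class AlignmentSkeleton:
    """A scored chain of match blocks with its implied overlap geometry.

    The chained span is extended to the nearer read end on each side; the
    extension distances are the overhangs: ``overhang_left`` is
    min(chain q_start, oriented chain s_start), ``overhang_right`` the
    mirror image.  Both are ~0 for a genuine dovetail or containment and
    grow when unaligned sequence flanks the chain on *both* reads, the
    signature of a repeat-induced or error-truncated overlap.  Seed
    coordinates in ``s_start``/``s_end`` are forward-strand (PAF style);
    ``chain_*`` keeps the unextended span for mapping-style consumers.
    """

    query: int
    seed: int
    strand: int
    blocks: tuple
    score: float
    covered: int
    q_len: int
    s_len: int
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    overhang_left: int = 0
    overhang_right: int = 0
    chain_q_start: int = 0
    chain_q_end: int = 0
    chain_s_start: int = 0
    chain_s_end: int = 0

    @property
    def overlap_len(self) -> int:
        return min(self.q_end - self.q_start, self.s_end - self.s_start)


def _finish_skeleton(query: Read, s_len: int, strand: int,
                     path: Sequence[MatchBlock], score: float) -> AlignmentSkeleton:
    qs, qe = path[0].q_start, path[-1].q_end
    ss, se = path[0].s_start, path[-1].s_end
    q_len = query.length
    e_l = min(qs, ss)
    e_r = min(q_len - qe, s_len - se)
    oq0, oq1 = qs - e_l, qe + e_r
    os0, os1 = ss - e_l, se + e_r
    covered = sum(b.covered for b in path)
    # forward-strand seed coordinates
    if strand < 0:
        fs0, fs1 = s_len - os1, s_len - os0
        cs0, cs1 = s_len - se, s_len - ss
    else:
        fs0, fs1 = os0, os1
        cs0, cs1 = ss, se
    return AlignmentSkeleton(
        query=query.id, seed=path[0].seed, strand=strand,
        blocks=tuple(path), score=score, covered=covered,
        q_len=q_len, s_len=s_len,
        q_start=oq0, q_end=oq1, s_start=fs0, s_end=fs1,
        overhang_left=e_l,
        overhang_right=e_r,
        chain_q_start=qs, chain_q_end=qe,
        chain_s_start=cs0, chain_s_end=cs1,
    )


def group_matches(matches: MatchArrays, seed_lens: dict, k: int):
    """Split raw matches into (seed, strand) groups in the oriented frame.

    Returns {(seed, strand): (q_pos array, oriented s_pos array)} with
    each group sorted by (q_pos, s_pos).
    """
    groups = {}
    if len(matches.q_p) == 0:
        return groups
    key = matches.seed * 2 + (matches.strand > 0)
    order = np.lexsort((matches.s_p, matches.q_p, key))
    qp = matches.q_p[order]
    sp = matches.s_p[order]
    seed = matches.seed[order]
    strand = matches.strand[order]
    bounds = np.flatnonzero(
        np.concatenate(([True], (seed[1:] != seed[:-1]) | (strand[1:] != strand[:-1])))
    )
    ends = np.concatenate((bounds[1:], [len(qp)]))
    for b, e in zip(bounds, ends):
        sd, st = int(seed[b]), int(strand[b])
        s_or = sp[b:e]
        if st < 0:
            s_or = seed_lens[sd] - k - s_or
        sub = np.lexsort((s_or, qp[b:e]))
        groups[(sd, st)] = (qp[b:e][sub], s_or[sub])
    return groups


def collect_match_blocks(
    q_pos: np.ndarray,
    s_pos: np.ndarray,
    seed: int,
    strand: int,
    k: int,
    max_gap: int = 100,
) -> list[MatchBlock]:
    """Greedily merge sorted colinear matches of one group into blocks.

    A match extends the current block when both coordinates are monotone
    non-decreasing and its diagonal differs from the previous match's by
    at most ``max_gap``.  ``covered`` counts distinct query bases under
    the k-mer matches of the block.
    """
    blocks: list[MatchBlock] = []
    n = len(q_pos)
    if n == 0:
        return blocks
    bq0 = int(q_pos[0])
    bs0 = int(s_pos[0])
    last_q, last_s = bq0, bs0
    last_diag = bq0 - bs0
    covered = k

    def flush(q1, s1):
        blocks.append(MatchBlock(seed, strand, bq0, q1 + k, bs0, s1 + k, covered))

    for i in range(1, n):
        q, s = int(q_pos[i]), int(s_pos[i])
        diag = q - s
        if q >= last_q and s >= last_s and abs(diag - last_diag) <= max_gap:
            covered += min(k, q - last_q)
        else:
            flush(last_q, last_s)
            bq0, bs0 = q, s
            covered = k
        last_q, last_s, last_diag = q, s, diag
    flush(last_q, last_s)
    return blocks


def _gaps(mb_i: MatchBlock, mb_j: MatchBlock) -> tuple[int, int]:
    return mb_j.q_start - mb_i.q_end, mb_j.s_start - mb_i.s_end


def edge_valid(mb_i: MatchBlock, mb_j: MatchBlock, k: int, delta: float) -> bool:
    """Colinearity test for a chaining edge between two ordered blocks."""
    d_q, d_s = _gaps(mb_i, mb_j)
    if d_q <= -k or d_s <= -k:
        return False
    m = min(d_q, d_s)
    bound = delta * (m if m > 0 else k)
    return abs(d_q - d_s) < bound


def _edge_penalty(mb_i: MatchBlock, mb_j: MatchBlock, cfg: RunConfig) -> float:
    d_q, d_s = _gaps(mb_i, mb_j)
    return cfg.gap_open * abs(d_q - d_s) + cfg.gap_extend * max(min(d_q, d_s), 0)


def chain_sdp(
    blocks: Sequence[MatchBlock], cfg: RunConfig
) -> tuple[list[int], float]:
    """Best chain through the block DAG by the vertex-score recursion.

    Returns (indices of the best path in input order, its score).  Blocks
    must be sorted by (q_start, s_start); edges run from earlier to later
    query starts only, so the graph is acyclic by construction.
    """
    n = len(blocks)
    if n == 0:
        return [], 0.0
    score = [float(b.covered) for b in blocks]
    parent = [-1] * n
    for j in range(1, n):
        bj = blocks[j]
        for i in range(j - 1, -1, -1):
            bi = blocks[i]
            if bi.q_start >= bj.q_start:
                continue
            if not edge_valid(bi, bj, cfg.k, cfg.delta):
                continue
            cand = score[i] + bj.covered - _edge_penalty(bi, bj, cfg)
            if cand > score[j]:
                score[j] = cand
                parent[j] = i
    best = int(np.argmax(score))
    path = []
    i = best
    while i != -1:
        path.append(i)
        i = parent[i]
    path.reverse()
    return path, score[best]


def extract_skeletons(
    query: Read,
    matches: MatchArrays,
    cfg: RunConfig,
    seed_lens: dict,
) -> list[AlignmentSkeleton]:
    """All high-scoring skeletons of one query against the seed batch.

    Repeatedly takes the globally best chain across every (seed, strand)
    group, removes its blocks from the group, and re-chains, until the
    best remaining score drops below ``min_skeleton_score``.
    """
    groups = group_matches(matches, seed_lens, cfg.k)
    group_blocks = {
        key: collect_match_blocks(qp, sp, key[0], key[1], cfg.k, cfg.max_gap)
        for key, (qp, sp) in groups.items()
    }
    cache: dict = {}
    skeletons: list[AlignmentSkeleton] = []
    while True:
        best_key, best_path, best_score = None, None, -np.inf
        for key, blocks in group_blocks.items():
            if not blocks:
                continue
            if key not in cache:
                cache[key] = chain_sdp(blocks, cfg)
            path, score = cache[key]
            if score > best_score or (score == best_score and best_key is not None
                                      and key < best_key):
                best_key, best_path, best_score = key, path, score
        if best_key is None or best_score < cfg.min_skeleton_score:
            break
        blocks = group_blocks[best_key]
        chosen = [blocks[i] for i in best_path]
        skeletons.append(
            _finish_skeleton(query, seed_lens[best_key[0]], best_key[1],
                             chosen, best_score)
        )
        remaining = [b for i, b in enumerate(blocks) if i not in set(best_path)]
        group_blocks[best_key] = remaining
        cache.pop(best_key, None)
    return skeletons


def rescue_repetitive(
    query: Read,
    query_minis: _MiniArrays,
    skeleton: AlignmentSkeleton,
    index: MinimizerIndex,
    cfg: RunConfig,
    seed_lens: dict,
) -> AlignmentSkeleton:
    """Refine a weak skeleton by re-searching repetitive minimizers.

    Repetitive hash values of the query are re-queried against the
    skeleton's seed only, keeping matches within ``rescue_band`` of the
    existing chain's diagonal; the block set is rebuilt and rechained.
    Returns the better of the original and refined skeleton, so the score
    never decreases.
    """
    rep_vals = {
        int(v) for v in query_minis.v if int(v) in index.repetitive_values
    }
    if len(rep_vals) < cfg.rescue_min_repetitive:
        return skeleton
    # re-query everything (repetitive included) against the skeleton's seed
    full = query_index(
        index, query_minis, include_repetitive=True, exclude_read=query.id,
    )
    if len(full.q_p) == 0:
        return skeleton
    keep = full.seed == skeleton.seed
    keep &= (full.strand > 0) == (skeleton.strand > 0)
    if not keep.any():
        return skeleton
    s_len = seed_lens[skeleton.seed]
    sp = full.s_p[keep]
    qp = full.q_p[keep]
    if skeleton.strand < 0:
        sp = s_len - cfg.k - sp
    diag0 = int(np.median([b.q_start - b.s_start for b in skeleton.blocks]))
    band = np.abs((qp - sp) - diag0) <= cfg.rescue_band
    if not band.any():
        return skeleton
    qp, sp = qp[band], sp[band]
    order = np.lexsort((sp, qp))
    blocks = collect_match_blocks(
        qp[order], sp[order], skeleton.seed, skeleton.strand,
        cfg.k, cfg.max_gap,
    )
    path, score = chain_sdp(blocks, cfg)
    if not path or score <= skeleton.score:
        return skeleton
    return _finish_skeleton(query, s_len, skeleton.strand,
                            [blocks[i] for i in path], score)
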