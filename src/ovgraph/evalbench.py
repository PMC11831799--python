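"""Evaluation of an overlap graph against (pseudo-)ground truth.

Truth comes either from simulator placements or from read-to-reference
mappings in PAF (reads unmapped or below ``min_mapq`` are flagged
ambiguous and excluded from every denominator; reads may keep multiple
placements).  True overlaps are unordered read pairs whose placement
intervals intersect by more than 500 bp on any placement combination.

Metrics:

* precision = TP / reported, sensitivity = TP / truth, where a reported
  pair is a true positive iff it is in the truth pair set;
* R%: fraction of reads having at least one truth overlap for which at
  least one true overlap was recovered;
* C% and Gap Num.: genome fraction covered by the union of placements of
  edge-bearing reads, and the number of maximal uncovered runs;
* Con. Num.: connected components among edge-bearing reads;
* block-wise FPR and R%: the genome is tiled into fixed-size blocks, a
  read belongs to every block its placement intersects, and per block the
  false-positive rate (FPs among overlaps touching the block) and R% are
  computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_paf import OverlapRecord, ReadSet
from .simreads import TruePlacement

__all__ = [
    "GroundTruthSet",
    "EvalReport",
    "build_truth",
    "reported_pairs_from_records",
    "reported_pairs_from_graph",
    "score_overlaps",
    "graph_metrics",
    "blockwise",
    "evaluate",
]

MIN_TRUE_OVERLAP = 500


@dataclass
class GroundTruthSet:
    """Per-read placements, ambiguity flags and derived truth pairs."""

    placements: dict                 # read id -> list of (start, end, strand)
    ambiguous: set                   # read ids excluded from all denominators
    truth_pairs: set                 # unordered (a, b) id pairs, a < b
    pair_lengths: dict = field(default_factory=dict)

    def reads_with_truth(self) -> set:
        out = set()
        for a, b in self.truth_pairs:
            out.add(a)
            out.add(b)
        return out


@dataclass
class EvalReport:
    precision: float
    sensitivity: float
    n_tp: int
    n_reported: int
    n_truth: int
    r_pct: float = float("nan")
    c_pct: float = float("nan")
    gap_num: int = 0
    con_num: int = 0
    block_size: int = 0
    block_fpr: list = field(default_factory=list)
    block_r: list = field(default_factory=list)


def _pairs_from_placements(placements: dict, ambiguous: set,
                           min_len: int) -> tuple[set, dict]:
    ivs = []
    for rid, plist in placements.items():
        if rid in ambiguous:
            continue
        for s, e, _ in plist:
            ivs.append((s, e, rid))
    ivs.sort()
    pairs: set = set()
    lengths: dict = {}
    for idx, (s, e, rid) in enumerate(ivs):
        for s2, e2, rid2 in ivs[idx + 1:]:
            if s2 >= e - min_len:
                break
            if rid == rid2:
                continue
            ov = min(e, e2) - s2
            if ov > min_len:
                key = (rid, rid2) if rid < rid2 else (rid2, rid)
                pairs.add(key)
                lengths[key] = max(lengths.get(key, 0), ov)
    return pairs, lengths


def build_truth(
    placements: list[TruePlacement] | None = None,
    mapping_records: list[OverlapRecord] | None = None,
    reads: ReadSet | None = None,
    min_mapq: int = 10,
    min_len: int = MIN_TRUE_OVERLAP,
    ref_len: int | None = None,
) -> GroundTruthSet:
    """Derive the ground-truth overlap set from one placement source.

    Exactly one of ``placements`` (simulator truth) or ``mapping_records``
    (read-to-reference PAF, requires ``reads``) must be given.
    """
    if (placements is None) == (mapping_records is None):
        raise ValueError("give exactly one of placements or mapping_records")
    by_read: dict = {}
    ambiguous: set = set()
    if placements is not None:
        for p in placements:
            if ref_len is not None and p.ref_end > ref_len:
                raise ValueError(
                    f"placement {p.ref_start}-{p.ref_end} beyond reference {ref_len}"
                )
            by_read.setdefault(p.read_id, []).append(
                (p.ref_start, p.ref_end, p.strand)
            )
    else:
        if reads is None:
            raise ValueError("reads are required to resolve PAF names")
        mapped: set = set()
        for rec in mapping_records:
            rid = reads.by_name(rec.query_name).id
            if rec.mapq < min_mapq:
                ambiguous.add(rid)
                continue
            if ref_len is not None and rec.target_end > ref_len:
                raise ValueError("mapping beyond reference length")
            mapped.add(rid)
            by_read.setdefault(rid, []).append(
                (rec.target_start, rec.target_end, rec.strand)
            )
        for r in reads:
            if r.id not in mapped:
                ambiguous.add(r.id)
        for rid in ambiguous:
            by_read.pop(rid, None)
    pairs, lengths = _pairs_from_placements(by_read, ambiguous, min_len)
    return GroundTruthSet(
        placements=by_read, ambiguous=ambiguous,
        truth_pairs=pairs, pair_lengths=lengths,
    )


def reported_pairs_from_records(records: list[OverlapRecord],
                                reads: ReadSet) -> set:
    pairs = set()
    for rec in records:
        a = reads.by_name(rec.query_name).id
        b = reads.by_name(rec.target_name).id
        if a != b:
            pairs.add((a, b) if a < b else (b, a))
    return pairs


def reported_pairs_from_graph(graph) -> set:
    return {
        (u, v) if u < v else (v, u) for u, v, _ in graph.edges()
    }


def score_overlaps(reported: set, truth: GroundTruthSet) -> EvalReport:
    """Precision and sensitivity over deduplicated unordered pairs.

    Pairs touching an ambiguous read are dropped from the reported count.
    """
    usable = {
        p for p in reported
        if p[0] not in truth.ambiguous and p[1] not in truth.ambiguous
    }
    tp = len(usable & truth.truth_pairs)
    n_rep = len(usable)
    n_truth = len(truth.truth_pairs)
    return EvalReport(
        precision=tp / n_rep if n_rep else float("nan"),
        sensitivity=tp / n_truth if n_truth else float("nan"),
        n_tp=tp, n_reported=n_rep, n_truth=n_truth,
    )


def _union_coverage(intervals: list[tuple[int, int]], genome_len: int):
    """Covered bases and maximal uncovered runs of the genome."""
    if not intervals:
        return 0, 1 if genome_len > 0 else 0
    ivs = sorted(intervals)
    covered = 0
    gaps = 0
    cur_end = 0
    for s, e in ivs:
        s = max(s, 0)
        e = min(e, genome_len)
        if e <= s:
            continue
        if s > cur_end:
            gaps += 1
            covered += e - s
            cur_end = e
        else:
            if e > cur_end:
                covered += e - cur_end
                cur_end = e
    if cur_end < genome_len:
        gaps += 1
    return covered, gaps


def graph_metrics(graph, truth: GroundTruthSet, genome_len: int):
    """(r_pct, c_pct, gap_num, con_num) of the produced graph."""
    reported = reported_pairs_from_graph(graph)
    usable = {
        p for p in reported
        if p[0] not in truth.ambiguous and p[1] not in truth.ambiguous
    }
    tp_pairs = usable & truth.truth_pairs
    eligible = truth.reads_with_truth()
    recovered = set()
    for a, b in tp_pairs:
        recovered.add(a)
        recovered.add(b)
    r_pct = len(recovered & eligible) / len(eligible) if eligible else float("nan")
    edge_bearing = [n for n in graph.g.nodes if graph.g.degree(n) > 0]
    intervals = []
    for rid in edge_bearing:
        for s, e, _ in truth.placements.get(rid, ()):  # ambiguous reads have none
            intervals.append((s, e))
    covered, gap_num = _union_coverage(intervals, genome_len)
    c_pct = covered / genome_len if genome_len else float("nan")
    sub = graph.g.subgraph(edge_bearing)
    con_num = nx.number_connected_components(sub) if edge_bearing else 0
    return r_pct, c_pct, gap_num, con_num


def blockwise(reported: set, truth: GroundTruthSet, genome_len: int,
              block_size: int):
    """Per-block (FPR, R%); blocks with no reads report None.

    A read belongs to every block its placement intersects.  For a block,
    FPR is the fraction of false positives among all reported overlaps
    touching the block, and R% the fraction of the block's truth-bearing
    reads with at least one true overlap recovered.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    n_blocks = max(1, -(-genome_len // block_size))
    read_blocks: dict = {}
    block_reads: list[set] = [set() for _ in range(n_blocks)]
    for rid, plist in truth.placements.items():
        if rid in truth.ambiguous:
            continue
        blocks = set()
        for s, e, _ in plist:
            first = max(0, s // block_size)
            last = min(n_blocks - 1, (e - 1) // block_size)
            blocks.update(range(first, last + 1))
        read_blocks[rid] = blocks
        for b in blocks:
            block_reads[b].add(rid)
    usable = {
        p for p in reported
        if p[0] not in truth.ambiguous and p[1] not in truth.ambiguous
    }
    fp_count = np.zeros(n_blocks, int)
    all_count = np.zeros(n_blocks, int)
    recovered: set = set()
    for pair in usable:
        is_tp = pair in truth.truth_pairs
        if is_tp:
            recovered.update(pair)
        touched = read_blocks.get(pair[0], set()) | read_blocks.get(pair[1], set())
        for b in touched:
            all_count[b] += 1
            if not is_tp:
                fp_count[b] += 1
    eligible = truth.reads_with_truth()
    fpr, rpct = [], []
    for b in range(n_blocks):
        if not block_reads[b]:
            fpr.append(None)
            rpct.append(None)
            continue
        fpr.append(fp_count[b] / all_count[b] if all_count[b] else None)
        elig_b = block_reads[b] & eligible
        rpct.append(len(elig_b & recovered) / len(elig_b) if elig_b else None)
    return fpr, rpct


def evaluate(graph, truth: GroundTruthSet, genome_len: int,
             block_size: int = 1000) -> EvalReport:
    """Full report: precision/sensitivity, graph metrics, block-wise rates."""
    reported = reported_pairs_from_graph(graph)
    report = score_overlaps(reported, truth)
    r_pct, c_pct, gap_num, con_num = graph_metrics(graph, truth, genome_len)
    fpr, rpct = blockwise(reported, truth, genome_len, block_size)
    report.r_pct = r_pct
    report.c_pct = c_pct
    report.gap_num = gap_num
    report.con_num = con_num
    report.block_size = block_size
    report.block_fpr = fpr
    report.block_r = rpct
    return report
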