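"""The global overlap graph, coverage model and iteration driver.

Skeletons surviving three filters become confident read overlaps (CROs):
(i) implied overlap length >= ``t_om``, (ii) non-redundant matched bases
>= ``t_nb``, (iii) overhang on both reads <= ``t_oh``; of the survivors
the ``n_as`` highest-scored per query are kept.  CROs accumulate in an
undirected graph (one edge per read pair, higher score wins).

Read coverage drives the iteration: each read is split into ``w_rc``-sized
non-overlapping windows; a window counts an edge as direct coverage when
the edge's interval on the read spans at least half of it, and counts a
read connected to the same seed as indirect coverage when that read's
interval on the seed, projected through the shared edge onto this read,
spans at least half of it.  A read's coverage is the mean over its
windows.  The adaptive threshold T_RC = median(read coverage) * ``p_rc``
defines the low-covered reads that become the next seed candidates and
the queries of later iterations; construction stops when too few new
seeds can be selected.

Optionally, the core graph is expanded by breadth-first transitive
inference: two reads sharing a neighbor gain an edge when composing the
two coordinate maps yields a geometry that passes the same length and
overhang checks as a CRO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_paf import OverlapRecord, Read, ReadSet, RunConfig
from .seed_index import (
    CoverageState,
    build_index,
    extract_minimizer_arrays,
    low_covered,
    query_index,
    select_seeds_initial,
    select_seeds_iter,
)
from .skeleton import AlignmentSkeleton, extract_skeletons, rescue_repetitive

__all__ = [
    "OverlapGraph",
    "CoverageProfile",
    "filter_cro",
    "add_overlaps",
    "estimate_read_coverage",
    "compute_trc",
    "should_stop",
    "run_iterations",
    "infer_transitive",
    "graph_to_records",
]

logger = logging.getLogger("ovgraph")


class OverlapGraph:
    """Undirected multi-attribute graph of confident read overlaps.

    One edge per unordered read pair; attributes record which endpoint was
    the query (``qid``) and the overlap geometry on both reads, with seed
    coordinates on the forward strand.
    """

    def __init__(self):
        self.g = nx.Graph()

    def __len__(self):
        return self.g.number_of_edges()

    def has_edge(self, a: int, b: int) -> bool:
        return self.g.has_edge(a, b)

    def edges(self):
        return self.g.edges(data=True)

    def neighbors(self, rid: int):
        if rid not in self.g:
            return ()
        return self.g.neighbors(rid)

    def edge(self, a: int, b: int) -> dict:
        return self.g.edges[a, b]

    def nodes_with_edges(self) -> list[int]:
        return [n for n in self.g.nodes if self.g.degree(n) > 0]

    def interval_on(self, data: dict, rid: int) -> tuple[int, int]:
        """The overlap interval of edge ``data`` on read ``rid``."""
        if data["qid"] == rid:
            return data["q_start"], data["q_end"]
        if data["tid"] == rid:
            return data["t_start"], data["t_end"]
        raise KeyError(f"read {rid} not on edge {data['qid']}-{data['tid']}")


@dataclass
class CoverageProfile:
    """Per-read window coverage and its mean."""

    w_rc: int
    windows: dict            # read id -> float array of per-window counts
    read_cov: np.ndarray     # mean window coverage per read

    def coverage(self, rid: int) -> float:
        return float(self.read_cov[rid])


def filter_cro(skeletons: list[AlignmentSkeleton], cfg: RunConfig) -> list[AlignmentSkeleton]:
    """Apply the three CRO filters, then keep the n_as highest-scored."""
    kept = [
        sk for sk in skeletons
        if sk.overlap_len >= cfg.t_om
        and sk.covered >= cfg.t_nb
        and sk.overhang_left <= cfg.t_oh
        and sk.overhang_right <= cfg.t_oh
    ]
    kept.sort(key=lambda sk: (-sk.score, sk.seed))
    return kept[: cfg.n_as]


def add_overlaps(graph: OverlapGraph, cros: list[AlignmentSkeleton],
                 iteration: int = 0) -> int:
    """Insert CROs as edges; a duplicate pair keeps the higher score."""
    added = 0
    for sk in cros:
        if sk.query == sk.seed:
            continue
        attrs = dict(
            qid=sk.query, tid=sk.seed,
            q_start=sk.q_start, q_end=sk.q_end,
            t_start=sk.s_start, t_end=sk.s_end,
            strand=sk.strand, score=float(sk.score), covered=int(sk.covered),
            hang_l=int(sk.overhang_left), hang_r=int(sk.overhang_right),
            iteration=iteration, inferred=False,
        )
        if graph.has_edge(sk.query, sk.seed):
            if graph.edge(sk.query, sk.seed)["score"] >= attrs["score"]:
                continue
        else:
            added += 1
        graph.g.add_edge(sk.query, sk.seed, **attrs)
    return added


def _project(data: dict, src: int, dst: int, lo: float, hi: float) -> tuple[float, float]:
    """Affine-map an interval on read ``src`` through edge ``data`` to ``dst``."""
    s0, s1 = (data["q_start"], data["q_end"]) if data["qid"] == src else (
        data["t_start"], data["t_end"])
    d0, d1 = (data["q_start"], data["q_end"]) if data["qid"] == dst else (
        data["t_start"], data["t_end"])
    span_s = s1 - s0
    span_d = d1 - d0
    f0 = (lo - s0) / span_s
    f1 = (hi - s0) / span_s
    if data["strand"] > 0:
        a, b = d0 + f0 * span_d, d0 + f1 * span_d
    else:
        a, b = d1 - f1 * span_d, d1 - f0 * span_d
    return (a, b) if a <= b else (b, a)


def _mark_windows(win: np.ndarray, w_rc: int, read_len: int,
                  lo: float, hi: float) -> None:
    """Add one count to each window at least half-spanned by [lo, hi)."""
    lo = max(lo, 0.0)
    hi = min(hi, float(read_len))
    if hi <= lo:
        return
    first = int(lo // w_rc)
    last = min(int(math.ceil(hi / w_rc)), len(win))
    for wi in range(first, last):
        w0 = wi * w_rc
        w1 = min(w0 + w_rc, read_len)
        if min(hi, w1) - max(lo, w0) >= 0.5 * (w1 - w0):
            win[wi] += 1.0


def estimate_read_coverage(graph: OverlapGraph, reads: ReadSet,
                           w_rc: int = 1000) -> CoverageProfile:
    """Window-based coverage from direct edges and shared-seed projections."""
    windows = {
        r.id: np.zeros(max(1, math.ceil(r.length / w_rc))) for r in reads
    }
    for rid in range(len(reads)):
        if rid not in graph.g:
            continue
        win = windows[rid]
        rlen = reads[rid].length
        for nb in graph.neighbors(rid):
            data = graph.edge(rid, nb)
            lo, hi = graph.interval_on(data, rid)
            _mark_windows(win, w_rc, rlen, lo, hi)
            # indirect: reads sharing the neighbor, projected through it
            r_lo, r_hi = graph.interval_on(data, nb)
            for other in graph.neighbors(nb):
                if other == rid:
                    continue
                odata = graph.edge(nb, other)
                o_lo, o_hi = graph.interval_on(odata, nb)
                j_lo, j_hi = max(r_lo, o_lo), min(r_hi, o_hi)
                if j_hi <= j_lo:
                    continue
                p_lo, p_hi = _project(data, nb, rid, j_lo, j_hi)
                _mark_windows(win, w_rc, rlen, p_lo, p_hi)
    read_cov = np.array([windows[i].mean() for i in range(len(reads))])
    return CoverageProfile(w_rc=w_rc, windows=windows, read_cov=read_cov)


def compute_trc(profile: CoverageProfile, p_rc: float = 0.5) -> float:
    """Adaptive low-coverage threshold: median read coverage times p_rc."""
    if len(profile.read_cov) == 0:
        raise ValueError("coverage profile over zero reads")
    return float(np.median(profile.read_cov)) * p_rc


def should_stop(n_reads: int, newly_selected: int, iteration: int,
                cfg: RunConfig) -> bool:
    """Stop when too few new seeds were selected or the cap is hit."""
    if iteration >= cfg.max_iterations:
        return True
    return newly_selected < cfg.stop_fraction * n_reads


def _process_queries(graph, reads, index, seed_lens, query_ids, cfg, iteration):
    n_skel = n_cro = 0
    for qid in query_ids:
        query = reads[qid]
        minis = extract_minimizer_arrays(query, cfg.w_sr, cfg.k)
        if len(minis) == 0:
            continue
        matches = query_index(index, minis, exclude_read=qid)
        skeletons = extract_skeletons(query, matches, cfg, seed_lens)
        rescue_cut = cfg.rescue_factor * cfg.min_skeleton_score
        best = max((sk.score for sk in skeletons), default=0.0)
        if best < rescue_cut:
            skeletons = [
                rescue_repetitive(query, minis, sk, index, cfg, seed_lens)
                if sk.score < rescue_cut else sk
                for sk in skeletons
            ]
        n_skel += len(skeletons)
        cros = filter_cro(skeletons, cfg)
        n_cro += add_overlaps(graph, cros, iteration)
    return n_skel, n_cro


def run_iterations(reads: ReadSet, cfg: RunConfig | None = None):
    """Coverage-guided iterative construction of the overlap graph.

    Returns (graph, coverage profile, state).  Deterministic given
    ``cfg.rng_seed``.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    if len(reads) == 0:
        raise ValueError("empty ReadSet")
    rng = np.random.default_rng(cfg.rng_seed)
    graph = OverlapGraph()
    state = CoverageState(n_reads=len(reads))
    seeds = select_seeds_initial(reads, cfg.p0, cfg.batch_bases)
    profile = None
    t_rc = 0.0
    while True:
        state.iteration += 1
        index = build_index(
            (reads[i] for i in seeds), cfg.w_sr, cfg.k, cfg.l, cfg.repeat_occ_cap
        )
        seed_lens = {i: reads[i].length for i in seeds}
        if state.iteration == 1:
            query_ids = range(len(reads))
        else:
            query_ids = [
                i for i in range(len(reads))
                if low_covered(state.coverage[i], t_rc)
            ]
        n_skel, n_new = _process_queries(
            graph, reads, index, seed_lens, query_ids, cfg, state.iteration
        )
        state.used_seeds.update(seeds)
        profile = estimate_read_coverage(graph, reads, cfg.w_rc)
        state.coverage = profile.read_cov
        t_rc = compute_trc(profile, cfg.p_rc)
        new_seeds = select_seeds_iter(
            state, reads, cfg.ps, t_rc, rng, cfg.batch_bases
        )
        logger.info(
            "iteration %d: %d seeds, %d queries, %d skeletons, %d new edges, "
            "median coverage %.2f",
            state.iteration, len(seeds), len(list(query_ids)), n_skel, n_new,
            float(np.median(profile.read_cov)),
        )
        if should_stop(len(reads), len(new_seeds), state.iteration, cfg):
            break
        seeds = new_seeds
    return graph, profile, state


def _compose_geometry(a: int, b: int, ea: dict, eb: dict, shared: int,
                      len_a: int, len_b: int, cfg: RunConfig):
    """Infer the overlap of reads a, b from their edges to a shared read."""
    a_lo, a_hi = (ea["q_start"], ea["q_end"]) if ea["qid"] == shared else (
        ea["t_start"], ea["t_end"])
    b_lo, b_hi = (eb["q_start"], eb["q_end"]) if eb["qid"] == shared else (
        eb["t_start"], eb["t_end"])
    j_lo, j_hi = max(a_lo, b_lo), min(a_hi, b_hi)
    if j_hi - j_lo < cfg.t_om:
        return None
    pa = _project(ea, shared, a, j_lo, j_hi)
    pb = _project(eb, shared, b, j_lo, j_hi)
    strand = ea["strand"] * eb["strand"]
    qa0, qa1 = pa
    if strand > 0:
        ob0, ob1 = pb
    else:
        ob0, ob1 = len_b - pb[1], len_b - pb[0]
    # dovetail extension to the nearer end on each side (oriented frame)
    e_l = min(qa0, ob0)
    e_r = min(len_a - qa1, len_b - ob1)
    oa = (qa0 - e_l, qa1 + e_r)
    ob = (ob0 - e_l, ob1 + e_r)
    if e_l > cfg.t_oh or e_r > cfg.t_oh:
        return None
    ovl = min(oa[1] - oa[0], ob[1] - ob[0])
    if ovl < cfg.t_om:
        return None
    if strand > 0:
        fb = ob
    else:
        fb = (len_b - ob[1], len_b - ob[0])
    q0, q1 = int(round(oa[0])), int(round(oa[1]))
    t0, t1 = int(round(fb[0])), int(round(fb[1]))
    q0, q1 = max(q0, 0), min(q1, len_a)
    t0, t1 = max(t0, 0), min(t1, len_b)
    if q1 <= q0 or t1 <= t0:
        return None
    return dict(
        qid=a, tid=b, q_start=q0, q_end=q1, t_start=t0, t_end=t1,
        strand=strand, score=float(min(ea["score"], eb["score"])),
        covered=0, hang_l=int(round(e_l)), hang_r=int(round(e_r)),
        inferred=True,
    )


def infer_transitive(graph: OverlapGraph, iterations: int,
                     cfg: RunConfig | None = None,
                     read_lens: dict | None = None) -> int:
    """Breadth-first transitive expansion of the overlap graph.

    Per iteration every pair of reads sharing a neighbor is tested; pairs
    whose composed geometry passes the CRO length/overhang checks gain an
    inferred edge (tagged with the iteration it was added in), usable by
    later iterations.  Stops early when an iteration adds nothing.
    Returns the number of edges added in total.
    """
    cfg = cfg or RunConfig()
    if read_lens is None:
        raise ValueError("read_lens (read id -> length) is required")
    if isinstance(read_lens, ReadSet):
        read_lens = {r.id: r.length for r in read_lens}
    total = 0
    for it in range(1, iterations + 1):
        new_edges = []
        seen = set()
        for shared in sorted(graph.g.nodes):
            nbrs = sorted(graph.neighbors(shared))
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, b = nbrs[i], nbrs[j]
                    if graph.has_edge(a, b) or (a, b) in seen:
                        continue
                    geom = _compose_geometry(
                        a, b, graph.edge(a, shared), graph.edge(b, shared),
                        shared, read_lens[a], read_lens[b], cfg,
                    )
                    if geom is not None:
                        geom["iteration"] = it
                        new_edges.append(geom)
                        seen.add((a, b))
        if not new_edges:
            break
        for geom in new_edges:
            graph.g.add_edge(geom["qid"], geom["tid"], **geom)
        total += len(new_edges)
        logger.info("expansion iteration %d: %d inferred edges", it, len(new_edges))
    return total


def graph_to_records(graph: OverlapGraph, reads: ReadSet,
                     profile: CoverageProfile | None = None) -> list[OverlapRecord]:
    """Export the graph as PAF records, sorted for byte-stable output.

    Column 10 carries the non-redundant matched bases of the skeleton,
    column 11 the overlap span on the query.  Tags: ``cv:f:`` estimated
    coverage of the query read, ``sk:i:`` skeleton score, and for
    inferred edges ``tr:i:`` the expansion iteration that added them.
    """
    records = []
    for u, v, d in sorted(graph.edges(), key=lambda t: (min(t[0], t[1]), max(t[0], t[1]))):
        q = reads[d["qid"]]
        t = reads[d["tid"]]
        block = d["q_end"] - d["q_start"]
        tags = {"sk": int(round(d["score"]))}
        if profile is not None:
            tags["cv"] = round(float(profile.read_cov[q.id]), 3)
        if d.get("inferred"):
            tags["tr"] = int(d["iteration"])
        records.append(OverlapRecord(
            query_name=q.name, query_len=q.length,
            query_start=d["q_start"], query_end=d["q_end"],
            strand="+" if d["strand"] > 0 else "-",
            target_name=t.name, target_len=t.length,
            target_start=d["t_start"], target_end=d["t_end"],
            n_matching_bases=min(int(d["covered"]), block),
            block_len=block, mapq=255, tags=tags,
        ))
    return records
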