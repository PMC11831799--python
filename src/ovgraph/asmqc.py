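"""Read-realignment-based contig misjoin detection and splitting.

Contigs are scanned in tiling 10-kb windows over read-to-contig
alignments (PAF).  Three signatures mark candidate misjoin regions:

* HCR - consecutive windows with mean depth above 3x the dataset depth;
* LCR - consecutive windows with mean depth below 15% of the dataset depth;
* CLIP - a window where more than 60% of its reads carry a large
  (>= 500 bp) clipping on either read end.

Candidates on one contig are merged when closer than 20 kb; merged
regions without a CLIP component are dropped when shorter than 20 kb,
and CLIP-bearing regions within 10 kb of a contig end are dropped as
contig-boundary artifacts.  Verified regions are excised and the contigs
split; fragments shorter than 1 kb are discarded.

A convenience mapper realigns reads to contigs with the same minimizer /
alignment-skeleton machinery used for overlapping, reporting the raw
chained span (no dovetail extension) so that clipped read ends remain
visible to the scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_paf import OverlapRecord, Read, ReadSet, RunConfig
from .seed_index import build_index, extract_minimizer_arrays, query_index
from .skeleton import extract_skeletons

__all__ = [
    "CandidateRegion",
    "DepthTrack",
    "map_reads_to_contigs",
    "scan_windows",
    "merge_filter",
    "split_contigs",
]

WINDOW = 10_000
HCR_FACTOR = 3.0
LCR_FACTOR = 0.15
CLIP_MIN = 500
CLIP_FRACTION = 0.60
MERGE_GAP = 20_000
MIN_REGION = 20_000
END_GUARD = 10_000
MIN_FRAGMENT = 1_000


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate misjoin interval on a contig (0-based half-open)."""

    contig: str
    start: int
    end: int
    kind: str  # "HCR", "LCR", "CLIP" or a "+"-joined combination after merging

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty region")


@dataclass
class DepthTrack:
    """Per-window mean depth of one contig plus the dataset depth."""

    contig: str
    window: int
    mean_depth: np.ndarray
    dataset_depth: float


def map_reads_to_contigs(reads: ReadSet, contigs: ReadSet,
                         cfg: RunConfig | None = None) -> list[OverlapRecord]:
    """Realign reads to contigs; report the best chained span per read.

    Geometry is the unextended chain span, so query bases outside it are
    the clip lengths the misjoin scanner keys on.  No overhang filter is
    applied - heavily clipped alignments are exactly the signal sought.
    """
    cfg = cfg or RunConfig()
    index = build_index(list(contigs), cfg.w_sr, cfg.k, cfg.l, cfg.repeat_occ_cap)
    contig_lens = {c.id: c.length for c in contigs}
    records: list[OverlapRecord] = []
    for read in reads:
        minis = extract_minimizer_arrays(read, cfg.w_sr, cfg.k)
        if len(minis) == 0:
            continue
        matches = query_index(index, minis)
        skeletons = extract_skeletons(read, matches, cfg, contig_lens)
        if not skeletons:
            continue
        best = max(skeletons, key=lambda sk: sk.score)
        contig = contigs[best.seed]
        records.append(OverlapRecord(
            query_name=read.name, query_len=read.length,
            query_start=best.chain_q_start, query_end=best.chain_q_end,
            strand="+" if best.strand > 0 else "-",
            target_name=contig.name, target_len=contig.length,
            target_start=best.chain_s_start, target_end=best.chain_s_end,
            n_matching_bases=best.covered,
            block_len=best.chain_q_end - best.chain_q_start,
            mapq=60, tags={"sk": int(round(best.score))},
        ))
    return records


def _depth_and_clips(records, contig_len: int, window: int):
    n_win = max(1, math.ceil(contig_len / window))
    base_sum = np.zeros(n_win)
    n_reads = np.zeros(n_win, int)
    n_clipped = np.zeros(n_win, int)
    for rec in records:
        t0, t1 = rec.target_start, rec.target_end
        clipped = (rec.query_start >= CLIP_MIN
                   or rec.query_len - rec.query_end >= CLIP_MIN)
        first = t0 // window
        last = min(n_win - 1, (t1 - 1) // window)
        for wi in range(first, last + 1):
            w0, w1 = wi * window, min((wi + 1) * window, contig_len)
            ov = min(t1, w1) - max(t0, w0)
            if ov <= 0:
                continue
            base_sum[wi] += ov
            n_reads[wi] += 1
            if clipped:
                n_clipped[wi] += 1
    w_sizes = np.array([
        min((wi + 1) * window, contig_len) - wi * window for wi in range(n_win)
    ])
    return base_sum / w_sizes, n_reads, n_clipped


def scan_windows(records: list[OverlapRecord], contigs: ReadSet,
                 window: int = WINDOW, dataset_depth: float | None = None
                 ) -> tuple[list[CandidateRegion], list[DepthTrack]]:
    """Tile contigs into windows and call HCR/LCR/CLIP candidates.

    ``dataset_depth`` is the sequencing depth D of the whole dataset; it
    must be positive.
    """
    if dataset_depth is None or dataset_depth <= 0:
        raise ValueError("dataset_depth must be a positive sequencing depth")
    by_contig: dict = {c.name: [] for c in contigs}
    for rec in records:
        if rec.target_name in by_contig:
            by_contig[rec.target_name].append(rec)
    regions: list[CandidateRegion] = []
    tracks: list[DepthTrack] = []
    for contig in contigs:
        depth, n_reads, n_clipped = _depth_and_clips(
            by_contig[contig.name], contig.length, window
        )
        tracks.append(DepthTrack(contig.name, window, depth, dataset_depth))
        n_win = len(depth)

        def _runs(mask):
            out = []
            start = None
            for wi in range(n_win):
                if mask[wi] and start is None:
                    start = wi
                elif not mask[wi] and start is not None:
                    out.append((start, wi))
                    start = None
            if start is not None:
                out.append((start, n_win))
            return out

        for w0, w1 in _runs(depth > HCR_FACTOR * dataset_depth):
            regions.append(CandidateRegion(
                contig.name, w0 * window, min(w1 * window, contig.length), "HCR"))
        for w0, w1 in _runs(depth < LCR_FACTOR * dataset_depth):
            regions.append(CandidateRegion(
                contig.name, w0 * window, min(w1 * window, contig.length), "LCR"))
        clip_mask = np.zeros(n_win, bool)
        for wi in range(n_win):
            if n_reads[wi] > 0 and n_clipped[wi] / n_reads[wi] > CLIP_FRACTION:
                clip_mask[wi] = True
        for w0, w1 in _runs(clip_mask):
            regions.append(CandidateRegion(
                contig.name, w0 * window, min(w1 * window, contig.length), "CLIP"))
    regions.sort(key=lambda r: (r.contig, r.start, r.end, r.kind))
    return regions, tracks


def merge_filter(regions: list[CandidateRegion],
                 contig_lens: dict) -> list[CandidateRegion]:
    """Merge nearby candidates and drop implausible ones.

    Regions on one contig closer than 20 kb merge into one (kinds joined
    with "+").  Merged regions without a CLIP component shorter than
    20 kb are dropped; CLIP-bearing regions within 10 kb of a contig end
    are dropped as boundary artifacts.
    """
    verified: list[CandidateRegion] = []
    by_contig: dict = {}
    for r in sorted(regions, key=lambda r: (r.contig, r.start, r.end)):
        by_contig.setdefault(r.contig, []).append(r)
    for contig, regs in sorted(by_contig.items()):
        clen = contig_lens[contig]
        merged: list[list] = []
        for r in regs:
            if merged and r.start - merged[-1][1] <= MERGE_GAP:
                merged[-1][1] = max(merged[-1][1], r.end)
                merged[-1][2].update(r.kind.split("+"))
            else:
                merged.append([r.start, r.end, set(r.kind.split("+"))])
        for start, end, kinds in merged:
            has_clip = "CLIP" in kinds
            if not has_clip and end - start < MIN_REGION:
                continue
            if has_clip and (start < END_GUARD or end > clen - END_GUARD):
                continue
            verified.append(CandidateRegion(
                contig, start, end, "+".join(sorted(kinds))))
    return verified


def split_contigs(contigs: ReadSet,
                  verified: list[CandidateRegion]) -> list[Read]:
    """Excise verified regions and split; fragments < 1 kb are dropped.

    Fragment names get a ``_partN`` suffix (1-based); contigs without
    regions pass through unchanged under their original name.
    """
    by_contig: dict = {}
    for r in verified:
        by_contig.setdefault(r.contig, []).append((r.start, r.end))
    out: list[Read] = []
    next_id = 0
    for contig in contigs:
        cuts = sorted(by_contig.get(contig.name, []))
        if not cuts:
            out.append(Read(next_id, contig.name, contig.seq))
            next_id += 1
            continue
        pieces = []
        pos = 0
        for s, e in cuts:
            if s > pos:
                pieces.append(contig.seq[pos:s])
            pos = max(pos, e)
        if pos < contig.length:
            pieces.append(contig.seq[pos:])
        part = 0
        for piece in pieces:
            if len(piece) < MIN_FRAGMENT:
                continue
            part += 1
            out.append(Read(next_id, f"{contig.name}_part{part}", piece))
            next_id += 1
    return out
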