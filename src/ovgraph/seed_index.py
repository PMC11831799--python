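"""Seed-read selection and the minimizer index over the current seed batch.

Seed reads form a "virtual reference": the first iteration takes the
longest reads, later iterations sample from reads whose estimated coverage
is still below the adaptive threshold.  A minimizer is the canonical k-mer
of minimum hash value within each window of ``w`` consecutive k-mer start
positions, stored as the quadruple (hash value, read id, position, strand).
Records of one seed batch are sorted by value; an auxiliary bucket table
keyed by the top ``2*l`` bits of the value (an l-mer-sized prefix) narrows
the binary search.  Values occurring more than ``repeat_occ_cap`` times are
flagged repetitive and skipped at query time unless explicitly requested
(the repeat-rescue path retrieves them).

All extraction is vectorized: sequences are 2-bit encoded, forward and
reverse-complement k-mer codes built by shift-or passes, the canonical
(lexicographically smaller) code hashed with an invertible 64-bit mixer,
and per-window minima taken with a sliding-window argmin.  K-mers touching
an N are invalid and never selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .io_paf import Read, ReadSet

__all__ = [
    "MinimizerRecord",
    "MinimizerIndex",
    "CoverageState",
    "extract_minimizers",
    "extract_minimizer_arrays",
    "build_index",
    "query_index",
    "select_seeds_initial",
    "select_seeds_iter",
    "splitmix64",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i

_U64 = np.uint64
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


def splitmix64(x):
    """The splitmix64 finalizer: an invertible 64-bit integer mixer."""
    x = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = (x + _U64(0x9E3779B97F4A7C15)) & _SENTINEL
        x = ((x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _SENTINEL
        x = ((x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)) & _SENTINEL
        x = x ^ (x >> _U64(31))
    return x


class MinimizerRecord(NamedTuple):
    """One minimizer: hash value, read id, k-mer start position, strand."""

    v: int
    r: int
    p: int
    s: str  # '+' if the forward k-mer is canonical, '-' otherwise


@dataclass
class _MiniArrays:
    """Column-oriented minimizers of one read (internal fast path)."""

    code: np.ndarray   # canonical 2-bit k-mer codes, uint64
    v: np.ndarray      # mixed hash values, uint64
    p: np.ndarray      # k-mer start positions, int64
    s: np.ndarray      # +1 forward-canonical, -1 reverse-canonical, int8

    def __len__(self) -> int:
        return len(self.p)


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward code, reverse-complement code and validity per k-mer start."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    invalid = (codes >= 4).astype(np.int32)
    bad = np.cumsum(invalid)
    ok = (bad[k - 1:] - np.concatenate(([0], bad[:-k]))) == 0
    c = np.where(codes >= 4, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << _U64(2)) | c[j:j + n]
            rev |= (_U64(3) - c[j:j + n]) << _U64(2 * j)
    return fwd, rev, ok


def _minimizer_arrays(seq: str, w: int, k: int) -> _MiniArrays:
    empty = _MiniArrays(
        np.empty(0, np.uint64), np.empty(0, np.uint64),
        np.empty(0, np.int64), np.empty(0, np.int8),
    )
    if len(seq) < k:
        return empty
    fwd, rev, ok = _kmer_codes(seq, k)
    canon = np.minimum(fwd, rev)
    strand = np.where(fwd <= rev, np.int8(1), np.int8(-1))
    h = splitmix64(canon)
    h[~ok] = _SENTINEL
    n = len(h)
    if n >= w:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
        picks = np.arange(n - w + 1) + win.argmin(axis=1)
    else:
        picks = np.array([int(h.argmin())])
    pos = np.unique(picks)
    pos = pos[h[pos] != _SENTINEL]
    return _MiniArrays(canon[pos], h[pos], pos.astype(np.int64), strand[pos])


def extract_minimizer_arrays(read: Read, w: int = 5, k: int = 15) -> _MiniArrays:
    return _minimizer_arrays(read.seq, w, k)


def extract_minimizers(read: Read, w: int = 5, k: int = 15) -> list[MinimizerRecord]:
    """Minimizers of one read as (value, read, position, strand) quadruples.

    Each window of ``w`` consecutive k-mer start positions contributes the
    position of its minimum-hash canonical k-mer (leftmost on ties);
    adjacent windows agreeing on the position collapse to one record.
    """
    arr = _minimizer_arrays(read.seq, w, k)
    return [
        MinimizerRecord(int(v), read.id, int(p), "+" if s > 0 else "-")
        for v, p, s in zip(arr.v, arr.p, arr.s)
    ]


@dataclass
class MinimizerIndex:
    """Sorted minimizer records of one seed batch plus the bucket table."""

    w: int
    k: int
    l: int
    repeat_occ_cap: int
    code: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    v: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    r: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    p: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    s: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    repetitive: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    buckets: dict = field(default_factory=dict)
    repetitive_values: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.v)

    def occ(self, value: int) -> int:
        lo = np.searchsorted(self.v, np.uint64(value), side="left")
        hi = np.searchsorted(self.v, np.uint64(value), side="right")
        return int(hi - lo)

    def lookup(self, value: int) -> tuple[int, int]:
        """Record range [lo, hi) for one hash value, via the bucket table."""
        value = np.uint64(value)
        key = int(value >> _U64(64 - 2 * self.l))
        rng = self.buckets.get(key)
        if rng is None:
            return (0, 0)
        lo, hi = rng
        lo = lo + int(np.searchsorted(self.v[lo:hi], value, side="left"))
        hi = lo + int(np.searchsorted(self.v[lo:hi], value, side="right"))
        return (lo, hi)


def build_index(
    seed_reads: Iterable[Read],
    w: int = 5,
    k: int = 15,
    l: int = 11,
    repeat_occ_cap: int = 500,
) -> MinimizerIndex:
    """Index the minimizers of a seed batch, sorted by hash value."""
    codes, vs, rs, ps, ss = [], [], [], [], []
    for read in seed_reads:
        arr = _minimizer_arrays(read.seq, w, k)
        codes.append(arr.code)
        vs.append(arr.v)
        rs.append(np.full(len(arr), read.id, dtype=np.int64))
        ps.append(arr.p)
        ss.append(arr.s)
    if not vs:
        raise ValueError("cannot build an index from an empty seed set")
    code = np.concatenate(codes)
    v = np.concatenate(vs)
    r = np.concatenate(rs)
    p = np.concatenate(ps)
    s = np.concatenate(ss)
    order = np.lexsort((p, r, v))
    code, v, r, p, s = code[order], v[order], r[order], p[order], s[order]
    # dedupe exact (v, r, p, s) duplicates from overlapping windows
    if len(v):
        keep = np.ones(len(v), bool)
        keep[1:] = (
            (v[1:] != v[:-1]) | (r[1:] != r[:-1]) | (p[1:] != p[:-1]) | (s[1:] != s[:-1])
        )
        code, v, r, p, s = code[keep], v[keep], r[keep], p[keep], s[keep]
    uniq, starts, counts = np.unique(v, return_index=True, return_counts=True)
    repetitive = np.zeros(len(v), bool)
    rep_vals = uniq[counts > repeat_occ_cap]
    for val in rep_vals:
        lo = np.searchsorted(v, val, side="left")
        hi = np.searchsorted(v, val, side="right")
        repetitive[lo:hi] = True
    keys = (v >> _U64(64 - 2 * l)).astype(np.uint64)
    buckets = {}
    if len(keys):
        boundaries = np.flatnonzero(np.concatenate(([True], keys[1:] != keys[:-1])))
        ends = np.concatenate((boundaries[1:], [len(keys)]))
        for b, e in zip(boundaries, ends):
            buckets[int(keys[b])] = (int(b), int(e))
    return MinimizerIndex(
        w=w, k=k, l=l, repeat_occ_cap=repeat_occ_cap,
        code=code, v=v, r=r, p=p, s=s,
        repetitive=repetitive, buckets=buckets,
        repetitive_values={int(x) for x in rep_vals},
    )


class MatchArrays(NamedTuple):
    """Minimizer matches between one query and the indexed seeds."""

    q_p: np.ndarray      # query k-mer start positions
    seed: np.ndarray     # seed read ids
    s_p: np.ndarray      # seed k-mer start positions
    strand: np.ndarray   # relative strand: +1 same, -1 opposite


def query_index(
    index: MinimizerIndex,
    query_minis: _MiniArrays,
    include_repetitive: bool = False,
    restrict_values: set | None = None,
    exclude_read: int | None = None,
) -> MatchArrays:
    """All (query minimizer, seed minimizer) pairs with equal hash value.

    Repetitive values are skipped unless ``include_repetitive``; the
    relative strand of a match is the product of the two strand fields.
    ``restrict_values`` limits matching to the given hash values (used by
    the repeat-rescue path); ``exclude_read`` drops self matches.
    """
    qp_out, seed_out, sp_out, st_out = [], [], [], []
    lo = np.searchsorted(index.v, query_minis.v, side="left")
    hi = np.searchsorted(index.v, query_minis.v, side="right")
    for i in range(len(query_minis)):
        a, b = int(lo[i]), int(hi[i])
        if a == b:
            continue
        val = int(query_minis.v[i])
        if restrict_values is not None and val not in restrict_values:
            continue
        if not include_repetitive and index.repetitive[a]:
            continue
        sl = slice(a, b)
        seeds = index.r[sl]
        mask = np.ones(b - a, bool)
        if exclude_read is not None:
            mask &= seeds != exclude_read
        if not mask.any():
            continue
        n = int(mask.sum())
        qp_out.append(np.full(n, query_minis.p[i]))
        seed_out.append(seeds[mask])
        sp_out.append(index.p[sl][mask])
        st_out.append((index.s[sl][mask] * query_minis.s[i]).astype(np.int8))
    if not qp_out:
        z = np.empty(0, np.int64)
        return MatchArrays(z, z.copy(), z.copy(), np.empty(0, np.int8))
    return MatchArrays(
        np.concatenate(qp_out).astype(np.int64),
        np.concatenate(seed_out).astype(np.int64),
        np.concatenate(sp_out).astype(np.int64),
        np.concatenate(st_out),
    )


@dataclass
class CoverageState:
    """Mutable bookkeeping of the iterative construction."""

    n_reads: int
    coverage: np.ndarray = None
    iteration: int = 0
    used_seeds: set = field(default_factory=set)

    def __post_init__(self):
        if self.coverage is None:
            self.coverage = np.zeros(self.n_reads, dtype=float)


def _cap_to_budget(ordered_ids, reads: ReadSet, batch_bases: int) -> list[int]:
    """Take reads in selection order until the base budget binds."""
    out, total = [], 0
    for rid in ordered_ids:
        length = reads[rid].length
        if out and total + length > batch_bases:
            break
        out.append(rid)
        total += length
    return out


def low_covered(coverage: float, t_rc: float) -> bool:
    """Is a read low-covered under threshold t_rc (zero-median safe)?"""
    return coverage < t_rc or (t_rc == 0 and coverage == 0)


def select_seeds_initial(reads: ReadSet, p0: float = 0.03,
                         batch_bases: int | None = None) -> list[int]:
    """The ceil(p0*N) longest reads; length ties broken by smaller id."""
    if len(reads) == 0:
        raise ValueError("empty ReadSet")
    n_pick = math.ceil(p0 * len(reads))
    order = sorted(range(len(reads)), key=lambda i: (-reads[i].length, i))
    picked = order[:n_pick]
    if batch_bases is not None:
        picked = _cap_to_budget(picked, reads, batch_bases)
    return sorted(picked)


def select_seeds_iter(
    state: CoverageState,
    reads: ReadSet,
    ps: float,
    t_rc: float,
    rng: np.random.Generator,
    batch_bases: int | None = None,
) -> list[int]:
    """A uniform sample of ceil(ps*|eligible|) never-seeded low-covered reads.

    With a degenerate threshold (t_rc == 0, i.e. the median coverage is
    still zero) the zero-coverage reads themselves count as low-covered,
    so the construction can bootstrap past an almost-empty first graph.
    """
    eligible = [
        i for i in range(len(reads))
        if low_covered(state.coverage[i], t_rc) and i not in state.used_seeds
    ]
    if not eligible:
        return []
    n_pick = math.ceil(ps * len(eligible))
    picked = list(rng.choice(len(eligible), size=n_pick, replace=False))
    picked = [eligible[int(j)] for j in sorted(picked)]
    if batch_bases is not None:
        picked = _cap_to_budget(picked, reads, batch_bases)
    return sorted(picked)
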