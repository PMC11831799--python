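"""Synthetic genome and long-read simulation with exact ground truth.

The generator emulates the shape of a PBSIM-style long-read experiment:
reads start uniformly along a random (optionally repeat-bearing) genome,
lengths follow a truncated normal, roughly half are reverse-complemented,
and sequencing errors are applied per base with a configurable
mismatch:insertion:deletion ratio.  The defaults mirror a noisy nanopore
run: 50x depth, 13 kb mean length, 13% error split 23:31:46 between
mismatches, insertions and deletions.

Every read carries an exact genome placement, from which true overlaps
(pairs of reads whose placements intersect by more than ``min_len`` bases)
are derived for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_paf import Read, ReadSet, revcomp

__all__ = [
    "SyntheticGenome",
    "TruePlacement",
    "random_genome",
    "sample_reads",
    "truth_overlaps",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.array(list("ACGT"))
MIN_READ_LEN = 500

DEFAULT_DEPTH = 50.0
DEFAULT_MEAN_LEN = 13_000
DEFAULT_LEN_SD = 2_600
DEFAULT_ERR_RATE = 0.13
DEFAULT_ERR_RATIO = (23, 31, 46)  # mismatch : insertion : deletion


@dataclass
class SyntheticGenome:
    """A random genome with optional planted approximate repeats.

    ``repeat_annotations`` lists (source_interval, dest_interval, identity)
    triples, intervals 0-based half-open on the genome.
    """

    seq: str
    repeat_annotations: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TruePlacement:
    """The genome interval a simulated read was sampled from."""

    read_id: int
    ref_start: int
    ref_end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.ref_start < self.ref_end:
            raise ValueError("bad placement interval")


def random_genome(length, gc=0.5, repeat_spec=(), seed=0) -> SyntheticGenome:
    """Generate an i.i.d. background genome with planted repeat copies.

    ``repeat_spec`` is a list of (copy_len, n_copies, divergence): a random
    source segment is copied ``n_copies - 1`` extra times to random
    positions, each copy mutated at the per-base ``divergence`` rate.
    Deterministic given ``seed``.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    annotations = []
    for copy_len, n_copies, divergence in repeat_spec:
        if copy_len > length:
            raise ValueError(f"repeat length {copy_len} exceeds genome {length}")
        src = int(rng.integers(0, length - copy_len + 1))
        src_iv = (src, src + copy_len)
        for _ in range(max(n_copies - 1, 0)):
            # keep the destination clear of the source so the copy cannot
            # overwrite (part of) its own template
            dst = src
            while abs(dst - src) < copy_len:
                dst = int(rng.integers(0, length - copy_len + 1))
            copy = codes[src:src + copy_len].copy()
            if divergence > 0:
                mut = rng.random(copy_len) < divergence
                copy[mut] = (copy[mut] + rng.integers(1, 4, mut.sum())) % 4
            codes[dst:dst + copy_len] = copy
            annotations.append((src_iv, (dst, dst + copy_len), 1.0 - divergence))
    return SyntheticGenome("".join(_BASES[codes]), annotations)


def _mutate(seq: str, err_rate: float, err_ratio, rng,
            stats: dict | None = None) -> str:
    """Apply per-base errors with the given mismatch:ins:del weight triple."""
    if err_rate <= 0:
        return seq
    weights = np.asarray(err_ratio, dtype=float)
    if weights.min() < 0 or weights.sum() <= 0:
        raise ValueError("err_ratio must be nonnegative with positive sum")
    weights = weights / weights.sum()
    n = len(seq)
    is_err = rng.random(n) < err_rate
    idx = np.flatnonzero(is_err)
    if idx.size == 0:
        return seq
    kinds = rng.choice(3, size=idx.size, p=weights)  # 0 mm, 1 ins, 2 del
    if stats is not None:
        stats["n_mismatch"] = stats.get("n_mismatch", 0) + int((kinds == 0).sum())
        stats["n_ins"] = stats.get("n_ins", 0) + int((kinds == 1).sum())
        stats["n_del"] = stats.get("n_del", 0) + int((kinds == 2).sum())
    out = []
    prev = 0
    base_codes = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
    for pos, kind in zip(idx, kinds):
        out.append(seq[prev:pos])
        if kind == 0:  # mismatch: any other base
            c = base_codes[seq[pos]]
            out.append(_BASES[(c + rng.integers(1, 4)) % 4])
            prev = pos + 1
        elif kind == 1:  # insertion before the current base
            out.append(_BASES[rng.integers(0, 4)])
            prev = pos
        else:  # deletion
            prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)


def sample_reads(
    genome: SyntheticGenome,
    depth: float = DEFAULT_DEPTH,
    mean_len: float = DEFAULT_MEAN_LEN,
    len_sd: float = DEFAULT_LEN_SD,
    err_rate: float = DEFAULT_ERR_RATE,
    err_ratio=DEFAULT_ERR_RATIO,
    seed: int = 0,
    stats: dict | None = None,
) -> tuple[ReadSet, list[TruePlacement]]:
    """Sample reads to the target depth with exact placements recorded.

    Start positions are uniform along the genome, with reads allowed to
    run off either end and clipped back to it (keeping at least 500 bp),
    so coverage is flat up to the genome boundaries.  Lengths are
    truncated normal (minimum 500 bp), half the reads are
    reverse-complemented.  Errors are applied to the read sequence after
    orientation; the recorded placement is always on the forward genome
    strand.  When a ``stats`` dict is passed it accumulates the applied
    per-type error counts and the template base total.
    """
    glen = len(genome)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if mean_len > glen:
        raise ValueError(f"mean read length {mean_len} exceeds genome length {glen}")
    rng = np.random.default_rng(seed)
    target = depth * glen
    reads: list[Read] = []
    placements: list[TruePlacement] = []
    sampled = 0
    i = 0
    while sampled < target:
        length = int(round(rng.normal(mean_len, len_sd)))
        length = max(MIN_READ_LEN, min(length, glen))
        # uniform start with end clipping: offset may be negative or run
        # past the genome, the placement keeps >= MIN_READ_LEN bases
        offset = int(rng.integers(-(length - MIN_READ_LEN), glen - MIN_READ_LEN + 1))
        start = max(0, offset)
        end = min(glen, offset + length)
        length = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        frag = genome.seq[start:start + length]
        if strand == "-":
            frag = revcomp(frag)
        seq = _mutate(frag, err_rate, err_ratio, rng, stats)
        if stats is not None:
            stats["n_template_bases"] = stats.get("n_template_bases", 0) + length
        reads.append(Read(i, f"read{i}", seq))
        placements.append(TruePlacement(i, start, start + length, strand))
        sampled += length
        i += 1
    return ReadSet(reads), placements


def truth_overlaps(placements, min_len: int = 500) -> set[tuple[int, int, int]]:
    """Unordered read pairs whose placements intersect by more than min_len.

    Returns (read_a, read_b, overlap_length) triples with read_a < read_b.
    Uses a start-sorted sweep; equivalent to the quadratic all-pairs check.
    """
    ivs = sorted(
        ((p.ref_start, p.ref_end, p.read_id) for p in placements), key=lambda t: (t[0], t[1], t[2])
    )
    out: set[tuple[int, int, int]] = set()
    for idx, (s, e, rid) in enumerate(ivs):
        for s2, e2, rid2 in ivs[idx + 1:]:
            if s2 >= e - min_len:
                break
            ov = min(e, e2) - s2
            if ov > min_len and rid != rid2:
                a, b = (rid, rid2) if rid < rid2 else (rid2, rid)
                out.add((a, b, ov))
    return out


def write_truth_tsv(reads: ReadSet, placements, path: str) -> None:
    """Write placements as TSV: read_name, ref_start, ref_end, strand."""
    with open(path, "wt") as fh:
        for p in placements:
            fh.write(f"{reads[p.read_id].name}\t{p.ref_start}\t{p.ref_end}\t{p.strand}\n")


def read_truth_tsv(path: str, reads: ReadSet) -> list[TruePlacement]:
    placements = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip():
                continue
            name, s, e, strand = raw.rstrip("\n").split("\t")
            placements.append(TruePlacement(reads.by_name(name).id, int(s), int(e), strand))
    return placements
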