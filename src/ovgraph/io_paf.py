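"""Sequence and PAF input/output plus the run configuration.

Reads are held in memory as plain strings with dense integer ids assigned
in input order.  Overlaps travel as PAF records: 12 mandatory tab-separated
columns followed by typed tags.  All coordinates are 0-based half-open on
the forward strand of each read, per the PAF convention.  Two tags are
given special meaning here: ``cv:f:`` carries the estimated sequencing
coverage of the query read and ``sk:i:`` the chaining score of the
alignment skeleton that produced the overlap.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Read",
    "ReadSet",
    "OverlapRecord",
    "RunConfig",
    "PafParseError",
    "read_sequences",
    "write_paf",
    "parse_paf",
    "load_config",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# anything outside the 5-letter alphabet collapses to N
_NORMALIZE = {c: c for c in "ACGTN"}


def _clean_seq(seq: str) -> str:
    up = seq.upper()
    if all(c in _NORMALIZE for c in up):
        return up
    return "".join(c if c in _NORMALIZE else "N" for c in up)


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A single input sequence with a dense, input-ordered integer id."""

    id: int
    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


class ReadSet:
    """An ordered, id-addressable collection of reads.

    Ids are dense (0..n-1) and assigned in input order, so a ReadSet is
    usable as both a list and a lookup table.
    """

    def __init__(self, reads: Iterable[Read] = ()):  # noqa: D107
        self._reads: list[Read] = list(reads)
        for i, r in enumerate(self._reads):
            if r.id != i:
                raise ValueError(f"read ids must be dense; got id {r.id} at index {i}")
        self._by_name = {r.name: r for r in self._reads}
        if len(self._by_name) != len(self._reads):
            raise ValueError("duplicate read names in ReadSet")

    def __len__(self) -> int:
        return len(self._reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self._reads)

    def __getitem__(self, read_id: int) -> Read:
        return self._reads[read_id]

    def by_name(self, name: str) -> Read:
        return self._by_name[name]

    def total_bases(self) -> int:
        return sum(r.length for r in self._reads)

    @classmethod
    def from_sequences(cls, named_seqs: Iterable[tuple[str, str]]) -> "ReadSet":
        return cls(
            Read(i, name, _clean_seq(seq)) for i, (name, seq) in enumerate(named_seqs)
        )


class PafParseError(ValueError):
    """A malformed PAF line or sequence record."""


def _open_maybe_gzip(path: str):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _sniff_format(handle) -> str | None:
    pos = handle.tell()
    first = handle.read(1)
    while first and first.isspace():
        first = handle.read(1)
    handle.seek(pos)
    if not first:
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise PafParseError(f"unrecognized sequence file start: {first!r}")


def read_sequences(path: str) -> ReadSet:
    """Read FASTA or FASTQ (optionally gzip-compressed) into a ReadSet.

    Lowercase bases are uppercased and any character outside ACGTN is
    mapped to N.  Record order defines read ids.
    """
    handle = _open_maybe_gzip(str(path))
    try:
        fmt = _sniff_format(handle)
        if fmt is None:
            return ReadSet()
        reads = []
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                reads.append(Read(i, rec.id, _clean_seq(str(rec.seq))))
        except ValueError as exc:
            raise PafParseError(
                f"malformed {fmt} record at index {len(reads)} in {path}: {exc}"
            ) from exc
    finally:
        handle.close()
    return ReadSet(reads)


def write_fasta(reads: Iterable[Read], path: str) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.name}\n{r.seq}\n")


@dataclass
class OverlapRecord:
    """One PAF line: a pairwise overlap/mapping between two sequences."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_matching_bases: int
    block_len: int
    mapq: int
    tags: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"bad query interval {self.query_start}-{self.query_end} "
                f"(len {self.query_len}) for {self.query_name}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"bad target interval {self.target_start}-{self.target_end} "
                f"(len {self.target_len}) for {self.target_name}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.block_len >= self.n_matching_bases >= 0):
            raise ValueError(
                f"block_len {self.block_len} < n_matching {self.n_matching_bases}"
            )

    def pair(self) -> tuple[str, str]:
        """The unordered read-name pair this record connects."""
        a, b = self.query_name, self.target_name
        return (a, b) if a <= b else (b, a)


_TAG_TYPES = {"i": int, "f": float, "A": str, "Z": str}


def _format_tag(key: str, value) -> str:
    if isinstance(value, bool):
        raise ValueError("boolean PAF tags are not supported")
    if isinstance(value, int):
        return f"{key}:i:{value}"
    if isinstance(value, float):
        return f"{key}:f:{value:g}"
    return f"{key}:Z:{value}"


def write_paf(records: Iterable[OverlapRecord], path: str) -> None:
    """Write records as PAF; refuses to write a record violating invariants."""
    with open(path, "wt") as fh:
        for i, rec in enumerate(records):
            try:
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"refusing to write PAF record {i}: {exc}") from exc
            cols = [
                rec.query_name,
                rec.query_len,
                rec.query_start,
                rec.query_end,
                rec.strand,
                rec.target_name,
                rec.target_len,
                rec.target_start,
                rec.target_end,
                rec.n_matching_bases,
                rec.block_len,
                rec.mapq,
            ]
            line = "\t".join(str(c) for c in cols)
            for key in sorted(rec.tags):
                line += "\t" + _format_tag(key, rec.tags[key])
            fh.write(line + "\n")


def parse_paf(path: str, strict: bool = True) -> list[OverlapRecord]:
    """Parse a PAF file; unknown tags are preserved.

    With ``strict=False`` malformed lines are collected and reported in a
    single summary error only if *all* lines fail; otherwise they are
    attached to the returned list as ``parse_paf.errors`` style side data.
    The default raises on the first malformed line with its line number.
    """
    records: list[OverlapRecord] = []
    errors: list[tuple[int, str]] = []
    with _open_maybe_gzip(str(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                msg = f"line {lineno}: expected >=12 columns, got {len(fields)}"
                if strict:
                    raise PafParseError(msg)
                errors.append((lineno, msg))
                continue
            try:
                rec = OverlapRecord(
                    query_name=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_name=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    n_matching_bases=int(fields[9]),
                    block_len=int(fields[10]),
                    mapq=int(fields[11]),
                )
            except ValueError as exc:
                msg = f"line {lineno}: non-integer coordinate field ({exc})"
                if strict:
                    raise PafParseError(msg) from exc
                errors.append((lineno, msg))
                continue
            for tag in fields[12:]:
                parts = tag.split(":", 2)
                if len(parts) != 3:
                    continue
                key, typ, val = parts
                conv = _TAG_TYPES.get(typ, str)
                try:
                    rec.tags[key] = conv(val)
                except ValueError:
                    rec.tags[key] = val
            records.append(rec)
    if not strict:
        return records, errors
    return records


@dataclass
class RunConfig:
    """All tunables of the overlap-graph construction pipeline.

    Percent-style parameters (``p0``, ``ps``) are stored as fractions of 1.
    Length thresholds are in base pairs.
    """

    p0: float = 0.03            # fraction of longest reads seeding iteration 1
    ps: float = 0.10            # fraction of eligible low-covered reads per later iteration
    w_sr: int = 5               # minimizer window: consecutive k-mer start positions
    k: int = 15                 # k-mer length
    l: int = 11                 # auxiliary bucket-key length (l-mer sized prefix)
    delta: float = 0.25         # max relative gap-length difference when chaining
    t_om: int = 500             # min implied overlap length of a kept overlap
    t_nb: int = 100             # min non-redundant matched bases of a kept overlap
    t_oh: int = 2000            # max overhang on either read of a kept overlap
    n_as: int = 2               # overlaps kept per query (highest scored)
    w_rc: int = 1000            # coverage-estimation window size
    p_rc: float = 0.5           # low-coverage threshold as a fraction of the median
    repeat_occ_cap: int = 500   # minimizer multiplicity above which a value is repetitive
    min_skeleton_score: int = 30  # stop chaining when the best score drops below this
    stop_fraction: float = 0.002  # stop when new seeds < this fraction of all reads
    batch_bases: int = 4_000_000_000  # seed-sequence budget per iteration (RAM control)
    rng_seed: int = 0
    # chaining cost model
    max_gap: int = 100          # per-step diagonal drift tolerated inside a match block
    gap_open: float = 0.3       # penalty per base of diagonal drift between blocks
    gap_extend: float = 0.01    # penalty per base of in-diagonal gap between blocks
    # repeat rescue
    rescue_factor: float = 3.0  # rescue skeletons scoring below factor*min_skeleton_score
    rescue_band: int = 500      # diagonal band (bp) for re-searching repetitive minimizers
    rescue_min_repetitive: int = 5
    max_iterations: int = 30

    def validate(self) -> None:
        if not self.k > self.l:
            raise ValueError(f"k ({self.k}) must exceed l ({self.l})")
        if not 0 < self.p_rc <= 1:
            raise ValueError(f"p_rc must be in (0, 1], got {self.p_rc}")
        for name in ("t_om", "t_nb", "t_oh", "w_rc", "w_sr", "max_gap", "rescue_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.p0 <= 1 or not 0 < self.ps <= 1:
            raise ValueError("p0 and ps must be fractions in (0, 1]")

    def updated(self, **kwargs) -> "RunConfig":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


_INT_FIELDS = {
    "w_sr", "k", "l", "t_om", "t_nb", "t_oh", "n_as", "w_rc",
    "repeat_occ_cap", "min_skeleton_score", "batch_bases", "rng_seed",
    "max_gap", "rescue_band", "rescue_min_repetitive", "max_iterations",
}


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a flat ``key=value`` text file plus overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in RunConfig.__dataclass_fields__:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                values[key] = int(val) if key in _INT_FIELDS else float(val)
    values.update(overrides)
    cfg = RunConfig(**values)
    cfg.validate()
    return cfg
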