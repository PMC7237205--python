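"""Genomic interval algebra: BED I/O, anchor merging, blacklist subtraction,
and multi-set membership tables.

All coordinates are 0-based half-open (BED convention). 1-based inputs must be
converted at the boundary before construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "AnchorSet",
    "MembershipTable",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "merge_cluster_recenter",
    "subtract_blacklist",
    "membership",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval` with an optional genome
    declaration (``chrom -> length``).

    Intervals are kept sorted by ``(chrom, start, end)``. When a genome is
    declared, chroms must be known and ends must not exceed chrom lengths.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.genome: Optional[Dict[str, int]] = dict(genome) if genome is not None else None
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if self.genome is not None:
            for iv in ivs:
                if iv.chrom not in self.genome:
                    raise ValueError(f"chrom {iv.chrom!r} not in declared genome")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval end {iv.end} exceeds length of {iv.chrom} "
                        f"({self.genome[iv.chrom]})"
                    )
        self._intervals: List[GenomicInterval] = ivs
        # per-chrom start/end arrays for the sorted-sweep overlap queries
        self._index: Dict[str, tuple] = {}
        for iv in ivs:
            self._index.setdefault(iv.chrom, ([], []))
            s, e = self._index[iv.chrom]
            s.append(iv.start)
            e.append(iv.end)
        self._index = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in self._index.items()
        }

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "name": [iv.name for iv in self],
                "score": [iv.score for iv in self],
                "strand": [iv.strand for iv in self],
            }
        )

    def merged(self) -> "IntervalSet":
        """Union of the set: overlapping or bookended intervals collapsed."""
        out: List[GenomicInterval] = []
        for iv in self._intervals:
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                prev = out.pop()
                out.append(GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)))
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(out, genome=self.genome)

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bp of ``[start, end)`` covered by the (merged) set."""
        if chrom not in self._index:
            return 0
        starts, ends = self._merged_index(chrom)
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())

    def _merged_index(self, chrom: str):
        if not hasattr(self, "_merged_cache"):
            self._merged_cache: Dict[str, tuple] = {}
        if chrom not in self._merged_cache:
            starts, ends = self._index[chrom]
            ms, me = [], []
            for s, e in zip(starts, ends):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            self._merged_cache[chrom] = (
                np.asarray(ms, dtype=np.int64),
                np.asarray(me, dtype=np.int64),
            )
        return self._merged_cache[chrom]


@dataclass
class AnchorSet:
    """Point anchors ``(chrom, position, strand)`` — e.g. motif centers or
    merged TSS positions."""

    chroms: List[str] = field(default_factory=list)
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    strands: List[str] = field(default_factory=list)
    genome: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not self.strands:
            self.strands = ["."] * len(self.chroms)
        if not (len(self.chroms) == len(self.positions) == len(self.strands)):
            raise ValueError("chroms, positions, strands must have equal length")
        if (self.positions < 0).any():
            raise ValueError("negative anchor position")
        if self.genome is not None:
            for c, p in zip(self.chroms, self.positions):
                if c not in self.genome:
                    raise ValueError(f"chrom {c!r} not in declared genome")
                if p >= self.genome[c]:
                    raise ValueError(f"anchor {p} beyond end of {c}")

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self):
        return iter(zip(self.chroms, self.positions, self.strands))


@dataclass
class MembershipTable:
    """One boolean row per query interval, one column per named reference set,
    plus combination counts and per-reference overlap fractions."""

    table: pd.DataFrame
    combination_counts: pd.Series
    fractions: pd.Series

    def __post_init__(self) -> None:
        assert int(self.combination_counts.sum()) == len(self.table)


# ---------------------------------------------------------------------------
# BED / chrom-sizes I/O


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column ``chrom<TAB>length`` file -> genome declaration dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed(
    path,
    dialect: str = "BED6",
    genome: Optional[Mapping[str, int]] = None,
    skip_unknown: bool = False,
) -> IntervalSet:
    """Read a BED3 or BED6 file into an :class:`IntervalSet`.

    Lines with ``start >= end`` raise; intervals on chroms absent from a
    declared genome raise unless ``skip_unknown``.
    """
    if dialect not in ("BED3", "BED6"):
        raise ValueError(f"unknown BED dialect: {dialect}")
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if genome is not None and chrom not in genome:
                if skip_unknown:
                    continue
                raise ValueError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            name = score = None
            strand = "."
            if dialect == "BED6" and len(fields) >= 6:
                name = fields[3] if fields[3] != "." else None
                score = float(fields[4]) if fields[4] != "." else None
                strand = fields[5]
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(intervals, genome=genome)


def write_bed(iset: IntervalSet, path, dialect: str = "BED6") -> None:
    with open(path, "w") as fh:
        for iv in iset:
            if dialect == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Operations


def merge_cluster_recenter(anchors: AnchorSet, radius: int = 500) -> AnchorSet:
    """Merge nearby anchors by single-linkage chaining and recenter clusters.

    Anchors at distance <= ``radius`` (on the same chrom) chain into one
    cluster; each cluster emits a single anchor at the floored midpoint of its
    extreme positions. Strand is ignored for clustering (output anchors are
    unstranded). The operation is idempotent: output anchors are pairwise more
    than ``radius`` apart.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    out_chroms: List[str] = []
    out_pos: List[int] = []
    by_chrom: Dict[str, List[int]] = {}
    for c, p, _ in anchors:
        by_chrom.setdefault(c, []).append(int(p))
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        cluster_min = cluster_max = pos[0]
        for p in pos[1:]:
            if p - cluster_max <= radius:
                cluster_max = p
            else:
                out_chroms.append(chrom)
                out_pos.append((cluster_min + cluster_max) // 2)
                cluster_min = cluster_max = p
        out_chroms.append(chrom)
        out_pos.append((cluster_min + cluster_max) // 2)
    return AnchorSet(out_chroms, np.asarray(out_pos, dtype=np.int64),
                     ["."] * len(out_chroms), genome=anchors.genome)


def subtract_blacklist(iset: IntervalSet, blacklist: IntervalSet) -> IntervalSet:
    """Drop every interval that overlaps the blacklist by >= 1 bp.

    Whole-interval removal, no trimming.
    """
    kept = [
        iv for iv in iset if blacklist.overlap_bp(iv.chrom, iv.start, iv.end) == 0
    ]
    return IntervalSet(kept, genome=iset.genome)


def membership(
    query: IntervalSet,
    refs: Mapping[str, IntervalSet],
    min_bp: int = 1,
) -> MembershipTable:
    """Boolean membership of each query interval in each named reference set.

    A query belongs to a reference iff their overlap is >= ``min_bp``.
    Combination counts (one per observed membership pattern) partition the
    query set; ``fractions[ref]`` is the share of queries overlapping ``ref``.
    """
    names = list(refs)
    cols = {}
    for name in names:
        ref = refs[name]
        cols[name] = [
            ref.overlap_bp(iv.chrom, iv.start, iv.end) >= min_bp for iv in query
        ]
    table = pd.DataFrame(cols, dtype=bool)
    if names:
        combo = table.apply(
            lambda row: "&".join(n for n in names if row[n]) or "none", axis=1
        ) if len(table) else pd.Series(dtype=object)
        combination_counts = combo.value_counts()
        fractions = table.mean(axis=0) if len(table) else pd.Series(0.0, index=names)
    else:
        combination_counts = pd.Series(dtype=int)
        fractions = pd.Series(dtype=float)
    if len(table) == 0:
        combination_counts = pd.Series(dtype=int)
    return MembershipTable(table, combination_counts, fractions)
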