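"""Fragment-center coverage tracks, anchor-profile matrices, and windowed
normalization.

The coverage statistic implemented here counts only the central three
nucleotides of each sequenced fragment into genome-anchored 50 bp bins, after
restricting to fragments of 130-200 bp — the protected-fragment footprint of a
chromatin reader in a MNase-based assay. For a fragment ``[start, end)`` the
center base is ``c = floor((start + end - 1) / 2)`` and the bases
``{c-1, c, c+1}`` each contribute one count to their containing bin, so mass
may split across a bin boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import AnchorSet, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "BinnedTrack",
    "SignalMatrix",
    "load_fragments",
    "filter_fragment_length",
    "center_weighted_coverage",
    "anchor_profile",
    "rpm_normalize",
    "window_rpkm",
    "point_coverage",
    "point_profile",
    "write_bedgraph",
]


@dataclass
class FragmentSet:
    """Sequenced fragments as parallel arrays of (chrom, start, end)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if len(self.starts) and (self.starts >= self.ends).any():
            raise ValueError("fragment with start >= end")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        """Center base per fragment: floor((start + end - 1) / 2)."""
        return (self.starts + self.ends - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "FragmentSet":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(dtype=np.int64),
            df["end"].to_numpy(dtype=np.int64),
            source=source,
        )


@dataclass
class BinnedTrack:
    """Per-chrom binned signal, bins genome-anchored at ``[k*w, (k+1)*w)``."""

    binsize: int
    data: Dict[str, np.ndarray]
    normalization: str = "raw"
    genome: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        if self.genome is not None:
            for c, v in self.data.items():
                expect = math.ceil(self.genome[c] / self.binsize)
                if len(v) != expect:
                    raise ValueError(
                        f"{c}: {len(v)} bins, expected ceil({self.genome[c]}/{self.binsize})={expect}"
                    )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.binsize,
            {c: v.copy() for c, v in self.data.items()},
            self.normalization,
            dict(self.genome) if self.genome else None,
        )


@dataclass
class SignalMatrix:
    """Anchor-by-offset-bin signal matrix covering ``[-flank, +flank)``."""

    values: np.ndarray  # (n_anchors, 2*flank/bin)
    flank: int
    binsize: int
    row_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ncol = 2 * self.flank // self.binsize
        if self.values.ndim != 2 or self.values.shape[1] != ncol:
            raise ValueError(f"expected {ncol} columns, got {self.values.shape}")
        if self.row_order is None:
            self.row_order = np.arange(self.values.shape[0])

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each offset bin relative to the anchor."""
        return -self.flank + self.binsize * np.arange(self.values.shape[1])

    @property
    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0) if len(self.values) else np.zeros(self.values.shape[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values[self.row_order], columns=self.offsets)


# ---------------------------------------------------------------------------
# Loading and filtering


def load_fragments(path, format: str = "BEDPE", min_mapq: int = 30) -> FragmentSet:
    """Load paired-end fragments from BEDPE or a SAM/BAM-convention alignment.

    Alignment templates with mapping quality <= ``min_mapq`` are dropped
    (strictly greater retained); BEDPE input is assumed pre-filtered.
    Discordant pairs (mates on different chroms) are skipped and counted.
    """
    if format == "BEDPE":
        chroms: List[str] = []
        starts: List[int] = []
        ends: List[int] = []
        n_discordant = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                if c1 != c2:
                    n_discordant += 1
                    continue
                chroms.append(c1)
                starts.append(min(s1, s2))
                ends.append(max(e1, e2))
        if n_discordant:
            logger.warning("skipped %d discordant pairs", n_discordant)
        return FragmentSet(np.array(chroms, dtype=object), starts, ends, source=str(path))
    elif format == "alignment":
        import pysam

        chroms, starts, ends = [], [], []
        n_discordant = 0
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af:
                # one record per template: read1 of a proper, quality pair
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if not read.is_paired or not read.is_read1:
                    continue
                if read.mapping_quality <= min_mapq:
                    continue
                if read.reference_id != read.next_reference_id:
                    n_discordant += 1
                    continue
                tlen = abs(read.template_length)
                if tlen == 0:
                    continue
                start = min(read.reference_start, read.next_reference_start)
                chroms.append(read.reference_name)
                starts.append(start)
                ends.append(start + tlen)
        if n_discordant:
            logger.warning("skipped %d discordant pairs", n_discordant)
        return FragmentSet(np.array(chroms, dtype=object), starts, ends, source=str(path))
    raise ValueError(f"unknown fragment format: {format}")


def filter_fragment_length(fragments: FragmentSet, lo: int = 130, hi: int = 200) -> FragmentSet:
    """Keep fragments with ``lo <= length <= hi`` (closed range)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    keep = (fragments.lengths >= lo) & (fragments.lengths <= hi)
    return FragmentSet(
        fragments.chroms[keep], fragments.starts[keep], fragments.ends[keep],
        source=fragments.source,
    )


# ---------------------------------------------------------------------------
# Coverage


def center_weighted_coverage(
    fragments: FragmentSet,
    genome: Mapping[str, int],
    binsize: int = 50,
) -> BinnedTrack:
    """Central-3-nt coverage in genome-anchored bins.

    Each fragment deposits one count at each of its three center bases
    ``{c-1, c, c+1}`` with ``c = floor((start+end-1)/2)``; bases falling off a
    chrom edge are clipped. Total track mass is ``3 * len(fragments)`` minus
    clipped bases.
    """
    data = {c: np.zeros(math.ceil(l / binsize)) for c, l in genome.items()}
    if len(fragments) == 0:
        return BinnedTrack(binsize, data, "raw", dict(genome))
    mids = fragments.midpoints
    for chrom in genome:
        sel = fragments.chroms == chrom
        if not sel.any():
            continue
        m = mids[sel]
        bases = np.concatenate([m - 1, m, m + 1])
        bases = bases[(bases >= 0) & (bases < genome[chrom])]
        np.add.at(data[chrom], bases // binsize, 1.0)
    return BinnedTrack(binsize, data, "raw", dict(genome))


def anchor_profile(
    source,
    anchors: AnchorSet,
    flank: int,
    binsize: int = 50,
    flip_minus_strand: bool = True,
    row_order: str = "descending_row_sum",
) -> SignalMatrix:
    """Signal matrix around anchors: row r, column j = mass in
    ``[pos - flank + j*bin, pos - flank + (j+1)*bin)``.

    ``source`` may be a :class:`FragmentSet` (center-base mass binned exactly
    at anchor-relative offsets) or a :class:`BinnedTrack` (genome-bin mass
    spread uniformly within each bin and integrated over profile bins).
    Minus-strand anchors are column-reversed when ``flip_minus_strand``.
    Anchors within ``flank`` of a chrom edge are dropped with a warning.
    """
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    ncol = 2 * flank // binsize

    if isinstance(source, FragmentSet):
        genome = None
        get_window = None
    elif isinstance(source, BinnedTrack):
        genome = source.genome
        if genome is None:
            raise ValueError("BinnedTrack source needs a genome declaration")
    else:
        raise TypeError("source must be FragmentSet or BinnedTrack")

    kept_rows: List[np.ndarray] = []
    n_dropped = 0
    if isinstance(source, FragmentSet):
        # group fragment center bases by chrom once
        by_chrom: Dict[str, np.ndarray] = {}
        mids = source.midpoints
        for chrom in set(source.chroms.tolist()):
            m = mids[source.chroms == chrom]
            by_chrom[chrom] = np.sort(np.concatenate([m - 1, m, m + 1]))
        for chrom, pos, strand in anchors:
            lo, hi = pos - flank, pos + flank
            if lo < 0 or (anchors.genome is not None and hi > anchors.genome[chrom]):
                n_dropped += 1
                continue
            bases = by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            window = bases[np.searchsorted(bases, lo): np.searchsorted(bases, hi)]
            row = np.bincount((window - lo) // binsize, minlength=ncol).astype(float)
            if strand == "-" and flip_minus_strand:
                row = row[::-1]
            kept_rows.append(row)
    else:
        w = source.binsize
        for chrom, pos, strand in anchors:
            lo, hi = pos - flank, pos + flank
            if lo < 0 or hi > genome[chrom]:
                n_dropped += 1
                continue
            vec = source.data[chrom]
            row = np.zeros(ncol)
            for j in range(ncol):
                a, b = lo + j * binsize, lo + (j + 1) * binsize
                k0, k1 = a // w, (b - 1) // w
                for k in range(k0, k1 + 1):
                    ov = min(b, (k + 1) * w) - max(a, k * w)
                    if 0 <= k < len(vec) and ov > 0:
                        row[j] += vec[k] * ov / w
            if strand == "-" and flip_minus_strand:
                row = row[::-1]
            kept_rows.append(row)

    if n_dropped:
        logger.warning("dropped %d anchors within %d bp of a chrom edge", n_dropped, flank)
    if not kept_rows:
        raise ValueError("no anchors survive the chrom-edge filter")
    values = np.vstack(kept_rows)
    if row_order == "descending_row_sum":
        order = np.argsort(-values.sum(axis=1), kind="stable")
    elif row_order == "input":
        order = np.arange(len(values))
    else:
        raise ValueError(f"unknown row_order: {row_order}")
    return SignalMatrix(values, flank, binsize, row_order=order)


# ---------------------------------------------------------------------------
# Normalization


def rpm_normalize(track: BinnedTrack, total_fragments: int) -> BinnedTrack:
    """Reads-per-million scaling: values * 1e6 / total_fragments."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    out = track.copy()
    for c in out.data:
        out.data[c] = out.data[c] * 1e6 / total_fragments
    out.normalization = "RPM"
    return out


def window_rpkm(
    read_chroms: Sequence[str],
    read_positions: np.ndarray,
    windows: IntervalSet,
    total_reads: int,
) -> pd.DataFrame:
    """Per-window RPKM of single-base read 5' ends.

    A read counts for window ``w`` iff its 5' end lies in ``w`` (half-open);
    RPKM_w = count_w * 1e9 / (total_reads * width_w).
    """
    if len(windows) == 0:
        raise ValueError("windows must be non-empty")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    read_chroms = np.asarray(read_chroms, dtype=object)
    read_positions = np.asarray(read_positions, dtype=np.int64)
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom in set(read_chroms.tolist()):
        by_chrom[chrom] = np.sort(read_positions[read_chroms == chrom])
    rows = []
    for iv in windows:
        if iv.width <= 0:
            raise ValueError("zero-width window")
        pos = by_chrom.get(iv.chrom, np.empty(0, dtype=np.int64))
        count = int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "count": count,
                "rpkm": count * 1e9 / (total_reads * iv.width),
            }
        )
    return pd.DataFrame(rows)


def point_coverage(
    read_chroms: Sequence[str],
    read_positions: np.ndarray,
    genome: Mapping[str, int],
    binsize: int = 50,
) -> BinnedTrack:
    """Binned counts of single-base read 5' ends (e.g. break ends)."""
    read_chroms = np.asarray(read_chroms, dtype=object)
    read_positions = np.asarray(read_positions, dtype=np.int64)
    data = {c: np.zeros(math.ceil(l / binsize)) for c, l in genome.items()}
    for chrom in genome:
        pos = read_positions[read_chroms == chrom]
        pos = pos[(pos >= 0) & (pos < genome[chrom])]
        if len(pos):
            np.add.at(data[chrom], pos // binsize, 1.0)
    return BinnedTrack(binsize, data, "raw", dict(genome))


def point_profile(
    read_chroms: Sequence[str],
    read_positions: np.ndarray,
    anchors: AnchorSet,
    flank: int,
    binsize: int = 50,
) -> SignalMatrix:
    """Anchor-relative profile of single-base read positions (exact offset
    binning, no center-base expansion)."""
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    ncol = 2 * flank // binsize
    read_chroms = np.asarray(read_chroms, dtype=object)
    read_positions = np.asarray(read_positions, dtype=np.int64)
    by_chrom = {
        c: np.sort(read_positions[read_chroms == c])
        for c in set(read_chroms.tolist())
    }
    rows = []
    n_dropped = 0
    for chrom, pos, strand in anchors:
        lo, hi = pos - flank, pos + flank
        if lo < 0 or (anchors.genome is not None and hi > anchors.genome[chrom]):
            n_dropped += 1
            continue
        p = by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        window = p[np.searchsorted(p, lo): np.searchsorted(p, hi)]
        row = np.bincount((window - lo) // binsize, minlength=ncol).astype(float)
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    if n_dropped:
        logger.warning("dropped %d anchors within %d bp of a chrom edge", n_dropped, flank)
    if not rows:
        raise ValueError("no anchors survive the chrom-edge filter")
    return SignalMatrix(np.vstack(rows), flank, binsize)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """4-column bedGraph (0-based half-open), zero bins omitted."""
    w = track.binsize
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            nz = np.nonzero(vec)[0]
            length = track.genome[chrom] if track.genome else (len(vec) * w)
            for k in nz:
                fh.write(f"{chrom}\t{k * w}\t{min((k + 1) * w, length)}\t{vec[k]:g}\n")
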