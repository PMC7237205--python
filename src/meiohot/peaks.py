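"""Poisson window enrichment peak calling and peak-strength quantification.

This is an explicit, documented simplified caller — a Poisson upper-tail test
per bin against a global (or depth-scaled control) expectation, with
significant bins merged across a gap — standing in for a full MACS-style
model. Externally called peak BED files can be ingested through
:func:`meiohot.intervals.read_bed` wherever a PeakSet is accepted downstream.
No deduplication is performed anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import BinnedTrack, FragmentSet
from .intervals import GenomicInterval, IntervalSet

__all__ = ["Peak", "PeakSet", "call_peaks", "peak_strength"]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    fold: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must be in (0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, score=self.fold)


@dataclass
class PeakSet:
    peaks: List[Peak]
    params: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_interval_set(self, genome=None) -> IntervalSet:
        return IntervalSet(
            [GenomicInterval(p.chrom, p.start, p.end, score=p.fold) for p in self.peaks],
            genome=genome,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": p.chrom, "start": p.start, "end": p.end,
                    "summit": p.summit, "fold": p.fold, "pvalue": p.pvalue,
                }
                for p in self.peaks
            ]
        )


def call_peaks(
    signal: BinnedTrack,
    control: Optional[BinnedTrack] = None,
    p_max: float = 0.001,
    merge_gap: int = 500,
    fold_min: float = 0.0,
    local_lambda: str = "global",
) -> PeakSet:
    """Call enriched regions by a per-bin Poisson upper-tail test.

    The per-bin expectation is the genome-wide mean bin count; with
    ``local_lambda="control-scaled"`` it is the elementwise maximum of that
    global mean and the depth-scaled control bin count. A bin with count x is
    significant iff P(X >= x | lam) <= p_max; significant bins within
    ``merge_gap`` bp merge into one peak. Peak fold enrichment is the max bin
    count over its expectation; peaks with fold <= ``fold_min`` are dropped
    (">2.5 kept" semantics). Summit is the midpoint of the max bin.
    """
    if local_lambda not in ("global", "control-scaled"):
        raise ValueError(f"unknown local_lambda mode: {local_lambda}")
    if control is not None and control.binsize != signal.binsize:
        raise ValueError("signal and control must share a binning")

    total = signal.total()
    nbins = sum(len(v) for v in signal.data.values())
    peaks: List[Peak] = []
    if total == 0 or nbins == 0:
        return PeakSet(peaks, _params(p_max, merge_gap, fold_min, local_lambda, signal.binsize))
    lam_global = total / nbins
    depth_ratio = (
        total / control.total() if (control is not None and control.total() > 0) else 1.0
    )

    w = signal.binsize
    for chrom in sorted(signal.data):
        vec = signal.data[chrom]
        lam = np.full(len(vec), lam_global)
        if control is not None and local_lambda == "control-scaled":
            lam = np.maximum(lam, control.data[chrom] * depth_ratio)
        pvals = stats.poisson.sf(vec - 1, lam)  # P(X >= x)
        sig = np.nonzero(pvals <= p_max)[0]
        if len(sig) == 0:
            continue
        # merge significant bins whose gap (bp between bin edges) <= merge_gap
        gap_bins = merge_gap // w
        runs: List[List[int]] = [[sig[0]]]
        for k in sig[1:]:
            if k - runs[-1][-1] - 1 <= gap_bins:
                runs[-1].append(k)
            else:
                runs.append([k])
        for run in runs:
            k0, k1 = run[0], run[-1]
            counts = vec[k0: k1 + 1]
            kmax = k0 + int(np.argmax(counts))
            fold = float(vec[kmax] / lam[kmax])
            if fold <= fold_min:
                continue
            pv = float(min(pvals[run]))
            end = (k1 + 1) * w
            if signal.genome is not None:
                end = min(end, signal.genome[chrom])
            peaks.append(
                Peak(chrom, k0 * w, end, summit=kmax * w + w // 2,
                     fold=fold, pvalue=max(pv, np.nextafter(0, 1)))
            )
    return PeakSet(peaks, _params(p_max, merge_gap, fold_min, local_lambda, signal.binsize))


def _params(p_max, merge_gap, fold_min, local_lambda, binsize) -> Dict:
    return {
        "p_max": p_max,
        "merge_gap": merge_gap,
        "fold_min": fold_min,
        "local_lambda": local_lambda,
        "binsize": binsize,
    }


def peak_strength(intervals: IntervalSet, fragments: FragmentSet) -> pd.DataFrame:
    """Per-interval strength: number of fragments overlapping by >= 1 bp."""
    by_chrom: Dict[str, tuple] = {}
    for chrom in set(fragments.chroms.tolist()):
        sel = fragments.chroms == chrom
        s = fragments.starts[sel]
        e = fragments.ends[sel]
        order = np.argsort(s, kind="stable")
        by_chrom[chrom] = (s[order], np.sort(e), e[order], len(s))
    rows = []
    for iv in intervals:
        if iv.chrom not in by_chrom:
            count = 0
        else:
            starts_sorted, ends_sorted, _, n = by_chrom[iv.chrom]
            # overlap iff start < iv.end and end > iv.start
            n_start_before_end = np.searchsorted(starts_sorted, iv.end, side="left")
            n_end_before_start = np.searchsorted(ends_sorted, iv.start, side="right")
            count = int(n_start_before_end - n_end_before_start)
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end, "count": count})
    return pd.DataFrame(rows)
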