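"""Hotspot-centric analyses: PWM motif scanning, motif-centered hotspot
filtering, F1-hybrid and allele classification, dual-histone-mark classes,
END-seq spike-in normalization, central/flank profile decomposition, and
hotspot-strength correlations.

Coordinates are 0-based half-open throughout; PWM scores are log2 odds against
a background base composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import SignalMatrix, window_rpkm
from .intervals import AnchorSet, GenomicInterval, IntervalSet

__all__ = [
    "PWM",
    "MotifHit",
    "SpikeSpec",
    "scan_motif",
    "scan_sequence",
    "center_and_filter_hotspots",
    "classify_hybrid_hotspots",
    "assign_allele_by_motif",
    "dual_mark_classes",
    "spikein_normalize",
    "central_flank_decomposition",
    "strength_correlation",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PWM:
    """Position probability matrix over {A, C, G, T} with pseudocount and a
    background composition; scoring uses the derived log2-odds matrix."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: Optional[np.ndarray] = None,
        name: str = "",
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, name)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        match_prob: float = 0.91,
        background: Optional[np.ndarray] = None,
        name: str = "",
    ) -> "PWM":
        """Degenerate PWM from a consensus string: ``match_prob`` on the
        consensus base, remainder split over the other three."""
        L = len(consensus)
        probs = np.full((L, 4), (1.0 - match_prob) / 3.0)
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = match_prob
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, name)

    @classmethod
    def read_tsv(cls, path, background: Optional[np.ndarray] = None, name: str = "") -> "PWM":
        """Probability TSV with header columns A, C, G, T."""
        df = pd.read_csv(path, sep="\t")
        probs = df[list(_BASES)].to_numpy(dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, name or str(path))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.probs, columns=list(_BASES)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # 0-based; motif occupies [start, start + L)
    strand: str
    score: float
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SpikeSpec:
    """Exogenous spike-in break locus mixed into a sample at fraction ``f``."""

    chrom: str
    position: int
    fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("spike fraction must be in (0, 1)")

    @property
    def divisor(self) -> float:
        """1/f — e.g. 20 for a 5% (1:20) spike-in."""
        return 1.0 / self.fraction


# ---------------------------------------------------------------------------
# Motif scanning


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of length L; windows containing
    non-ACGT characters score -inf."""
    L = lom.shape[0]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        col = encoded[j: j + n]
        invalid = col < 0
        bad |= invalid
        scores += lom[j, np.where(invalid, 0, col)]
    scores[bad] = -np.inf
    return scores


def scan_sequence(seq: str, pwm: PWM, threshold: float, chrom: str = "seq") -> List[MotifHit]:
    """Scan one sequence on both strands; overlapping hits are resolved
    greedily best-score-first (ties: leftmost, then + strand)."""
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    lom = pwm.log_odds
    fwd = _window_scores(_encode(seq), lom)
    rev = _window_scores(_encode(seq.translate(_COMPLEMENT)[::-1]), lom)
    candidates: List[MotifHit] = []
    for i in np.nonzero(fwd >= threshold)[0]:
        candidates.append(MotifHit(chrom, int(i), "+", float(fwd[i]), L))
    n = len(seq)
    for i in np.nonzero(rev >= threshold)[0]:
        # window i on the reverse strand maps to [n - i - L, n - i) forward
        candidates.append(MotifHit(chrom, int(n - i - L), "-", float(rev[i]), L))
    candidates.sort(key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1))
    accepted: List[MotifHit] = []
    for h in candidates:
        if any(h.start < a.end and a.start < h.end for a in accepted):
            continue
        accepted.append(h)
    accepted.sort(key=lambda h: h.start)
    return accepted


def scan_motif(genome: Mapping[str, str], pwm: PWM, threshold: float) -> List[MotifHit]:
    """Scan every chrom of ``genome`` (name -> sequence) for PWM hits."""
    hits: List[MotifHit] = []
    for chrom in sorted(genome):
        hits.extend(scan_sequence(genome[chrom], pwm, threshold, chrom=chrom))
    return hits


# ---------------------------------------------------------------------------
# Hotspot centering and classification


def center_and_filter_hotspots(
    hotspots: IntervalSet, hits: Sequence[MotifHit]
) -> Tuple[AnchorSet, Dict[str, int]]:
    """Anchor each hotspot at its single in-interval motif midpoint.

    Hotspots with exactly one hit yield an anchor (motif midpoint, motif
    strand); hotspots with zero or multiple hits are excluded and tallied in
    the report (multi-motif hotspots are excluded from centered analyses;
    zero-hit hotspots cannot be motif-centered at all).
    """
    by_chrom: Dict[str, List[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    chroms: List[str] = []
    positions: List[int] = []
    strands: List[str] = []
    report = {"kept": 0, "zero_motif": 0, "multi_motif": 0}
    for iv in hotspots:
        inside = [
            h for h in by_chrom.get(iv.chrom, [])
            if h.start >= iv.start and h.end <= iv.end
        ]
        if len(inside) == 1:
            chroms.append(iv.chrom)
            positions.append(inside[0].center)
            strands.append(inside[0].strand)
            report["kept"] += 1
        elif len(inside) == 0:
            report["zero_motif"] += 1
        else:
            report["multi_motif"] += 1
    return (
        AnchorSet(chroms, np.asarray(positions, dtype=np.int64), strands,
                  genome=hotspots.genome),
        report,
    )


def classify_hybrid_hotspots(
    f1_peaks: IntervalSet,
    parental_b6: IntervalSet,
    parental_cast: IntervalSet,
) -> pd.DataFrame:
    """Label each F1-hybrid peak by >= 1 bp overlap with parental hotspot maps:
    shared-B6 / shared-CAST / shared-both / novel."""
    rows = []
    for iv in f1_peaks:
        in_b6 = parental_b6.overlap_bp(iv.chrom, iv.start, iv.end) >= 1
        in_cast = parental_cast.overlap_bp(iv.chrom, iv.start, iv.end) >= 1
        if in_b6 and in_cast:
            label = "shared-both"
        elif in_b6:
            label = "shared-B6"
        elif in_cast:
            label = "shared-CAST"
        else:
            label = "novel"
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end, "class": label})
    df = pd.DataFrame(rows)
    df.attrs["counts"] = df["class"].value_counts().to_dict() if len(df) else {}
    df.attrs["fractions"] = (
        (df["class"].value_counts() / len(df)).to_dict() if len(df) else {}
    )
    return df


def assign_allele_by_motif(
    hotspots: IntervalSet,
    genome: Mapping[str, str],
    pwm_a: PWM,
    pwm_b: PWM,
    labels: Tuple[str, str] = ("Dom2", "Cast"),
    margin: float = 1.0,
) -> pd.DataFrame:
    """Assign each hotspot to the PRDM9 allele whose PWM scores best inside it.

    The best score of each PWM over both strands of the hotspot sequence is
    compared; a difference below ``margin`` (log2-odds units) is called
    ambiguous.
    """
    rows = []
    for iv in hotspots:
        seq = genome[iv.chrom][iv.start: iv.end]
        best = []
        for pwm in (pwm_a, pwm_b):
            if len(seq) < len(pwm):
                best.append(-np.inf)
                continue
            lom = pwm.log_odds
            fwd = _window_scores(_encode(seq), lom)
            rev = _window_scores(_encode(seq.translate(_COMPLEMENT)[::-1]), lom)
            best.append(float(max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf))))
        delta = best[0] - best[1]
        if not np.isfinite(delta) or abs(delta) < margin:
            allele = "ambiguous"
        else:
            allele = labels[0] if delta > 0 else labels[1]
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "allele": allele,
                f"score_{labels[0]}": best[0], f"score_{labels[1]}": best[1],
            }
        )
    return pd.DataFrame(rows)


def dual_mark_classes(
    zc_peaks: IntervalSet,
    k4_peaks: IntervalSet,
    k36_peaks: IntervalSet,
    zc_strengths: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Classify reader peaks by overlap (>= 1 bp) with H3K4me3 and H3K36me3
    peak sets into {both, K4-only, K36-only, neither}; optionally compare
    per-class peak strengths (one-sided Mann-Whitney rank-sum: both > single).
    """
    rows = []
    for iv in zc_peaks:
        k4 = k4_peaks.overlap_bp(iv.chrom, iv.start, iv.end) >= 1
        k36 = k36_peaks.overlap_bp(iv.chrom, iv.start, iv.end) >= 1
        label = {
            (True, True): "both",
            (True, False): "K4-only",
            (False, True): "K36-only",
            (False, False): "neither",
        }[(k4, k36)]
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end, "class": label})
    df = pd.DataFrame(rows)
    counts = df["class"].value_counts().to_dict() if len(df) else {}
    n = len(df)
    summary: Dict = {
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()} if n else {},
    }
    if zc_strengths is not None:
        strengths = np.asarray(zc_strengths, dtype=float)
        if len(strengths) != n:
            raise ValueError("strengths must align with zc_peaks")
        df["strength"] = strengths
        both = strengths[(df["class"] == "both").to_numpy()]
        tests = {}
        for other in ("K4-only", "K36-only", "neither"):
            vals = strengths[(df["class"] == other).to_numpy()]
            if len(both) and len(vals):
                stat, p = stats.mannwhitneyu(both, vals, alternative="greater")
                tests[other] = {"U": float(stat), "p": float(p)}
        summary["rank_sum_both_greater"] = tests
    return df, summary


# ---------------------------------------------------------------------------
# END-seq spike-in normalization and resection decomposition


def spikein_normalize(
    read_chroms: Sequence[str],
    read_positions: np.ndarray,
    hotspot_windows: IntervalSet,
    spike: SpikeSpec,
    spike_halfwidth: int = 3000,
) -> Dict[str, float]:
    """Spike-in-normalized END-seq intensity for one sample.

    Signal is summed as RPKM over the hotspot windows (nominally ±3 kb around
    hotspot centers), divided by the RPKM around the spiked-in break, and then
    divided by 1/f (= 20 for a 5% spike). Because both RPKM terms share the
    same library size, the result is invariant to global depth rescaling.
    """
    read_chroms = np.asarray(read_chroms, dtype=object)
    read_positions = np.asarray(read_positions, dtype=np.int64)
    total = len(read_positions)
    if total == 0:
        raise ValueError("sample has no reads")
    hs = window_rpkm(read_chroms, read_positions, hotspot_windows, total)
    spike_iv = IntervalSet(
        [GenomicInterval(spike.chrom, max(0, spike.position - spike_halfwidth),
                         spike.position + spike_halfwidth)]
    )
    sp = window_rpkm(read_chroms, read_positions, spike_iv, total)
    spike_rpkm = float(sp["rpkm"].iloc[0])
    if spike_rpkm == 0:
        raise ValueError("zero spike-in signal: cannot normalize")
    hotspot_rpkm = float(hs["rpkm"].sum())
    normalized = hotspot_rpkm / spike_rpkm / spike.divisor
    return {
        "hotspot_rpkm": hotspot_rpkm,
        "spike_rpkm": spike_rpkm,
        "spike_count": int(sp["count"].iloc[0]),
        "divisor": spike.divisor,
        "normalized": normalized,
    }


@dataclass
class ProfileDecomposition:
    """Mean signal split into a central window (break/invasion intermediates)
    and symmetric flanks (resection tracts)."""

    central_halfwidth: int
    flank_range: Tuple[int, int]
    central: float
    flank: float

    def __post_init__(self) -> None:
        if self.central_halfwidth > self.flank_range[0]:
            raise ValueError("central window must not extend past the flank start")


def decompose_profile(
    matrix: SignalMatrix,
    central_halfwidth: int = 250,
    flank_range: Tuple[int, int] = (250, 3000),
) -> ProfileDecomposition:
    """Split a mean anchor profile into central and flanking components."""
    if matrix.flank < flank_range[1]:
        raise ValueError("profile flank must cover the requested flank range")
    if central_halfwidth > flank_range[0]:
        raise ValueError("central window must not extend past the flank start")
    prof = matrix.mean_profile
    centers = matrix.offsets + matrix.binsize / 2.0
    # central [-ch, ch), flank [fs, fe] on both sides: disjoint when ch <= fs
    central_mask = np.abs(centers) < central_halfwidth
    flank_mask = (np.abs(centers) >= flank_range[0]) & (np.abs(centers) <= flank_range[1])
    return ProfileDecomposition(
        central_halfwidth,
        flank_range,
        float(prof[central_mask].mean()),
        float(prof[flank_mask].mean()),
    )


def central_flank_decomposition(
    profiles: Mapping[str, SignalMatrix],
    central_halfwidth: int = 250,
    flank_range: Tuple[int, int] = (250, 3000),
    contrast: Optional[Tuple[str, str]] = None,
) -> Dict:
    """Per-sample central/flank decomposition with an optional genotype
    contrast (e.g. KO vs WT): flank ratio and central ratio."""
    per_sample = {
        name: decompose_profile(m, central_halfwidth, flank_range)
        for name, m in profiles.items()
    }
    out: Dict = {
        "central_halfwidth": central_halfwidth,
        "flank_range": list(flank_range),
        "samples": {
            name: {"central": d.central, "flank": d.flank}
            for name, d in per_sample.items()
        },
    }
    if contrast is not None:
        num, den = contrast
        out["contrast"] = {
            "numerator": num,
            "denominator": den,
            "flank_ratio": per_sample[num].flank / per_sample[den].flank,
            "central_ratio": per_sample[num].central / per_sample[den].central,
        }
    return out


# ---------------------------------------------------------------------------
# Strength correlations


def strength_correlation(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    restrict: Optional[np.ndarray] = None,
    min_n: int = 10,
) -> Dict[str, float]:
    """Spearman correlation between two per-hotspot metrics, optionally
    restricted (e.g. to autosomal hotspots coinciding with a reader peak).

    Uses average ranks for ties; the two-sided p-value comes from the t
    approximation t = rho * sqrt((n-2)/(1-rho^2)), except at n <= 10 where
    the full permutation distribution is enumerated (the t approximation is
    unreliable at such sizes).
    """
    df = table if restrict is None else table.loc[np.asarray(restrict, bool)]
    n = len(df)
    if n < min_n:
        raise ValueError(f"only {n} hotspots after restriction (need >= {min_n})")
    x = df[metric_x].to_numpy(dtype=float)
    y = df[metric_y].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant metric: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        from .coexpression import exact_spearman_p

        p = exact_spearman_p(x, y)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return {"rho": rho, "p": p, "n": n}
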