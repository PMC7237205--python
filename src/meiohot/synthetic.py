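"""Synthetic data generation for every input modality, with exported ground
truth.

Each generator is a pure function of its seed, and each returns (or attaches)
a machine-readable truth table so downstream estimates can be compared with
what was planted rather than with hard-coded constants. The generators
emulate:

* a random genome with recombination-hotspot motifs planted at known centers
  (two PRDM9-allele consensus motifs, optional multi-motif hotspots);
* paired-end chromatin-reader fragments with nucleosome-phased symmetric
  enrichment around hotspot centers, a central nucleosome-depleted region,
  and a truncated-normal length distribution straddling the 130-200 bp
  retention window;
* END-seq break 5' ends: a sharp central peak per hotspot plus exponentially
  decaying resection flanks out to +/-3 kb, with an exogenous spike-in break
  locus mixed at a set fraction;
* UMI count matrices with a planted Spearman correlation structure to a
  target gene (Gaussian copula, then Poisson sampling with per-cell depths);
* protein families with two paralog clades, conserved domain blocks, and
  configurable catalytic-residue states;
* one-set-of-sites titration heats with optional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import FragmentSet
from .evolution import Msa
from .hotspots import SpikeSpec
from .intervals import GenomicInterval, IntervalSet
from .itc import BindingParams, InjectionHeats, TitrationSchedule, forward_one_set_of_sites

__all__ = [
    "SyntheticGenome",
    "HotspotTruth",
    "SpikeSpec",
    "generate_genome",
    "plant_hotspots",
    "simulate_cutrun",
    "simulate_endseq",
    "simulate_sc_counts",
    "simulate_protein_families",
    "simulate_itc",
    "DEFAULT_MOTIFS",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Two 16-bp allele consensus motifs, Hamming distance 8 apart — stand-ins for
# the binding motifs of two PRDM9 zinc-finger alleles.
DEFAULT_MOTIFS: Dict[str, str] = {
    "Dom2": "CCTCCCTAGCCACGTA",
    "Cast": "CCTGATTACGCACGTA",
}


@dataclass
class SyntheticGenome:
    """Random genome: chrom name -> A/C/G/T sequence, plus the seed that
    produced it."""

    chroms: Dict[str, str]
    seed: int

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i: i + width] + "\n")


@dataclass
class HotspotTruth:
    """Planted hotspot ground truth."""

    table: pd.DataFrame  # chrom, center, allele, strand, strength, n_motifs
    halfwidth: int
    motifs: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def intervals(self, genome: Optional[Mapping[str, int]] = None) -> IntervalSet:
        ivs = [
            GenomicInterval(r.chrom, int(r.center) - self.halfwidth,
                            int(r.center) + self.halfwidth, name=f"hs{i}")
            for i, r in enumerate(self.table.itertuples())
        ]
        return IntervalSet(ivs, genome=dict(genome) if genome else None)

    def windows(self, halfwidth: int, genome: Optional[Mapping[str, int]] = None) -> IntervalSet:
        ivs = [
            GenomicInterval(r.chrom, max(0, int(r.center) - halfwidth),
                            int(r.center) + halfwidth)
            for r in self.table.itertuples()
        ]
        return IntervalSet(ivs, genome=dict(genome) if genome else None)


# ---------------------------------------------------------------------------
# Genome and hotspots


def generate_genome(seed: int, chrom_lengths: Mapping[str, int]) -> SyntheticGenome:
    """Uniform-random genome; byte-identical for a given seed."""
    rng = np.random.default_rng(seed)
    chroms = {}
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {name}: {length}")
        chroms[name] = "".join(_BASES[rng.integers(0, 4, size=int(length))])
    return SyntheticGenome(chroms, seed)


def plant_hotspots(
    genome: SyntheticGenome,
    n: int,
    allele_mix: Optional[Mapping[str, float]] = None,
    motifs: Optional[Mapping[str, str]] = None,
    min_spacing: int = 6000,
    multi_motif_fraction: float = 0.0,
    hotspot_halfwidth: int = 1000,
    edge_margin: int = 5000,
    seed: int = 0,
) -> Tuple[SyntheticGenome, HotspotTruth]:
    """Plant ``n`` hotspot motifs into a copy of the genome.

    Each hotspot gets one allele (drawn from ``allele_mix``), one strand, and
    its allele's consensus motif written into the sequence centered on the
    hotspot center (reverse complement on '-'). Exactly
    ``round(n * multi_motif_fraction)`` hotspots receive a second copy of
    their motif inside the hotspot interval, to exercise multi-motif
    exclusion downstream. Centers are pairwise >= ``min_spacing`` apart and
    >= ``edge_margin`` from chrom ends.
    """
    motifs = dict(motifs or DEFAULT_MOTIFS)
    allele_mix = dict(allele_mix or {a: 1.0 / len(motifs) for a in motifs})
    if abs(sum(allele_mix.values()) - 1.0) > 1e-9:
        raise ValueError("allele_mix must sum to 1")
    for allele in allele_mix:
        if allele not in motifs:
            raise ValueError(f"no motif for allele {allele!r}")
        if len(motifs[allele]) >= min_spacing:
            raise ValueError("motif length must be < min_spacing")
    rng = np.random.default_rng(seed)

    lengths = genome.lengths
    chrom_names = list(lengths)
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    centers: Dict[str, List[int]] = {c: [] for c in chrom_names}
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    order: List[Tuple[str, int]] = []
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {n} hotspots at spacing {min_spacing} "
                f"(placed {placed})"
            )
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        L = lengths[chrom]
        if L <= 2 * edge_margin:
            continue
        pos = int(rng.integers(edge_margin, L - edge_margin))
        if all(abs(pos - q) >= min_spacing for q in centers[chrom]):
            centers[chrom].append(pos)
            order.append((chrom, pos))
            placed += 1

    alleles = list(allele_mix)
    probs = np.array([allele_mix[a] for a in alleles])
    chosen_alleles = [alleles[i] for i in rng.choice(len(alleles), size=n, p=probs)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    strengths = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    n_multi = int(round(n * multi_motif_fraction))
    multi_idx = set(rng.choice(n, size=n_multi, replace=False).tolist()) if n_multi else set()

    seqs = {c: list(s) for c, s in genome.chroms.items()}

    def _write(chrom: str, center: int, motif: str, strand: str) -> None:
        m = motif if strand == "+" else motif.translate(_COMPLEMENT)[::-1]
        start = center - len(m) // 2
        seqs[chrom][start: start + len(m)] = list(m)

    rows = []
    for i, (chrom, center) in enumerate(order):
        allele, strand = chosen_alleles[i], strands[i]
        motif = motifs[allele]
        _write(chrom, center, motif, strand)
        n_motifs = 1
        if i in multi_idx:
            offset = hotspot_halfwidth // 2
            _write(chrom, center + offset, motif, strand)
            n_motifs = 2
        rows.append(
            {
                "chrom": chrom, "center": center, "allele": allele,
                "strand": strand, "strength": strengths[i], "n_motifs": n_motifs,
            }
        )
    truth = HotspotTruth(pd.DataFrame(rows), hotspot_halfwidth, dict(motifs))
    return SyntheticGenome({c: "".join(s) for c, s in seqs.items()}, genome.seed), truth


# ---------------------------------------------------------------------------
# CUT&RUN fragments


def truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, clip: Tuple[float, float]
) -> np.ndarray:
    a, b = (clip[0] - mean) / sd, (clip[1] - mean) / sd
    vals = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.rint(vals).astype(np.int64)


def simulate_cutrun(
    genome: SyntheticGenome,
    truth: HotspotTruth,
    n_fragments: int,
    frag_len_mean: float = 165.0,
    frag_len_sd: float = 15.0,
    len_clip: Tuple[float, float] = (100.0, 250.0),
    ndr_halfwidth: int = 75,
    nucleosome_spacing: int = 180,
    jitter_sd: float = 20.0,
    signal_fraction: float = 0.7,
    seed: int = 0,
) -> FragmentSet:
    """Paired-end reader fragments around planted hotspots.

    Signal-fragment midpoints sit on the +/-1 and +/-2 nucleosome positions
    (center +/- spacing, +/- 2*spacing) with bounded Gaussian jitter, and
    never within ``ndr_halfwidth`` of a hotspot center (the nucleosome
    depleted region). Background midpoints are uniform. Lengths are
    truncated-normal so a downstream [130, 200] filter removes an
    analytically known fraction.
    """
    if not (0.0 <= signal_fraction <= 1.0):
        raise ValueError("signal_fraction must be in [0, 1]")
    if nucleosome_spacing <= ndr_halfwidth + 2:
        raise ValueError("nucleosome_spacing must exceed ndr_halfwidth + 2")
    rng = np.random.default_rng(seed)
    lengths_by_chrom = genome.lengths
    margin = 2 * nucleosome_spacing + 300
    for r in truth.table.itertuples():
        if r.center < margin or r.center > lengths_by_chrom[r.chrom] - margin:
            raise ValueError(f"hotspot at {r.chrom}:{r.center} too close to chrom edge")

    n_signal = int(rng.binomial(n_fragments, signal_fraction))
    n_bg = n_fragments - n_signal
    frag_lengths = truncated_normal_lengths(rng, n_fragments, frag_len_mean, frag_len_sd, len_clip)

    chrom_parts: List[np.ndarray] = []
    mid_parts: List[np.ndarray] = []

    if n_signal:
        w = truth.table["strength"].to_numpy(float)
        hs_idx = rng.choice(len(truth.table), size=n_signal, p=w / w.sum())
        nuc = rng.choice([-2, -1, 1, 2], size=n_signal)
        jitter = rng.normal(0.0, jitter_sd, size=n_signal)
        # keep midpoints strictly outside the NDR (+2 bp guard for the
        # floor((start+end-1)/2) midpoint convention)
        max_in = nucleosome_spacing - ndr_halfwidth - 3
        jitter = np.clip(jitter, -max_in, max_in)
        offsets = nuc * nucleosome_spacing + np.rint(jitter).astype(np.int64)
        centers = truth.table["center"].to_numpy(np.int64)[hs_idx]
        chrom_parts.append(truth.table["chrom"].to_numpy(object)[hs_idx])
        mid_parts.append(centers + offsets)
    if n_bg:
        chrom_names = list(lengths_by_chrom)
        wts = np.array([lengths_by_chrom[c] for c in chrom_names], float)
        picks = rng.choice(len(chrom_names), size=n_bg, p=wts / wts.sum())
        lens = np.array([lengths_by_chrom[c] for c in chrom_names], np.int64)[picks]
        chrom_parts.append(np.array(chrom_names, dtype=object)[picks])
        mid_parts.append(150 + (rng.random(n_bg) * (lens - 300)).astype(np.int64))

    chroms = np.concatenate(chrom_parts) if chrom_parts else np.empty(0, dtype=object)
    mids_arr = (np.concatenate(mid_parts) if mid_parts else np.empty(0, np.int64))
    starts = mids_arr - frag_lengths // 2
    ends = starts + frag_lengths
    # clip to chrom bounds (background near edges)
    chrom_len = np.array([lengths_by_chrom[c] for c in chroms], dtype=np.int64)
    under = starts < 0
    ends[under] -= starts[under]
    starts[under] = 0
    over = ends > chrom_len
    starts[over] -= ends[over] - chrom_len[over]
    ends[over] = chrom_len[over]
    return FragmentSet(chroms, starts, ends, source="simulate_cutrun")


# ---------------------------------------------------------------------------
# END-seq reads


def simulate_endseq(
    genome: SyntheticGenome,
    truth: HotspotTruth,
    n_reads: int,
    central_fraction: float = 0.5,
    resection_mean: float = 800.0,
    max_flank: int = 3000,
    min_flank: int = 300,
    central_halfwidth: int = 50,
    genotype_flank_scale: float = 1.0,
    break_rate_scale: float = 1.0,
    spike: Optional[SpikeSpec] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-base break 5' ends around planted hotspots.

    Per hotspot (strength-weighted): central reads fall uniformly within
    +/- ``central_halfwidth`` of the center; flank reads at offsets
    ``min_flank`` + Exponential(``resection_mean``), truncated at
    ``max_flank``, on either side (resection tracts shorter than
    ``min_flank`` are not resolved from the central peak).
    ``genotype_flank_scale`` multiplies the expected number of flank reads
    only; ``break_rate_scale`` multiplies both components (a genotype with
    more breaks per cell). ``n_reads`` is the nominal per-cell sequencing
    depth: when a spike-in is given, spike reads at the spike locus are added
    with expected count = f * n_reads, independent of the bulk break rate —
    spike-in cells are mixed by cell count, so their signal tracks depth, not
    the bulk break frequency.

    Returns a frame with columns chrom, pos, origin in {central, flank,
    spike}.
    """
    if resection_mean > max_flank:
        raise ValueError("resection_mean must be <= max_flank")
    if not (0.0 <= central_fraction <= 1.0):
        raise ValueError("central_fraction must be in [0, 1]")
    if min_flank <= central_halfwidth:
        raise ValueError("min_flank must exceed central_halfwidth")
    rng = np.random.default_rng(seed)

    n_central = int(rng.poisson(n_reads * central_fraction * break_rate_scale))
    n_flank = int(
        rng.poisson(n_reads * (1.0 - central_fraction) * break_rate_scale * genotype_flank_scale)
    )

    w = truth.table["strength"].to_numpy(float)
    p = w / w.sum()
    hs_chroms = truth.table["chrom"].to_numpy(object)
    hs_centers = truth.table["center"].to_numpy(np.int64)
    chrom_parts: List[np.ndarray] = []
    pos_parts: List[np.ndarray] = []
    origin_parts: List[np.ndarray] = []

    if n_central:
        idx = rng.choice(len(hs_centers), size=n_central, p=p)
        offs = rng.integers(-central_halfwidth, central_halfwidth + 1, size=n_central)
        chrom_parts.append(hs_chroms[idx])
        pos_parts.append(hs_centers[idx] + offs)
        origin_parts.append(np.full(n_central, "central", dtype=object))
    if n_flank:
        idx = rng.choice(len(hs_centers), size=n_flank, p=p)
        span = max_flank - min_flank
        # inverse-CDF sample of Exp(mean) truncated at span
        u = rng.random(n_flank) * (1.0 - np.exp(-span / resection_mean))
        mag = min_flank + (-resection_mean * np.log1p(-u))
        side = rng.choice([-1, 1], size=n_flank)
        chrom_parts.append(hs_chroms[idx])
        pos_parts.append(hs_centers[idx] + np.rint(side * mag).astype(np.int64))
        origin_parts.append(np.full(n_flank, "flank", dtype=object))
    if spike is not None:
        n_spike = int(rng.poisson(spike.fraction * n_reads))
        offs = rng.integers(-central_halfwidth, central_halfwidth + 1, size=n_spike)
        chrom_parts.append(np.full(n_spike, spike.chrom, dtype=object))
        pos_parts.append(spike.position + offs)
        origin_parts.append(np.full(n_spike, "spike", dtype=object))
    if not chrom_parts:
        return pd.DataFrame({"chrom": [], "pos": [], "origin": []})
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_parts),
            "pos": np.concatenate(pos_parts).astype(np.int64),
            "origin": np.concatenate(origin_parts),
        }
    )


# ---------------------------------------------------------------------------
# Single-cell UMI counts


def simulate_sc_counts(
    n_genes: int,
    n_cells: int,
    target_gene: str = "Prdm9",
    planted_rho: Optional[Mapping[str, float]] = None,
    depth_range: Tuple[float, float] = (0.7, 1.3),
    mean_expression: float = 100.0,
    dispersion_sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x cells UMI matrix with planted Spearman correlations to a
    target gene.

    A Gaussian copula sets the rank dependence: gene i's latent variable has
    Pearson correlation r_i = 2 sin(pi rho_i / 6) with the target latent (the
    exact bivariate-normal inversion of Spearman's rho), then latent
    quantiles map through a log-normal rate and Poisson sampling with
    per-cell depth factors. Poisson sampling and low-count ties attenuate
    rank correlations; the defaults emulate deeply sequenced full-length
    single-cell libraries (high per-gene counts), which keeps the empirical
    rho within 0.1 of the planted value at 500+ cells.

    ``planted_rho`` maps gene names to target Spearman correlations; genes
    not named are independent (rho 0). Gene names not already of the form
    ``gene###`` are appended as extra rows.
    """
    planted_rho = dict(planted_rho or {})
    for g, r in planted_rho.items():
        if abs(r) > 0.95:
            raise ValueError(
                f"|rho| > 0.95 requested for {g!r}: copula distortion too large"
            )
    rng = np.random.default_rng(seed)
    base_names = [f"gene{i:04d}" for i in range(n_genes)]
    names = [target_gene] + [g for g in planted_rho if g not in base_names and g != target_gene]
    names += [g for g in base_names if g != target_gene and g not in names]
    rho_vec = np.array([1.0 if g == target_gene else planted_rho.get(g, 0.0) for g in names])

    z_target = rng.standard_normal(n_cells)
    r_latent = 2.0 * np.sin(np.pi * rho_vec / 6.0)
    eps = rng.standard_normal((len(names), n_cells))
    Z = r_latent[:, None] * z_target[None, :] + np.sqrt(1.0 - r_latent ** 2)[:, None] * eps
    Z[0] = z_target  # target gene is its own latent

    depths = rng.uniform(depth_range[0], depth_range[1], size=n_cells)
    gene_means = rng.lognormal(np.log(mean_expression), 0.5, size=len(names))
    # rank-preserving log-normal rate from the latent quantiles
    rates = np.exp(dispersion_sigma * Z - 0.5 * dispersion_sigma ** 2)
    lam = gene_means[:, None] * rates * depths[None, :]
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=names, columns=[f"cell{j:05d}" for j in range(n_cells)])
    df.attrs["planted_rho"] = {g: float(r) for g, r in zip(names, rho_vec)}
    df.attrs["target_gene"] = target_gene
    return df


# ---------------------------------------------------------------------------
# Protein families


def simulate_protein_families(
    n1: int,
    n2: int,
    length: int = 200,
    domain_blocks: Optional[Mapping[str, Tuple[int, int]]] = None,
    conservation_levels: Optional[Mapping[str, float]] = None,
    outgroup: str = "outgroup",
    catalytic_positions: Sequence[int] = (60, 70, 80),
    catalytic_residue: str = "Y",
    catalytic_states: Optional[Mapping[str, Sequence[bool]]] = None,
    between_divergence: float = 0.4,
    within_divergence: float = 0.08,
    interdomain_distances: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> Tuple[Msa, pd.DataFrame, pd.DataFrame]:
    """Two paralog clades of protein sequences with conserved domain blocks.

    ``domain_blocks`` maps block names to 0-based half-open residue ranges
    (defaults: zf-CW at [90, 140), PWWP at [150, 195)); each block mutates at
    rate scaled by ``1 - conservation`` (default conservation 1.0 for domain
    blocks, 0.0 for background — a level of exactly 1 yields invariant
    columns). Catalytic positions (1-based in the reference) carry
    ``catalytic_residue`` unless ``catalytic_states[species]`` turns one off
    (replaced by 'F'). Returns (alignment, domain-hit table with configurable
    genomic inter-domain distances, truth table).
    """
    domain_blocks = dict(domain_blocks or {"zf-CW": (90, 140), "PWWP": (150, 195)})
    conservation_levels = dict(conservation_levels or {})
    for name in domain_blocks:
        conservation_levels.setdefault(name, 1.0)
    bg_conservation = conservation_levels.get("background", 0.0)
    for name, lvl in conservation_levels.items():
        if not (0.0 <= lvl <= 1.0):
            raise ValueError(f"conservation level for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)

    # per-column mutability multiplier: (1 - conservation)
    mutability = np.full(length, 1.0 - bg_conservation)
    for name, (a, b) in domain_blocks.items():
        mutability[a:b] = 1.0 - conservation_levels[name]
    cat_cols = [p - 1 for p in catalytic_positions]
    for c in cat_cols:
        mutability[c] = 0.0  # catalytic state is set explicitly from truth

    root = rng.choice(_AA, size=length)
    for c in cat_cols:
        root[c] = catalytic_residue

    def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
        out = seq.copy()
        hit = rng.random(length) < rate * mutability
        for j in np.nonzero(hit)[0]:
            choices = _AA[_AA != out[j]]
            out[j] = rng.choice(choices)
        return out

    anc1 = mutate(root, between_divergence / 2.0)
    anc2 = mutate(root, between_divergence / 2.0)
    # guarantee clade separation at freely mutating columns
    free = np.nonzero(mutability >= 1.0)[0]
    n_force = max(4, int(between_divergence * len(free) * 0.3))
    for j in rng.choice(free, size=min(n_force, len(free)), replace=False) if len(free) else []:
        choices = _AA[(_AA != anc1[j])]
        anc2[j] = rng.choice(choices)

    ids1 = [f"family1_sp{i + 1}" for i in range(n1)]
    ids2 = [f"family2_sp{i + 1}" for i in range(n2)]
    sequences: Dict[str, str] = {}
    truth_rows = []
    catalytic_states = dict(catalytic_states or {})
    for ids, anc, family in ((ids1, anc1, "family1"), (ids2, anc2, "family2")):
        for name in ids:
            seq = mutate(anc, within_divergence)
            states = list(catalytic_states.get(name, [True] * len(cat_cols)))
            for keep, c in zip(states, cat_cols):
                seq[c] = catalytic_residue if keep else "F"
            sequences[name] = "".join(seq)
            truth_rows.append(
                {"id": name, "family": family, "n_catalytic": int(sum(states))}
            )
    og = mutate(root, 1.0)
    for c in cat_cols:
        og[c] = "F"
    sequences[outgroup] = "".join(og)
    truth_rows.append({"id": outgroup, "family": "outgroup", "n_catalytic": 0})

    # domain-hit table in genomic coordinates (bp), one subject per species
    interdomain_distances = dict(interdomain_distances or {})
    hit_rows = []
    for name in ids1 + ids2:
        dist = int(interdomain_distances.get(name, rng.integers(0, 60_001)))
        zf_start = 1_000
        zf_end = zf_start + 165
        pw_start = zf_end + dist
        pw_end = pw_start + 200
        for domain, s, e in (("zf-CW", zf_start, zf_end), ("PWWP", pw_start, pw_end)):
            hit_rows.append(
                {
                    "species": name, "subject": f"{name}_locus", "domain": domain,
                    "start": s, "end": e, "score": float(100 + rng.integers(0, 50)),
                }
            )
    msa = Msa(sequences, reference_id=ids1[0])
    return msa, pd.DataFrame(hit_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ITC


def simulate_itc(
    params: BindingParams,
    schedule: TitrationSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> InjectionHeats:
    """Forward one-set-of-sites heats plus Gaussian noise of SD ``noise_sd``
    (ucal)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = forward_one_set_of_sites(params, schedule)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return InjectionHeats(
        clean.heats + rng.normal(0.0, noise_sd, size=len(clean.heats)),
        clean.molar_ratio,
    )


# ---------------------------------------------------------------------------
# Plain-text writers


def fragments_to_bedpe(fragments: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(fragments.chroms, fragments.starts, fragments.ends):
            mid = (s + e) // 2
            fh.write(f"{c}\t{s}\t{mid}\t{c}\t{mid}\t{e}\t.\t.\t+\t-\n")


def reads_to_bed(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in reads.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.origin}\n")
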