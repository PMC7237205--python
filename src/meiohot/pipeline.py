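"""End-to-end recipes tying the stages together on simulated inputs.

Each recipe builds its inputs with the synthetic generators (or reads them
from configured paths), runs the corresponding analysis chain, and returns a
JSON-serializable summary embedding the configuration and its hash. Given the
same config and seed, a recipe is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import coverage as cov
from . import evolution as evo
from . import hotspots as hs
from . import itc
from . import peaks as pk
from . import synthetic as syn
from .intervals import AnchorSet, IntervalSet

logger = logging.getLogger(__name__)

__all__ = ["RECIPES", "run_recipe", "default_config", "config_hash"]


def config_hash(config: Dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def default_config(seed: int = 0) -> Dict:
    """Per-stage defaults shared by the recipes."""
    return {
        "seed": seed,
        "genome": {"chrom_lengths": {"chr1": 2_000_000}},
        "hotspots": {
            "n": 60, "min_spacing": 12_000, "multi_motif_fraction": 0.1,
            "hotspot_halfwidth": 1000,
            "allele_mix": {"Dom2": 0.5, "Cast": 0.5},
        },
        "cutrun": {
            "n_fragments": 300_000, "signal_fraction": 0.6,
            "frag_len_mean": 165, "frag_len_sd": 15, "len_clip": [100, 250],
            "ndr_halfwidth": 75, "nucleosome_spacing": 180,
        },
        "coverage": {"binsize": 50, "len_lo": 130, "len_hi": 200, "flank": 1000},
        "peaks": {"p_max": 0.001, "merge_gap": 500, "fold_min": 0.0},
        "endseq": {
            "n_reads": 1_000_000, "central_fraction": 0.5, "resection_mean": 800,
            "max_flank": 3000, "min_flank": 300, "central_halfwidth": 50,
            "flank_scale_ko": 2.0,
            "spike": {"chrom": "chrSpike", "position": 50_000, "fraction": 0.05},
            "spike_chrom_length": 100_000,
            "decompose": {"central_halfwidth": 250, "flank_range": [250, 3000]},
        },
        "coexpr": {
            "n_genes": 200, "n_cells": 1000, "target_gene": "Prdm9",
            "planted_rho": {"Zcwpw1": 0.5, "geneA": 0.35, "geneB": 0.2},
            "top_k": 25,
        },
        "evo": {
            "n1": 8, "n2": 8, "n_bootstrap": 50,
            "catalytic_positions": [60, 70, 80],
        },
        "itc": {
            "kd": 2.0, "dh": -10.0, "n_sites": 1.0,
            "cell_conc": 25.0, "syringe_conc": 343.0,
            "n_injections": 16, "injection_volume": 2.5,
            "cell_volume": 200.0, "temperature": 298.15, "noise_sd": 0.0,
        },
    }


def _simulated_hotspot_genome(config: Dict, seed: int):
    g = syn.generate_genome(seed, config["genome"]["chrom_lengths"])
    hsc = config["hotspots"]
    return syn.plant_hotspots(
        g, n=hsc["n"], allele_mix=hsc["allele_mix"],
        min_spacing=hsc["min_spacing"],
        multi_motif_fraction=hsc["multi_motif_fraction"],
        hotspot_halfwidth=hsc["hotspot_halfwidth"], seed=seed + 1,
    )


def recipe_cutrun_hotspots(config: Dict) -> Dict:
    """Reader CUT&RUN around planted hotspots: fragment filter, center-3-nt
    coverage, peak calling, motif centering, anchored profile."""
    seed = config["seed"]
    # single-allele background (B6-like): every hotspot carries the Dom2 motif
    config = dict(config)
    config["hotspots"] = dict(config["hotspots"], allele_mix={"Dom2": 1.0})
    genome, truth = _simulated_hotspot_genome(config, seed)
    cc = config["cutrun"]
    frags = syn.simulate_cutrun(
        genome, truth, n_fragments=cc["n_fragments"],
        frag_len_mean=cc["frag_len_mean"], frag_len_sd=cc["frag_len_sd"],
        len_clip=tuple(cc["len_clip"]), ndr_halfwidth=cc["ndr_halfwidth"],
        nucleosome_spacing=cc["nucleosome_spacing"],
        signal_fraction=cc["signal_fraction"], seed=seed + 2,
    )
    cvc = config["coverage"]
    kept = cov.filter_fragment_length(frags, cvc["len_lo"], cvc["len_hi"])
    track = cov.center_weighted_coverage(kept, genome.lengths, cvc["binsize"])
    peaks = pk.call_peaks(track, p_max=config["peaks"]["p_max"],
                          merge_gap=config["peaks"]["merge_gap"],
                          fold_min=config["peaks"]["fold_min"])
    peak_set = peaks.to_interval_set(genome.lengths)
    # recall of planted hotspots by peak overlap
    hs_ivs = truth.intervals(genome.lengths)
    recovered = sum(
        1 for iv in hs_ivs if peak_set.overlap_bp(iv.chrom, iv.start, iv.end) >= 1
    )
    pwm = hs.PWM.from_consensus(truth.motifs["Dom2"], name="Dom2")
    hits = hs.scan_motif(genome.chroms, pwm, threshold=10.0)
    anchors, center_report = hs.center_and_filter_hotspots(hs_ivs, hits)
    profile = cov.anchor_profile(kept, anchors, flank=cvc["flank"], binsize=cvc["binsize"])
    mean_prof = profile.mean_profile
    sym_err = float(
        np.max(np.abs(mean_prof - mean_prof[::-1])) / max(mean_prof.max(), 1e-12)
    )
    strengths = pk.peak_strength(hs_ivs, kept)
    return {
        "n_fragments_total": len(frags),
        "n_fragments_retained": len(kept),
        "retained_fraction": len(kept) / max(len(frags), 1),
        "n_peaks": len(peaks),
        "hotspot_recall": recovered / len(hs_ivs),
        "centering": center_report,
        "profile_symmetry_error": sym_err,
        "mean_hotspot_strength": float(strengths["count"].mean()),
    }


def recipe_endseq_contrast(config: Dict) -> Dict:
    """WT vs KO END-seq: spike-in normalization and central/flank
    decomposition of the break profile."""
    seed = config["seed"]
    ec = config["endseq"]
    cfg_genome = dict(config["genome"]["chrom_lengths"])
    genome, truth = _simulated_hotspot_genome(config, seed)
    spike = hs.SpikeSpec(**ec["spike"])
    genome_decl = dict(genome.lengths)
    genome_decl[spike.chrom] = ec["spike_chrom_length"]

    samples = {}
    for name, flank_scale, s in (("WT", 1.0, seed + 3), ("KO", ec["flank_scale_ko"], seed + 4)):
        samples[name] = syn.simulate_endseq(
            genome, truth, n_reads=ec["n_reads"],
            central_fraction=ec["central_fraction"],
            resection_mean=ec["resection_mean"], max_flank=ec["max_flank"],
            min_flank=ec["min_flank"], central_halfwidth=ec["central_halfwidth"],
            genotype_flank_scale=flank_scale, spike=spike, seed=s,
        )
    windows = truth.windows(3000, genome_decl)
    anchors = AnchorSet(
        truth.table["chrom"].tolist(),
        truth.table["center"].to_numpy(np.int64),
        ["."] * len(truth.table),
        genome=genome_decl,
    )
    norm = {}
    profiles = {}
    for name, reads in samples.items():
        norm[name] = hs.spikein_normalize(
            reads["chrom"], reads["pos"].to_numpy(), windows, spike
        )
        m = cov.point_profile(
            reads["chrom"], reads["pos"].to_numpy(), anchors,
            flank=ec["max_flank"], binsize=50,
        )
        # spike-normalize the profile for cross-sample comparability: raw
        # profile counts over raw spike counts (library depth cancels)
        m.values = m.values / (norm[name]["spike_count"] * spike.divisor)
        profiles[name] = m
    dc = ec["decompose"]
    decomp = hs.central_flank_decomposition(
        profiles, central_halfwidth=dc["central_halfwidth"],
        flank_range=tuple(dc["flank_range"]), contrast=("KO", "WT"),
    )
    return {
        "normalized_intensity": {k: v["normalized"] for k, v in norm.items()},
        "decomposition": decomp,
        "flank_ratio": decomp["contrast"]["flank_ratio"],
        "central_ratio": decomp["contrast"]["central_ratio"],
        "genome": cfg_genome,
    }


def recipe_hybrid_alleles(config: Dict) -> Dict:
    """F1-hybrid hotspot classification against parental maps plus
    motif-based allele assignment."""
    seed = config["seed"]
    genome, truth = _simulated_hotspot_genome(config, seed)
    rng = np.random.default_rng(seed + 5)
    hs_ivs = list(truth.intervals(genome.lengths))
    alleles = truth.table["allele"].tolist()
    # parental maps: Dom2 hotspots active in B6, Cast hotspots in CAST;
    # a random subset of hotspots is left out of both maps -> novel in F1
    novel_mask = rng.random(len(hs_ivs)) < 0.2
    b6 = IntervalSet(
        [iv for iv, a, nv in zip(hs_ivs, alleles, novel_mask) if a == "Dom2" and not nv],
        genome=genome.lengths,
    )
    cast = IntervalSet(
        [iv for iv, a, nv in zip(hs_ivs, alleles, novel_mask) if a == "Cast" and not nv],
        genome=genome.lengths,
    )
    f1 = IntervalSet(hs_ivs, genome=genome.lengths)
    classes = hs.classify_hybrid_hotspots(f1, b6, cast)
    expected_novel = int(novel_mask.sum())

    pwm_d = hs.PWM.from_consensus(truth.motifs["Dom2"], name="Dom2")
    pwm_c = hs.PWM.from_consensus(truth.motifs["Cast"], name="Cast")
    allele_calls = hs.assign_allele_by_motif(f1, genome.chroms, pwm_d, pwm_c)
    # single-motif hotspots with known truth
    truth_sorted = truth.table.sort_values(["chrom", "center"]).reset_index(drop=True)
    correct = (allele_calls["allele"].to_numpy() == truth_sorted["allele"].to_numpy())
    return {
        "class_counts": classes.attrs["counts"],
        "novel_expected": expected_novel,
        "novel_called": int(classes.attrs["counts"].get("novel", 0)),
        "allele_accuracy": float(correct.mean()),
        "n_hotspots": len(hs_ivs),
    }


def recipe_coexpr_rank(config: Dict) -> Dict:
    """Single-cell co-expression ranking against the target gene."""
    seed = config["seed"]
    cc = config["coexpr"]
    mat = syn.simulate_sc_counts(
        n_genes=cc["n_genes"], n_cells=cc["n_cells"],
        target_gene=cc["target_gene"], planted_rho=cc["planted_rho"], seed=seed + 6,
    )
    norm = cx.normalize_counts(mat)
    table = cx.spearman_coexpression(norm, cc["target_gene"])
    ranked = table[table["gene"] != cc["target_gene"]].reset_index(drop=True)
    top = ranked.iloc[0]
    top_k = table.head(cc["top_k"])["gene"].tolist()
    order = cx.hierarchical_order(norm.loc[[g for g in top_k if g in norm.index]])
    return {
        "top_gene": str(top["gene"]),
        "top_rho": float(top["rho"]),
        "top_p": float(top["p"]),
        "planted_rho": mat.attrs["planted_rho"].get(str(top["gene"])),
        "n_cells_ordered": int(len(order)),
        "rho_table_head": ranked.head(5)[["gene", "rho"]].to_dict("records"),
    }


def recipe_evo_screen(config: Dict) -> Dict:
    """Dual-domain ortholog screen: hit pairing, paralog assignment,
    conservation and catalytic-residue tally."""
    seed = config["seed"]
    ev = config["evo"]
    msa, hits, truth = syn.simulate_protein_families(
        n1=ev["n1"], n2=ev["n2"],
        catalytic_positions=tuple(ev["catalytic_positions"]), seed=seed + 7,
    )
    candidates = evo.pair_domain_hits(hits, max_distance=50_000)
    fam1_refs = [f"family1_sp{i}" for i in (1, 2)]
    fam2_refs = [f"family2_sp{i}" for i in (1, 2)]
    assignment = evo.assign_paralog(
        msa, fam1_refs, fam2_refs, outgroup="outgroup",
        n_bootstrap=ev["n_bootstrap"], seed=seed + 8,
    )
    merged = assignment.assignments.merge(truth, on="id")
    acc = float((merged["family_x"] == merged["family_y"]).mean()) if len(merged) else 1.0
    profile = evo.conservation_profile(msa, msa.reference_id)
    tally = evo.catalytic_conservation(
        msa, msa.reference_id, positions=tuple(ev["catalytic_positions"])
    )
    return {
        "n_species_screened": int(hits["species"].nunique()),
        "n_candidates_within_50kb": int(len(candidates)),
        "paralog_accuracy": acc,
        "mean_support": float(assignment.assignments["support"].mean()),
        "mean_conservation": float(profile["score"].mean()),
        "n_fully_catalytic": int((tally["n_conserved"] == 3).sum()),
    }


def recipe_itc_fit(config: Dict) -> Dict:
    """Simulate a titration and fit the one-set-of-sites model."""
    seed = config["seed"]
    ic = config["itc"]
    schedule = itc.TitrationSchedule(
        cell_volume=ic["cell_volume"], cell_conc=ic["cell_conc"],
        syringe_conc=ic["syringe_conc"],
        injection_volumes=[ic["injection_volume"]] * ic["n_injections"],
        temperature=ic["temperature"],
    )
    params = itc.BindingParams(kd=ic["kd"], dh=ic["dh"], n=ic["n_sites"])
    heats = syn.simulate_itc(params, schedule, noise_sd=ic["noise_sd"], seed=seed + 9)
    fit = itc.fit_one_set_of_sites(heats.heats, schedule)
    thermo = itc.derive_thermo(fit.params, schedule.temperature)
    return {
        "true": {"kd_uM": ic["kd"], "dh_kcal_mol": ic["dh"], "n_sites": ic["n_sites"]},
        "fitted": {
            "kd_uM": fit.params.kd, "dh_kcal_mol": fit.params.dh,
            "n_sites": fit.params.n, "baseline_ucal": fit.params.baseline,
        },
        "converged": fit.converged,
        "residual_norm": fit.residual_norm,
        "thermo": {
            "dG_kcal_mol": thermo.dg, "dS_cal_mol_K": thermo.ds,
            "T_K": thermo.temperature,
        },
    }


RECIPES = {
    "cutrun-hotspots": recipe_cutrun_hotspots,
    "endseq-contrast": recipe_endseq_contrast,
    "hybrid-alleles": recipe_hybrid_alleles,
    "coexpr-rank": recipe_coexpr_rank,
    "evo-screen": recipe_evo_screen,
    "itc-fit": recipe_itc_fit,
}


def run_recipe(name: str, config: Optional[Dict] = None,
               out_dir: Optional[str] = None) -> Dict:
    """Run one named recipe; returns (and optionally writes) its summary
    bundle, stamped with the config hash."""
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; choose from {sorted(RECIPES)}")
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    try:
        summary = RECIPES[name](cfg)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"recipe {name!r} failed: {exc}") from exc
    bundle = {"recipe": name, "config_hash": config_hash(cfg), "config": cfg,
              "summary": summary}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{name}.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=_jsonable)
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return str(obj)
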