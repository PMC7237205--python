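# Methods

`meiohot` implements the computational core of a meiotic-recombination
hotspot study centered on a dual histone-methylation reader protein
(ZCWPW1-like, carrying zf-CW and PWWP domains) acting downstream of the
hotspot-positioning methyltransferase PRDM9. This note documents the models,
the defaults and why they were chosen, the synthetic-data generators, and
the known limitations.

## Coordinates and containers

All genomic coordinates are 0-based half-open (BED convention); 1-based
inputs must be converted at the I/O boundary. Interval logic is a sorted
sweep over per-chrom start/end arrays (`IntervalSet`); point features
(motif centers, merged TSS) are `AnchorSet`s. Anchor merging uses
single-linkage chaining — anchors within the radius (default 500 bp) join
one cluster, which is recentered at the floored midpoint of its extreme
positions. Chaining was chosen because it matches common merge tools and is
idempotent, which is tested. Blacklist subtraction removes any interval with
≥1 bp of overlap rather than trimming it.

## Fragment-center coverage

CUT&RUN-style protected fragments are reduced to their central three
nucleotides: for a fragment `[start, end)` the center base is
`c = floor((start + end − 1)/2)` (the left-of-center base for even lengths,
which the assay does not define) and each of `{c−1, c, c+1}` adds one count
to its genome-anchored 50 bp bin — mass can split across a bin boundary, and
the track total is exactly 3× the fragment count up to chrom-edge clipping.
Fragments are first restricted to the closed length range [130, 200] bp (the
reader-protected footprint; bounds read as inclusive) and, when loading
alignments, to mapping quality strictly greater than 30. The "quality > 30"
rule is interpreted as MAPQ, the only per-template quality available at this
stage.

Anchor profiles bin the same center-base mass at anchor-relative offsets
(`[−flank, +flank)`), reverse columns for minus-strand anchors, drop anchors
within `flank` of a chrom edge, and order heatmap rows by descending row sum
(configurable). Windowed RPKM assigns a read to a window iff its 5′ end lies
inside it — END-seq reads mark break-proximal ends, so 5′-end assignment is
the physically meaningful rule; fragment-overlap counting is available as an
option through `peak_strength`.

## Peak calling

The caller is an explicit Poisson window test, not a MACS reimplementation:
per-bin expectation λ is the genome-wide mean bin count (optionally the
elementwise max with a depth-scaled control), a bin is significant iff
`P(X ≥ x | λ) ≤ p_max` (default 0.001), significant bins within the merge
gap join one peak (default 500 bp; 1,000 bp recommended for END-seq-style
broad signal), fold enrichment is the max bin count over λ, and peaks with
fold ≤ `fold_min` are dropped, so `fold_min = 2.5` keeps strictly >2.5×
sites. No deduplication is performed anywhere. Absolute peak counts from
this caller are not comparable to MACS output; externally called peak BED
files can be ingested instead wherever peaks are consumed.

## Motif scanning and hotspot classification

PWMs carry per-position probabilities (pseudocount 0.01 per base when built
from counts) and score windows as Σ log2(p/background) on both strands;
overlapping hits are resolved greedily best-score-first with ties broken
leftmost then plus-strand. Hotspots are motif-centered only when they
contain exactly one hit: multi-motif hotspots are excluded from centered
analyses, and zero-hit hotspots necessarily are too, both tallied in an
exclusion report. Allele assignment compares the best in-hotspot score of
the two allele PWMs; a gap below the margin (default 1 bit) is called
ambiguous. F1-hybrid peaks are labeled shared-B6 / shared-CAST /
shared-both / novel by ≥1 bp overlap with the two parental hotspot maps.
Dual-mark classes (H3K4me3/H3K36me3 both, single, neither) use the same
overlap rule, and per-class strength comparisons use a one-sided
Mann–Whitney rank-sum test.

## END-seq spike-in normalization and resection decomposition

Sample intensity is the RPKM sum over ±3 kb hotspot windows divided by the
RPKM around the spiked-in break locus (default window ±3 kb, configurable —
the exact spike window is an open choice) and then divided by 1/f, i.e. by
20 for a 5% (1:20) spike. Because both RPKM terms share the library size,
the statistic is exactly invariant to global depth rescaling; spike-in cells
are mixed by cell count, so it is *not* invariant to a change in the bulk
break rate, which is the quantity it is designed to recover.

Break profiles decompose into a central window (±250 bp; break/invasion
intermediates) and symmetric flanks (250–3,000 bp; resection endpoints).
These window choices are not dictated by the underlying assay — the
central/flank contrast is qualitative — so they are parameters, recorded in
the output. The central window is `[−ch, ch)` and the flank `[fs, fe]`;
windows are disjoint whenever `ch ≤ fs`, which permits the default
`ch = fs = 250`.

Spearman correlations between per-hotspot strength metrics use average ranks
for ties and a two-sided t-approximation p-value, replaced by full
permutation enumeration at n ≤ 10 where the approximation is poor.

## Single-cell co-expression

Counts are normalized with median-ratio size factors (cell total over the
median cell total) and log2(x+1). This is deliberately simpler than
pooling-based normalization: every downstream statistic is rank-based
per gene, so the choice only matters through rank-preserving per-cell
scaling, and the planted-truth tests confirm insensitivity. Genes are
ranked by Spearman rho against the target gene (ties averaged; exact
permutation p at ≤10 cells); constant genes are excluded with a flag. Cell
ordering for heatmaps is agglomerative complete-linkage clustering on
Euclidean distances over the top-correlated genes.

Whether to correlate raw or normalized counts is genuinely open; the
default is normalized, with raw counts one call away, and the two agree on
rank order in the synthetic tests.

## Ortholog screen, paralog assignment, conservation

Candidate dual-domain loci require at least one zf-CW and one PWWP hit on
the same subject with an inter-domain gap (nearest ends; 0 when
overlapping) of at most 50 kb inclusive; the best-scoring pair per subject
is kept. Paralog families are separated with a neighbor-joining tree on
p-distances (mismatch fraction over pairwise non-gap columns), rooted at a
declared outgroup; a candidate takes the family of the first ancestor on
its root path that contains references of exactly one family, and is
unresolved when that ancestor mixes both. Support is the agreement fraction
over column-bootstrap replicates (default 100). NJ replaces
maximum-likelihood inference deliberately: only the two-family bipartition
is consumed, which NJ recovers exactly on clean data (tested on additive
matrices and simulated clades); the tree and the method label are written
to output metadata.

Conservation profiles drop columns gapped in the reference, exclude gaps
from column frequencies (renormalizing), and report the max residue
frequency as the score — a documented stand-in for proprietary alignment
viewers' conservation scores — plus Shannon entropy in bits. Catalytic
tallies map 1-based ungapped reference positions (default 276/341/357,
tyrosine) through cumulative non-gap counts to alignment columns; if the
reference itself lacks the queried residue at a queried position the call
errors rather than guessing an isoform numbering.

## ITC one-set-of-sites model

For N identical independent sites, after injection i with dilution-corrected
totals `M_i` (macromolecule) and `X_i` (ligand), the bound fraction Θ solves
`Θ² − Θ(1 + X/(NM) + K_D/(NM)) + X/(NM) = 0` (root in [0,1]); cumulative
heat is `Q_i = N Θ_i M_i ΔH V0` and the per-injection heat applies the
standard displaced-volume correction
`ΔQ_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2 + baseline`. The
instrument's own correction is proprietary, so this standard formulation is
the documented choice. Units are fixed (µM, µL, kcal/mol, µcal). Fitting is
nonlinear least squares over (log K_D, ΔH, N, baseline) — the log scale
stabilizes K_D across the c = N·M0/K_D range — initialized at N = 1, ΔH
from the first injections, and K_D from a transition-sharpness heuristic;
non-convergence is flagged, never silently returned. Noiseless recovery is
verified to <1e-4 relative for c in [1, 1000]. Derived quantities:
ΔG = RT ln(K_D in molar), ΔS = (ΔH − ΔG)/T (reported in cal/mol/K), with
ΔG = ΔH − TΔS holding to machine precision. By convention N absorbs
active-concentration error; this is documented, not corrected.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of its seed and exports a truth table;
tests compare estimates to truth, never to constants.

* **Genome/hotspots** — uniform-random bases; two 16-bp allele consensus
  motifs (Hamming distance 8) written at hotspot centers, reverse
  complement on minus strands; hotspot centers pairwise ≥ min spacing
  (default 6 kb, 12 kb in the recipes); an exact `round(n·fraction)` subset
  receives a second motif to exercise multi-motif exclusion. No base
  composition, repeat, or mappability structure is modeled.
* **CUT&RUN fragments** — midpoints on the ±1/±2 nucleosome positions
  (spacing 180 bp) with clipped Gaussian jitter so no midpoint enters the
  ±75 bp nucleosome-depleted region; uniform background; truncated-normal
  lengths (165 ± 15, clipped to [100, 250]) so the [130, 200] filter removes
  an analytically known ~2% mass. No sequence bias or duplicates.
* **END-seq reads** — per hotspot, central reads uniform in ±50 bp; flank
  offsets `min_flank + Exp(mean 800 bp)` truncated at 3 kb on both sides,
  with `min_flank = 300 bp` representing the shortest resolvable resection
  tract (it also keeps the flank component out of the ±250 bp central
  analysis window, as real resection signal sits clear of the break-proximal
  peak). A genotype scale multiplies flank reads only (resection phenotype)
  or all bulk reads (break-rate phenotype); spike reads are Poisson with
  mean f × nominal depth, independent of bulk break rate.
* **UMI matrices** — Gaussian copula with latent Pearson `r = 2 sin(πρ/6)`
  (the exact bivariate-normal inversion of Spearman's rho), log-normal
  rates, per-cell depth factors, Poisson sampling. Defaults (mean 100
  counts, rate sigma 1.0) emulate deeply sequenced full-length single-cell
  libraries; sparser droplet-style matrices would attenuate rank
  correlations more than the ±0.1 fidelity the generator guarantees.
  Requested |ρ| > 0.95 is refused (copula distortion).
* **Protein families** — a root sequence diverges into two clades
  (between-clade rate 0.4, within-clade 0.08) with domain blocks held at
  configurable conservation (1.0 ⇒ invariant columns) and catalytic
  positions set explicitly from truth; the domain-hit table assigns
  genomic-scale inter-domain distances spanning the 50 kb screen boundary.
  Alignments are gap-free by construction — gap handling is tested on
  constructed alignments instead.
* **ITC heats** — the forward model plus i.i.d. Gaussian noise.

Passing tests on these generators demonstrates the correctness of the
statistics and transformations, not robustness to alignment artifacts,
copy-number structure, batch effects, or droplet sparsity, none of which
are simulated.

## Problem sizes

The bundled recipes run on a 2 Mb single-chrom genome with 60 hotspots,
3×10⁵ CUT&RUN fragments, and 10⁶ END-seq reads per sample — sizes at which
every planted effect is detected with comfortable margin while a full
recipe completes in seconds; all sizes are config knobs.
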