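"""Dual-domain ortholog screening, paralog assignment, conservation
profiling, and catalytic-residue tallying.

The screen pairs zf-CW and PWWP domain hits on the same subject sequence,
requiring both domains within 50 kb. Candidate orthologs are assigned to one
of two paralog families (e.g. ZCWPW1 vs ZCWPW2) by neighbor joining on
p-distances with column-bootstrap support, rooted at a declared outgroup.
Conservation is profiled per reference column as the max residue frequency
and as Shannon entropy in bits, with gap characters excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "Msa",
    "read_alignment",
    "pair_domain_hits",
    "p_distance_matrix",
    "nj_tree",
    "assign_paralog",
    "conservation_profile",
    "catalytic_conservation",
    "percent_identity",
]

GAP = "-"


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped sequences keyed by
    id, with a designated reference sequence."""

    sequences: Dict[str, str]
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences have unequal lengths: {lengths}")
        if self.reference_id is not None and self.reference_id not in self.sequences:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def ids(self) -> List[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, j: int) -> List[str]:
        return [s[j] for s in self.sequences.values()]

    def subset(self, ids: Sequence[str]) -> "Msa":
        return Msa({i: self.sequences[i] for i in ids}, reference_id=None)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def read_alignment(path, reference_id: Optional[str] = None) -> Msa:
    """Aligned FASTA -> Msa (via Biopython)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Msa(seqs, reference_id=reference_id)


# ---------------------------------------------------------------------------
# Dual-domain screening


def pair_domain_hits(hits: pd.DataFrame, max_distance: int = 50_000) -> pd.DataFrame:
    """Pair zf-CW and PWWP domain hits on the same subject into candidate
    loci.

    ``hits`` columns: species, subject, domain ('zf-CW'|'PWWP'), start, end,
    score. Candidates require at least one hit per domain on the same
    subject; the inter-domain distance is the gap between the nearest ends of
    the two aligned regions (0 when they overlap) and must be
    <= ``max_distance`` (inclusive). The best pair per subject (by summed
    score) is retained. Order of rows in ``hits`` does not affect the result.
    """
    required = {"species", "subject", "domain", "start", "end", "score"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    bad = hits.loc[hits["start"] >= hits["end"]]
    if len(bad):
        raise ValueError("domain hit with start >= end")
    rows = []
    for (species, subject), grp in hits.groupby(["species", "subject"], sort=True):
        cw = grp[grp["domain"] == "zf-CW"]
        pw = grp[grp["domain"] == "PWWP"]
        if cw.empty or pw.empty:
            continue
        best = None
        for _, a in cw.sort_values(["start", "end"]).iterrows():
            for _, b in pw.sort_values(["start", "end"]).iterrows():
                dist = max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]))
                if dist > max_distance:
                    continue
                key = (a["score"] + b["score"], -dist)
                if best is None or key > best[0]:
                    best = (key, a, b, dist)
        if best is not None:
            _, a, b, dist = best
            rows.append(
                {
                    "species": species,
                    "subject": subject,
                    "zfcw_start": int(a["start"]), "zfcw_end": int(a["end"]),
                    "pwwp_start": int(b["start"]), "pwwp_end": int(b["end"]),
                    "distance": int(dist),
                    "score": float(a["score"] + b["score"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "subject", "zfcw_start", "zfcw_end",
                 "pwwp_start", "pwwp_end", "distance", "score"],
    )


# ---------------------------------------------------------------------------
# Trees and paralog assignment


def p_distance_matrix(msa: Msa, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Pairwise p-distance (mismatch fraction over shared non-gap columns)."""
    ids = list(ids) if ids is not None else msa.ids
    arrs = {i: np.frombuffer(msa.sequences[i].encode(), dtype="S1") for i in ids}
    gap = np.frombuffer(GAP.encode(), dtype="S1")[0]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            shared = (a != gap) & (b != gap)
            ns = int(shared.sum())
            d = 0.5 if ns == 0 else float((a[shared] != b[shared]).mean())
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None):
    """Neighbor-joining tree; rooted at the outgroup's attachment node when
    given. Returns a skbio TreeNode."""
    tree = nj(dm)
    if outgroup is not None:
        tip = tree.find(outgroup)
        if tip.parent is not None and tip.parent.parent is not None:
            tree = tree.root_at(tip.parent)
    return tree


@dataclass
class ParalogAssignment:
    assignments: pd.DataFrame  # columns: id, family, support
    tree_newick: str

    def family_of(self, seq_id: str) -> str:
        row = self.assignments.loc[self.assignments["id"] == seq_id]
        if row.empty:
            raise KeyError(seq_id)
        return str(row["family"].iloc[0])


def _assign_one(tree, candidate: str, fam1: set, fam2: set) -> str:
    """Walk from the candidate tip toward the root; the first ancestor whose
    leaf set contains any reference decides the family (both families ->
    unresolved)."""
    node = tree.find(candidate)
    while node.parent is not None:
        node = node.parent
        leaves = {t.name for t in node.tips()}
        has1 = bool(leaves & fam1)
        has2 = bool(leaves & fam2)
        if has1 and has2:
            return "unresolved"
        if has1:
            return "family1"
        if has2:
            return "family2"
    return "unresolved"


def assign_paralog(
    msa: Msa,
    family1_refs: Sequence[str],
    family2_refs: Sequence[str],
    outgroup: str,
    candidates: Optional[Sequence[str]] = None,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> ParalogAssignment:
    """Assign candidate sequences to paralog family1 or family2.

    An NJ tree on p-distances is rooted at the outgroup; each candidate is
    assigned to the family whose references share its smallest enclosing
    clade that excludes the other family's references. Support is the
    fraction of ``n_bootstrap`` column-resampled trees agreeing with the
    point assignment.
    """
    fam1, fam2 = set(family1_refs), set(family2_refs)
    if not fam1 or not fam2:
        raise ValueError("need at least one reference per family")
    if outgroup not in msa.sequences:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    if candidates is None:
        candidates = [
            i for i in msa.ids if i not in fam1 | fam2 and i != outgroup
        ]
    ids = msa.ids
    dm = p_distance_matrix(msa)
    tree = nj_tree(dm, outgroup=outgroup)
    point = {c: _assign_one(tree, c, fam1, fam2) for c in candidates}

    agree = {c: 0 for c in candidates}
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    seq_arr = np.array([list(msa.sequences[i]) for i in ids])
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        boot = Msa({ids[k]: "".join(seq_arr[k, cols]) for k in range(len(ids))})
        bt = nj_tree(p_distance_matrix(boot), outgroup=outgroup)
        for c in candidates:
            if _assign_one(bt, c, fam1, fam2) == point[c]:
                agree[c] += 1
    support = {c: (agree[c] / n_bootstrap if n_bootstrap else 1.0) for c in candidates}
    df = pd.DataFrame(
        {"id": list(candidates),
         "family": [point[c] for c in candidates],
         "support": [support[c] for c in candidates]}
    )
    return ParalogAssignment(df, str(tree).strip())


# ---------------------------------------------------------------------------
# Conservation


def conservation_profile(msa: Msa, reference_id: Optional[str] = None) -> pd.DataFrame:
    """Per-reference-column conservation: alignment columns where the
    reference is gapped are removed; per retained column (gaps excluded,
    frequencies renormalized) the score is the max residue frequency and the
    entropy is Shannon H = -sum p log2 p in bits. All-gap columns are flagged
    with NaN score/entropy.

    Returns a frame with ref_pos (1-based ungapped), column (alignment
    index), score, entropy.
    """
    ref_id = reference_id or msa.reference_id
    if ref_id is None:
        raise ValueError("no reference sequence declared")
    ref = msa.sequences[ref_id]
    rows = []
    ref_pos = 0
    for j, ch in enumerate(ref):
        if ch == GAP:
            continue
        ref_pos += 1
        residues = [c for c in msa.column(j) if c != GAP]
        if not residues:
            score = entropy = np.nan
        else:
            _, counts = np.unique(residues, return_counts=True)
            freqs = counts / counts.sum()
            score = float(freqs.max())
            entropy = float(-(freqs * np.log2(freqs)).sum())
        rows.append({"ref_pos": ref_pos, "column": j, "score": score, "entropy": entropy})
    return pd.DataFrame(rows)


def map_reference_positions(msa: Msa, reference_id: str, positions: Sequence[int]) -> List[int]:
    """Map 1-based ungapped reference positions to alignment column indices."""
    ref = msa.sequences[reference_id]
    cols = []
    wanted = set(positions)
    found = {}
    ref_pos = 0
    for j, ch in enumerate(ref):
        if ch == GAP:
            continue
        ref_pos += 1
        if ref_pos in wanted:
            found[ref_pos] = j
    missing = [p for p in positions if p not in found]
    if missing:
        raise ValueError(
            f"positions {missing} beyond reference ungapped length ({ref_pos})"
        )
    return [found[p] for p in positions]


def catalytic_conservation(
    msa: Msa,
    reference_id: str,
    positions: Sequence[int] = (276, 341, 357),
    residue: str = "Y",
) -> pd.DataFrame:
    """Count, per sequence, how many queried catalytic positions carry the
    queried residue.

    Positions are 1-based in the ungapped reference. The reference must carry
    ``residue`` at every queried position (otherwise the numbering or isoform
    is wrong and an error is raised instead of guessing).
    """
    cols = map_reference_positions(msa, reference_id, positions)
    ref = msa.sequences[reference_id]
    for p, j in zip(positions, cols):
        if ref[j] != residue:
            raise ValueError(
                f"reference residue at position {p} is {ref[j]!r}, expected "
                f"{residue!r} (position/isoform mismatch)"
            )
    rows = []
    for name, seq in msa.sequences.items():
        count = sum(1 for j in cols if seq[j] == residue)
        rows.append({"id": name, "n_conserved": count})
    return pd.DataFrame(rows)


def percent_identity(msa: Msa, id_a: str, id_b: str) -> float:
    """Matches / columns where both sequences are non-gap."""
    a, b = msa.sequences[id_a], msa.sequences[id_b]
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        raise ValueError("no shared non-gap columns")
    return sum(1 for x, y in pairs if x == y) / len(pairs)
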