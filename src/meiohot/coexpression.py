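"""Single-cell co-expression ranking against a target gene.

UMI counts are normalized with median-ratio size factors and a log2
transform, then every gene is ranked by its Spearman correlation with the
target gene across cells. Because the statistic is rank-based, the ranking is
insensitive to the exact normalization scheme. A hierarchical ordering of
cells over the top-correlated genes reproduces the usual heatmap layout.
"""

from __future__ import annotations

import itertools
import logging
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_counts",
    "spearman_coexpression",
    "hierarchical_order",
    "exact_spearman_p",
]


def normalize_counts(matrix: pd.DataFrame, min_cell_fraction: float = 0.0) -> pd.DataFrame:
    """Median-ratio size-factor normalization of a genes x cells UMI matrix.

    Per-cell size factor = cell total / median(cell totals); each count maps
    to log2(count / size_factor + 1). All-zero cells are dropped with a
    warning. ``min_cell_fraction`` > 0 additionally drops genes expressed in
    fewer than that fraction of cells (degenerate rank protection).
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("UMI counts must be non-negative")
    totals = matrix.sum(axis=0)
    zero_cells = totals[totals == 0].index
    if len(zero_cells) == len(totals):
        raise ValueError("all cells have zero counts")
    if len(zero_cells):
        logger.warning("dropping %d all-zero cells", len(zero_cells))
        matrix = matrix.drop(columns=zero_cells)
        totals = totals.drop(zero_cells)
    size_factors = totals / totals.median()
    norm = np.log2(matrix.div(size_factors, axis=1) + 1.0)
    if min_cell_fraction > 0:
        expressed = (matrix > 0).mean(axis=1)
        norm = norm.loc[expressed >= min_cell_fraction]
    return norm


def spearman_coexpression(
    matrix: pd.DataFrame,
    target_gene: str,
    exact_p_max_n: int = 10,
) -> pd.DataFrame:
    """Spearman rho of every gene against ``target_gene`` across cells.

    Ties get average ranks; the two-sided p-value uses the t approximation
    (exact permutation enumeration for n <= ``exact_p_max_n`` cells).
    Constant genes are excluded (rho undefined) and flagged in
    ``result.attrs["excluded_constant"]``. The table is sorted by rho
    descending and carries a 1-based rank column.
    """
    if target_gene not in matrix.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cells")
    target = matrix.loc[target_gene].to_numpy(dtype=float)
    if np.all(target == target[0]):
        raise ValueError("target gene is constant")
    constant = np.all(X == X[:, :1], axis=1)
    ranks = stats.rankdata(X, axis=1)
    rt = stats.rankdata(target)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    tc = rt - rt.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ tc) / denom
    rho[constant] = np.nan
    if n <= exact_p_max_n:
        pvals = np.array(
            [np.nan if constant[i] else exact_spearman_p(X[i], target)
             for i in range(len(X))]
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pvals[np.abs(rho) >= 1.0] = 0.0
    out = pd.DataFrame({"gene": matrix.index, "rho": rho, "p": pvals})
    excluded = out.loc[out["rho"].isna(), "gene"].tolist()
    out = out.dropna(subset=["rho"]).sort_values(
        "rho", ascending=False, kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["excluded_constant"] = excluded
    out.attrs["target"] = target_gene
    return out


def exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n only).

    Enumerates all n! permutations of one variable; p = fraction with
    |rho_perm| >= |rho_observed|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        ac = a - a.mean()
        bc = b - b.mean()
        d = np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
        return 0.0 if d == 0 else float(ac @ bc / d)

    obs = abs(_rho(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho(rx, ry[list(perm)])) >= obs - 1e-12:
            count += 1
    return count / total


def hierarchical_order(
    submatrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> np.ndarray:
    """Leaf order of columns (cells) from agglomerative clustering on the
    top-gene submatrix. Deterministic: scipy breaks merge ties by index."""
    if submatrix.shape[0] < 2:
        raise ValueError("need at least 2 genes (rows) to cluster cells")
    X = submatrix.to_numpy(dtype=float).T  # observations = cells
    if np.isnan(X).any():
        raise ValueError("NaN in matrix")
    if X.shape[0] < 2:
        return np.arange(X.shape[0])
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    return np.asarray(hierarchy.leaves_list(Z))
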