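"""Cross-dataset comparison of differential-expression results and samples.

Concordance between two case/control studies is measured as the Spearman (and
Pearson) correlation of per-gene DE statistics (t or log2 fold change) over
the genes shared by both result tables, with a one-sided test of positive
correlation.  Sample-level similarity across studies is summarized by
hierarchical clustering of a category-level median distance matrix and by
classical (Torgerson) multidimensional scaling, both on the distance
1 - Pearson correlation after quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

__all__ = [
    "ConcordanceReport",
    "concordance",
    "quantile_normalize",
    "category_summary_clustering",
    "classical_mds",
]


@dataclass
class ConcordanceReport:
    spearman: float
    spearman_p_onesided: float
    pearson: float
    pearson_p_onesided: float
    n_shared_genes: int
    stat: str


def _onesided_p(r: float, n: int) -> float:
    """One-sided p-value for H1: correlation > 0, via the t approximation."""
    if n < 3:
        return float("nan")
    r = min(max(r, -0.9999999), 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(stats.t.sf(t, df=n - 2))


def concordance(de_a: pd.DataFrame, de_b: pd.DataFrame, stat: str = "t") -> ConcordanceReport:
    """Correlation of DE statistics between two result tables.

    Both tables must be indexed by gene id and carry the column named by
    ``stat`` ("t" or "log2FC").  Only the gene intersection is used.
    """
    if stat not in de_a.columns or stat not in de_b.columns:
        raise KeyError(f"column {stat!r} must be present in both DE tables")
    shared = de_a.index.intersection(de_b.index)
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need at least 3")
    if n < 100:
        warnings.warn(f"only {n} shared genes; concordance estimate is unstable")
    x = de_a.loc[shared, stat].to_numpy(dtype=float)
    y = de_b.loc[shared, stat].to_numpy(dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceReport(
        spearman=rho,
        spearman_p_onesided=_onesided_p(rho, n),
        pearson=r,
        pearson_p_onesided=_onesided_p(r, n),
        n_shared_genes=n,
        stat=stat,
    )


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) to the mean sorted-value distribution.

    After normalization all columns have identical sorted values; ties within
    a column receive the mean of the reference values at the tied ranks.
    """
    x = expr.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # fractional average ranks over ties interpolate the reference values
        ranks = stats.rankdata(x[:, j], method="average") - 1
        frac = ranks % 1
        lo = np.floor(ranks).astype(int)
        hi = np.minimum(lo + 1, len(reference) - 1)
        out[:, j] = reference[lo] * (1 - frac) + reference[hi] * frac
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns of x."""
    d = 1.0 - np.corrcoef(x.T)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2, 0.0, None)


def category_summary_clustering(
    expr: pd.DataFrame,
    categories: Sequence[str],
    quantile_norm: bool = True,
) -> tuple[pd.DataFrame, str]:
    """Cluster sample categories by median cross-category distance.

    A pairwise 1 - correlation distance is computed for all samples (columns
    of ``expr``), the median distance over all pairs from categories (A, B)
    forms a summary distance matrix, and complete-linkage clustering of that
    matrix gives the final tree.

    Returns the summary distance matrix and the tree serialized as Newick.
    """
    categories = pd.Series(list(categories), index=expr.columns)
    counts = categories.value_counts()
    if (counts < 1).any():
        raise ValueError("every category needs at least one sample")
    if quantile_norm:
        expr = quantile_normalize(expr)
    dist = _correlation_distance(expr.to_numpy(dtype=float))
    cats = list(counts.index)
    k = len(cats)
    summary = np.zeros((k, k))
    idx = {c: np.flatnonzero((categories == c).to_numpy()) for c in cats}
    for i in range(k):
        for j in range(i + 1, k):
            block = dist[np.ix_(idx[cats[i]], idx[cats[j]])]
            summary[i, j] = summary[j, i] = float(np.median(block))
    summary_df = pd.DataFrame(summary, index=cats, columns=cats)
    if k < 2:
        return summary_df, f"{cats[0]};"
    Z = hierarchy.linkage(squareform(summary, checks=False), method="complete")
    tree = TreeNode.from_linkage_matrix(Z, cats)
    newick = str(tree).strip()
    return summary_df, newick


def classical_mds(data: pd.DataFrame, k: int = 2, is_distance: bool | None = None) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    ``data`` is either a symmetric sample x sample distance matrix or a
    gene x sample expression matrix (then 1 - correlation distances are
    computed first; set ``is_distance`` to force the interpretation).
    Coordinates are the top-k eigenvectors of the double-centered squared
    distance matrix scaled by the square roots of their eigenvalues;
    deterministic up to sign.
    """
    x = data.to_numpy(dtype=float)
    if is_distance is None:
        is_distance = (
            x.shape[0] == x.shape[1]
            and np.allclose(x, x.T, atol=1e-10)
            and np.allclose(np.diag(x), 0, atol=1e-10)
        )
    if is_distance:
        d = x
        names = data.index
    else:
        d = _correlation_distance(x)
        names = data.columns
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int(np.sum(vals > 1e-10))
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k} to {n_pos}")
        k = max(n_pos, 1)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    return pd.DataFrame(coords, index=names, columns=[f"MDS{i+1}" for i in range(k)])
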